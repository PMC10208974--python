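"""Comparative risk assessment of consumption-linked disease burden.

Four dietary risk factors (low intake of fruits, vegetables and legumes;
high intake of red meat) act on four disease endpoints (coronary heart
disease, stroke, cancer, type-II diabetes).  For each risk-disease pair the
population attributable fraction is

    PAF = (int RR(x) P(x) dx - RR(TMREL)) / int RR(x) P(x) dx,

where TMREL is the theoretical minimum risk exposure level.  The pipeline
assumes the entire national population sits at the mean intake x, i.e.
P(x) is a point mass, so PAF = (RR(x) - RR(TMREL)) / RR(x); the continuous
integral form is provided as an oracle and extension.

Relative-risk curves are log-linear per serving with TMREL clipping,

    RR(x) = rr_per_unit ** (clip(x) / serving_size),

where clip(x) = min(x, TMREL) for protective factors (no additional
benefit beyond TMREL) and max(x, TMREL) for harmful ones (no benefit below
TMREL).  This functional form, and the shipped parameter values, are
documented overridable choices — see docs/methods.md.

Risk factors are combined assuming independence:
PAF = 1 - prod_i (1 - PAF_i).  Attributable DALYs multiply the combined
PAF by disease-specific DALY totals; avoided DALYs difference two diets,
with bounds from re-running the whole chain at the lower/upper 95% CI
relative-risk parameters.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import integrate

from .errors import ConfigError, DataError

PROTECTIVE = "protective"
HARMFUL = "harmful"

RR_VARIANTS = ("central", "lower", "upper")


@dataclass(frozen=True)
class RelativeRiskModel:
    """Log-linear relative-risk curve for one risk-factor/disease pair.

    ``rr_per_unit`` (with its 95% CI) is the relative risk per
    ``serving_size`` grams/day of intake; ``tmrel`` is in g/day.
    """

    risk_factor: str
    disease: str
    rr_per_unit: float
    rr_lower: float
    rr_upper: float
    serving_size: float
    tmrel: float
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in (PROTECTIVE, HARMFUL):
            raise ConfigError(f"direction must be protective or harmful, got {self.direction!r}")
        if not (0 < self.rr_lower <= self.rr_per_unit <= self.rr_upper):
            raise ConfigError(
                f"{self.risk_factor}/{self.disease}: RR bounds must be positive and ordered"
            )
        if self.serving_size <= 0:
            raise ConfigError("serving_size must be > 0")
        if self.direction == PROTECTIVE and (self.rr_per_unit >= 1 or self.tmrel <= 0):
            raise ConfigError("protective factors need rr_per_unit < 1 and tmrel > 0")
        if self.direction == HARMFUL and (self.rr_per_unit <= 1 or self.tmrel < 0):
            raise ConfigError("harmful factors need rr_per_unit > 1 and tmrel >= 0")

    def rr(self, variant: str = "central") -> float:
        if variant == "central":
            return self.rr_per_unit
        if variant == "lower":
            return self.rr_lower
        if variant == "upper":
            return self.rr_upper
        raise ConfigError(f"unknown RR variant {variant!r}")


def relative_risk_at(model: RelativeRiskModel, intake: float, variant: str = "central") -> float:
    """RR at a population-mean intake level (g/day), with TMREL clipping."""
    if intake < 0:
        raise DataError("intake must be >= 0")
    rr = model.rr(variant)
    if model.direction == PROTECTIVE:
        x = min(intake, model.tmrel)
    else:
        x = max(intake, model.tmrel)
    return float(rr ** (x / model.serving_size))


def paf_point_mass(model: RelativeRiskModel, intake: float, variant: str = "central") -> float:
    """PAF with the whole population at one intake level.

    May be negative when current intake is *healthier* than the TMREL
    counterfactual (RR(x) < RR(TMREL)); always <= 1.
    """
    rr_x = relative_risk_at(model, intake, variant)
    rr_t = relative_risk_at(model, model.tmrel, variant)
    if rr_x == 0:
        raise DataError("RR(x) = 0: invalid relative-risk model")
    return (rr_x - rr_t) / rr_x


def paf_continuous(
    model: RelativeRiskModel,
    density: Callable[[np.ndarray], np.ndarray],
    support: tuple[float, float],
    variant: str = "central",
    *,
    norm_tol: float = 1e-6,
) -> float:
    """PAF for a continuous exposure distribution, by numerical quadrature.

    ``density`` must integrate to 1 over ``support`` (checked to
    ``norm_tol``).  With a near-degenerate density this converges to
    :func:`paf_point_mass` and therefore serves as its independent oracle.
    """
    a, b = support
    if not (0 <= a < b):
        raise DataError("support must satisfy 0 <= a < b")
    mass, _ = integrate.quad(density, a, b, limit=200)
    if abs(mass - 1.0) > norm_tol:
        raise DataError(f"exposure density integrates to {mass}, not 1")

    def integrand(x: float) -> float:
        return relative_risk_at(model, x, variant) * float(density(x))

    mean_rr, _ = integrate.quad(integrand, a, b, limit=200)
    rr_t = relative_risk_at(model, model.tmrel, variant)
    return (mean_rr - rr_t) / mean_rr


def combine_pafs(pafs: Iterable[float]) -> float:
    """Multi-risk combination under independence: 1 - prod(1 - PAF_i)."""
    pafs = list(pafs)
    if any(p > 1 for p in pafs):
        raise DataError("PAF values must be <= 1")
    prod = 1.0
    for p in pafs:
        prod *= 1.0 - p
    return 1.0 - prod


def validate_burden(burden: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("country", "disease", "dalys") if c not in burden.columns]
    if missing:
        raise DataError(f"disease burden table missing columns: {missing}")
    if (burden["dalys"] < 0).any():
        raise DataError("disease DALYs must be >= 0")
    return burden


def combined_pafs(
    exposures: pd.DataFrame,
    models: Sequence[RelativeRiskModel],
    variant: str = "central",
) -> pd.DataFrame:
    """Combined PAF per (country, disease) from per-risk point-mass PAFs.

    ``exposures`` has columns ``country, risk_factor, intake_g``.
    Risk factors with no exposure row for a country are an error.
    """
    required = {"country", "risk_factor", "intake_g"}
    if not required.issubset(exposures.columns):
        raise DataError(f"exposure table needs columns {sorted(required)}")
    intake = exposures.set_index(["country", "risk_factor"])["intake_g"]
    rows = []
    for country in sorted(exposures["country"].unique()):
        per_disease: dict[str, list[float]] = {}
        for m in models:
            key = (country, m.risk_factor)
            if key not in intake.index:
                raise DataError(f"no exposure for risk factor {m.risk_factor!r} in {country!r}")
            p = paf_point_mass(m, float(intake[key]), variant)
            per_disease.setdefault(m.disease, []).append(p)
        for disease, pafs in per_disease.items():
            rows.append({"country": country, "disease": disease, "paf": combine_pafs(pafs)})
    return pd.DataFrame(rows)


def attributable_dalys(
    pafs: pd.DataFrame, burden: pd.DataFrame
) -> tuple[pd.DataFrame, float]:
    """Attributable DALYs = PAF x disease DALYs, per country and globally.

    ``pafs`` has columns ``country, disease, paf``.  A missing burden row
    for a nonzero PAF is an error.  Returns (per-country table, global
    total).
    """
    validate_burden(burden)
    m = pafs.merge(burden, on=["country", "disease"], how="left")
    missing = m["dalys"].isna() & (m["paf"] != 0)
    if missing.any():
        rows = m.loc[missing, ["country", "disease"]].head().to_dict("records")
        raise DataError(f"missing burden rows for: {rows}")
    m["dalys"] = m["dalys"].fillna(0.0)
    m["attributable"] = m["paf"] * m["dalys"]
    per_country = m.groupby("country", as_index=False)["attributable"].sum()
    return per_country, float(m["attributable"].sum())


def avoided_dalys(
    base_exposures: pd.DataFrame,
    scenario_exposures: pd.DataFrame,
    models: Sequence[RelativeRiskModel],
    burden: pd.DataFrame,
) -> dict[str, float]:
    """Globally avoided DALYs moving from the base diet to a scenario diet.

    Central value differences attributable burden under central RR
    parameters; the uncertainty range re-runs the entire chain with the
    lower and upper 95% CI relative-risk parameters and reports the ordered
    (min, max).  Negative avoided DALYs (a scenario worse than base) are
    legal.
    """
    out = {}
    for variant in RR_VARIANTS:
        _, base_total = attributable_dalys(
            combined_pafs(base_exposures, models, variant), burden
        )
        _, scen_total = attributable_dalys(
            combined_pafs(scenario_exposures, models, variant), burden
        )
        out[variant] = base_total - scen_total
    lo, hi = sorted((out["lower"], out["upper"]))
    return {"value": out["central"], "lower": lo, "upper": hi}
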