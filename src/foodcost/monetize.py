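"""Monetarization of endpoint damages in 2018 US dollars.

Human health (DALYs) is valued by the budget-constraint method: one DALY is
worth the potential average annual economic production of a person at full
well-being,

    MF_HH = alpha * (GDP + GHP),        GHP = ghp_fraction * GDP,

with GDP the 2018 US GDP per capita (PPP) and alpha an adjustment factor
(default 1.87, uncertainty range 1.57-2.12) correcting potential production
for unemployment, ill health, trade barriers and under-education.

Ecosystem damage (species loss) is valued by benefit transfer from a
year-2000 valuation, scaled by income growth through the income elasticity
of willingness to pay for ecosystem protection:

    MF_ECO_2018 = MF_ECO_2000 * (GDP_2018 / GDP_2000) ** elasticity.

Costs are the product of endpoint impacts and factors; cost bounds pair the
impact CI bounds with the factor bounds (lower x lower, upper x upper).
Everything is linear and expressed in 2018 USD; there is no deflator
machinery and no alternative valuation school.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigError, DataError
from .lcia import ECO, HH

COMBINED = "COMBINED"


def human_health_factor(gdp: float, ghp_fraction: float = 0.5, alpha: float = 1.87) -> float:
    """USD per DALY via the budget-constraint method (see module docstring)."""
    if gdp <= 0 or alpha <= 0:
        raise ConfigError("human_health_factor requires gdp > 0 and alpha > 0")
    if ghp_fraction < 0:
        raise ConfigError("ghp_fraction must be >= 0")
    return alpha * (gdp + ghp_fraction * gdp)


def ecosystem_factor(
    mf_2000: float, gdp_2000: float, gdp_2018: float, elasticity: float = 0.38
) -> float:
    """USD per species-loss unit in 2018, by benefit transfer from 2000."""
    if min(mf_2000, gdp_2000, gdp_2018) <= 0:
        raise ConfigError("ecosystem_factor requires positive monetary inputs")
    if elasticity < 0:
        raise ConfigError("elasticity must be >= 0")
    return mf_2000 * (gdp_2018 / gdp_2000) ** elasticity


@dataclass(frozen=True)
class MonetarizationFactors:
    """Valuation factors with uncertainty ranges, all in 2018 USD.

    Defaults reproduce the budget-constraint human-health factor from the
    configured US 2018 GDP per capita (PPP) and carry the ecosystem factor
    bounds directly as configuration (the procedure generating the
    ecosystem bounds is not re-derived here).
    """

    alpha: float = 1.87
    alpha_lower: float = 1.57
    alpha_upper: float = 2.12
    gdp_2018: float = 62_967.0
    ghp_fraction: float = 0.5
    mf_eco: float = 17_891_594.0
    mf_eco_lower: float = 4_472_899.0
    mf_eco_upper: float = 44_728_985.0
    elasticity_eco: float = 0.38
    mf_hh: float = field(init=False)
    mf_hh_lower: float = field(init=False)
    mf_hh_upper: float = field(init=False)

    def __post_init__(self) -> None:
        if not (self.alpha_lower <= self.alpha <= self.alpha_upper):
            raise ConfigError("alpha bounds must be ordered")
        if not (0 < self.mf_eco_lower <= self.mf_eco <= self.mf_eco_upper):
            raise ConfigError("ecosystem factor bounds must be positive and ordered")
        object.__setattr__(
            self, "mf_hh", human_health_factor(self.gdp_2018, self.ghp_fraction, self.alpha)
        )
        object.__setattr__(
            self,
            "mf_hh_lower",
            human_health_factor(self.gdp_2018, self.ghp_fraction, self.alpha_lower),
        )
        object.__setattr__(
            self,
            "mf_hh_upper",
            human_health_factor(self.gdp_2018, self.ghp_fraction, self.alpha_upper),
        )

    def triple(self, endpoint: str) -> tuple[float, float, float]:
        """(lower, central, upper) factor for an endpoint."""
        if endpoint == HH:
            return self.mf_hh_lower, self.mf_hh, self.mf_hh_upper
        if endpoint == ECO:
            return self.mf_eco_lower, self.mf_eco, self.mf_eco_upper
        raise ConfigError(f"unknown endpoint {endpoint!r}; expected HH or ECO")


def monetize(impacts: pd.DataFrame, factors: MonetarizationFactors) -> pd.DataFrame:
    """Convert endpoint impacts to costs, appending COMBINED = HH + ECO rows.

    ``impacts`` is tidy with columns including ``endpoint, value`` and
    optionally ``lower``/``upper``; any other columns (country, fbs_group,
    income_group, ...) are treated as identifiers.  Cost bounds pair impact
    bounds with factor bounds: lower = impact_lower * mf_lower, upper =
    impact_upper * mf_upper.
    """
    unknown = set(impacts["endpoint"]) - {HH, ECO}
    if unknown:
        raise ConfigError(f"cannot monetize endpoints {sorted(unknown)}")
    has_bounds = {"lower", "upper"}.issubset(impacts.columns)
    id_cols = [c for c in impacts.columns if c not in ("endpoint", "value", "lower", "upper", "provenance")]

    out = impacts.copy()
    for ep in (HH, ECO):
        lo, mid, up = factors.triple(ep)
        sel = out["endpoint"] == ep
        out.loc[sel, "value"] = out.loc[sel, "value"] * mid
        if has_bounds:
            out.loc[sel, "lower"] = out.loc[sel, "lower"] * lo
            out.loc[sel, "upper"] = out.loc[sel, "upper"] * up
    value_cols = ["value"] + (["lower", "upper"] if has_bounds else [])
    keep = id_cols + ["endpoint"] + value_cols
    out = out[keep]
    combined = out.groupby(id_cols, as_index=False)[value_cols].sum() if id_cols else (
        out[value_cols].sum().to_frame().T
    )
    combined["endpoint"] = COMBINED
    combined = combined[keep]
    return pd.concat([out, combined], ignore_index=True)


def hidden_cost_factor(total_cost: float, fce: float) -> float:
    """Externality cost per dollar of final consumption expenditure.

    Aggregate-level factors must be formed as sum(cost)/sum(fce), not as a
    mean of country ratios.
    """
    if fce <= 0:
        raise DataError("missing or non-positive food expenditure (FCE)")
    return total_cost / fce


def cost_share_of_gdp(total_cost: float, gdp: float) -> float:
    """Externality cost as a percentage of GDP."""
    if gdp <= 0:
        raise DataError("non-positive GDP")
    return 100.0 * total_cost / gdp
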