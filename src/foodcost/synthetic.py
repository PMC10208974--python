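"""Synthetic input worlds with the statistical structure the analysis
assumes, so every pipeline stage is testable without external downloads.

The generator emulates the shape of the study's data sources — food-balance
sheet supply split into domestic and import channels, per-item life-cycle
intensity catalogs with lognormal uncertainty, export weights, an income-
group country registry, disease burden envelopes and relative-risk curves —
without imitating any real country's marginals.  Its structural guarantees:

* animal-sourced food groups have systematically higher per-kcal endpoint
  intensities than plant groups (configurable multiplier, default 2.5,
  echoing the roughly twofold per-kcal externality gap between income
  groups that diet composition produces);
* per-capita calorie totals and ASF calorie shares rise from low- to
  high-income countries;
* every group has at least one global ("GLO") intensity item, and a random
  subset of countries get country-specific items, exercising the
  global-average fallback of the supply accounting;
* intensities are drawn per kcal and converted to per kg through the
  energy-density table, so mass and energy accounting stay consistent.

The generator also records its own analytic accounting of the world it
built (``World.truth``) using plain numpy loops, independent of the pandas
pipeline, so tests can check known-truth recovery exactly.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import defaults
from .defaults import (
    ASF_CLASSES,
    RISK_FACTOR_GROUPS,
    SUBSTITUTE_CLASSES,
    default_classes,
    default_densities,
    default_eat_targets,
    default_rr_models,
)
from .errors import ConfigError
from .lcia import ECO, HH
from .monetize import MonetarizationFactors
from .supply import GLO, INCOME_GROUPS
from .world import World, config_hash

logger = logging.getLogger(__name__)

GWP = "GWP"  # midpoint carried alongside endpoints for GHG reporting

#: z-score of the 97.5th percentile, used to turn a GSD into 95% CI bounds.
_Z95 = 1.959963984540054


@dataclass(frozen=True)
class WorldConfig:
    """Knobs of the synthetic world generator (see module docstring).

    Per-kcal base intensities are calibrated so that a high-income synthetic
    diet lands in the few-thousand-USD/capita/yr externality range once
    monetarized with the default factors.
    """

    seed: int = 0
    n_countries: dict[str, int] = field(
        default_factory=lambda: {"LIC": 5, "LMIC": 5, "UMIC": 5, "HIC": 5}
    )
    kcal_total: dict[str, float] = field(
        default_factory=lambda: {"LIC": 2200.0, "LMIC": 2450.0, "UMIC": 2800.0, "HIC": 3100.0}
    )
    asf_kcal_share: dict[str, float] = field(
        default_factory=lambda: {"LIC": 0.08, "LMIC": 0.14, "UMIC": 0.24, "HIC": 0.32}
    )
    gdp_pc: dict[str, float] = field(
        default_factory=lambda: {"LIC": 2000.0, "LMIC": 6000.0, "UMIC": 15000.0, "HIC": 45000.0}
    )
    fce_pc: dict[str, float] = field(
        default_factory=lambda: {"LIC": 350.0, "LMIC": 700.0, "UMIC": 1300.0, "HIC": 2600.0}
    )
    asf_multiplier: float = 2.5
    substitute_multiplier: float = 1.5
    item_gsd: float = 1.3
    unc_gsd_range: tuple[float, float] = (1.2, 2.0)
    import_share_mean: float = 0.3
    country_item_prob: float = 0.4
    hh_perkcal: float = 6.0e-9    # DALY per kcal, plant-group base
    eco_perkcal: float = 4.0e-11  # species loss per kcal, plant-group base
    gwp_perkcal: float = 1.0e-3   # kg CO2e per kcal, plant-group base
    force_substitute_below_asf: bool = False

    def __post_init__(self) -> None:
        if self.asf_multiplier <= 0 or self.substitute_multiplier <= 0:
            raise ConfigError("intensity multipliers must be > 0")
        if self.item_gsd < 1:
            raise ConfigError("item_gsd must be >= 1")
        if not set(self.n_countries) <= set(INCOME_GROUPS):
            raise ConfigError(f"income groups must be among {INCOME_GROUPS}")
        if not (0 <= self.import_share_mean < 1):
            raise ConfigError("import_share_mean must lie in [0, 1)")


_ASF_KCAL_WEIGHTS = {
    "beef": 0.20, "lamb": 0.05, "pork": 0.18, "poultry": 0.18,
    "eggs": 0.08, "dairy": 0.18, "fish": 0.10, "animal-fat": 0.03,
}
_PLANT_KCAL_WEIGHTS = {
    "wheat": 0.22, "rice": 0.18, "maize": 0.10, "potatoes": 0.05,
    "vegetables": 0.04, "fruits": 0.05, "beans": 0.06, "soybeans": 0.04,
    "nuts": 0.03, "vegetable-oils": 0.12, "sugar": 0.08, "beverages": 0.03,
}
#: groups supplied only through scenario substitution (zero baseline supply)
_SUBSTITUTE_ONLY = ("insects", "meat-alternatives", "milk-alternatives")

_DISEASE_RATE = {"CHD": 0.020, "stroke": 0.015, "cancer": 0.025, "T2D": 0.008}


def _country_codes(cfg: WorldConfig) -> pd.DataFrame:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    prefix = {"LIC": "L", "LMIC": "M", "UMIC": "U", "HIC": "H"}
    rows = []
    for ig in INCOME_GROUPS:
        for i in range(cfg.n_countries.get(ig, 0)):
            code = prefix[ig] + letters[i // 26] + letters[i % 26]
            rows.append({"country": code, "income_group": ig})
    if not rows:
        raise ConfigError("no countries configured")
    return pd.DataFrame(rows)


def generate_world(cfg: WorldConfig | None = None) -> World:
    """Generate a full, validated input bundle, deterministic for a seed."""
    cfg = cfg or WorldConfig()
    rng = np.random.default_rng(int(cfg.seed) & 0x7FFFFFFF)
    classes = default_classes()
    densities = default_densities()
    density = densities.set_index("fbs_group")["kcal_per_kg"]
    cls_of = classes.set_index("fbs_group")["food_class"]
    asf_groups = [g for g, c in cls_of.items() if c in ASF_CLASSES]
    sub_groups = [g for g, c in cls_of.items() if c in SUBSTITUTE_CLASSES]

    countries = _country_codes(cfg)

    # -- registry -----------------------------------------------------------
    reg_rows = []
    for _, row in countries.iterrows():
        ig = row["income_group"]
        reg_rows.append({
            "country": row["country"],
            "income_group": ig,
            "population": float(np.round(rng.lognormal(np.log(1.5e7), 0.8))),
            "gdp_pc": cfg.gdp_pc[ig] * rng.lognormal(0.0, 0.20),
            "fce_pc": cfg.fce_pc[ig] * rng.lognormal(0.0, 0.15),
        })
    registry = pd.DataFrame(reg_rows)

    # -- supply -------------------------------------------------------------
    supply_rows = []
    for _, row in registry.iterrows():
        c, ig = row["country"], row["income_group"]
        total_kcal = cfg.kcal_total[ig] * rng.lognormal(0.0, 0.05)
        asf_share = float(np.clip(cfg.asf_kcal_share[ig] * rng.lognormal(0.0, 0.15), 0.0, 0.8))
        asf_kcal = total_kcal * asf_share
        plant_kcal = total_kcal - asf_kcal
        asf_w = rng.dirichlet(40.0 * np.array(list(_ASF_KCAL_WEIGHTS.values())))
        plant_w = rng.dirichlet(40.0 * np.array(list(_PLANT_KCAL_WEIGHTS.values())))
        kcal_by_group = dict(zip(_ASF_KCAL_WEIGHTS, asf_kcal * asf_w))
        kcal_by_group.update(zip(_PLANT_KCAL_WEIGHTS, plant_kcal * plant_w))
        for g in _SUBSTITUTE_ONLY:
            kcal_by_group[g] = 0.0
        for g, kcal in kcal_by_group.items():
            if cfg.import_share_mean > 0:
                imp_share = float(rng.beta(
                    4.0 * cfg.import_share_mean, 4.0 * (1.0 - cfg.import_share_mean)
                ))
            else:
                imp_share = 0.0
            kg = kcal * 365.0 / float(density[g])
            supply_rows.append({
                "country": c, "fbs_group": g,
                "domestic_kg": kg * (1.0 - imp_share),
                "import_kg": kg * imp_share,
                "energy_kcal": kcal,
            })
    supply = pd.DataFrame(supply_rows)

    # -- intensity catalog (per-kcal draws -> per-kg entries) ---------------
    base_perkcal = {HH: cfg.hh_perkcal, ECO: cfg.eco_perkcal, GWP: cfg.gwp_perkcal}
    sigma_item = float(np.log(cfg.item_gsd))
    all_groups = list(_ASF_KCAL_WEIGHTS) + list(_PLANT_KCAL_WEIGHTS) + list(_SUBSTITUTE_ONLY)
    item_rows = []  # (item, country, group, endpoint, perkcal, gsd)
    for g in all_groups:
        if cls_of[g] in ASF_CLASSES:
            mult = cfg.asf_multiplier
        elif g in _SUBSTITUTE_ONLY:
            mult = cfg.substitute_multiplier
        else:
            mult = 1.0
        holders = [GLO] + [
            c for c in countries["country"] if rng.random() < cfg.country_item_prob
        ]
        for holder in holders:
            item = f"{g}-{holder}"
            gsd = float(rng.uniform(*cfg.unc_gsd_range))
            for ep in (HH, ECO, GWP):
                perkcal = base_perkcal[ep] * mult * float(rng.lognormal(0.0, sigma_item))
                item_rows.append((item, holder, g, ep, perkcal, gsd))
    items = pd.DataFrame(
        item_rows, columns=["item", "country", "fbs_group", "endpoint", "perkcal", "gsd"]
    )

    if cfg.force_substitute_below_asf:
        # construct worlds where every substitute per-kcal intensity sits
        # strictly below every removed (ASF) per-kcal intensity
        for ep in (HH, ECO, GWP):
            sel_ep = items["endpoint"] == ep
            min_asf = items.loc[sel_ep & items["fbs_group"].isin(asf_groups), "perkcal"].min()
            sel_sub = sel_ep & items["fbs_group"].isin(sub_groups)
            max_sub = items.loc[sel_sub, "perkcal"].max()
            if max_sub >= 0.9 * min_asf:
                items.loc[sel_sub, "perkcal"] *= 0.9 * min_asf / max_sub

    catalog = items.copy()
    catalog["value"] = catalog["perkcal"] * catalog["fbs_group"].map(density)
    catalog["lower"] = catalog["value"] / catalog["gsd"] ** _Z95
    catalog["upper"] = catalog["value"] * catalog["gsd"] ** _Z95
    catalog = catalog[
        ["item", "country", "fbs_group", "endpoint", "value", "lower", "upper", "gsd"]
    ]

    # -- export weights -----------------------------------------------------
    weight_rows = []
    for g, tbl in items[items["endpoint"] == HH].groupby("fbs_group"):
        w = rng.dirichlet(np.full(len(tbl), 2.0))
        for item, wi in zip(tbl["item"], w):
            weight_rows.append({"fbs_group": g, "item": item, "weight": float(wi)})
    weights = pd.DataFrame(weight_rows)

    # -- disease burden -----------------------------------------------------
    burden_rows = []
    for _, row in registry.iterrows():
        for d, rate in _DISEASE_RATE.items():
            burden_rows.append({
                "country": row["country"], "disease": d,
                "dalys": rate * row["population"] * float(rng.lognormal(0.0, 0.2)),
            })
    burden = pd.DataFrame(burden_rows)

    truth = _analytic_truth(supply, catalog, weights, density)
    truth["item_perkcal"] = items[["item", "fbs_group", "endpoint", "perkcal"]].copy()

    cfg_dict = dataclasses.asdict(cfg)
    world = World(
        supply=supply,
        catalog=catalog,
        weights=weights,
        registry=registry,
        classes=classes,
        densities=densities,
        eat_targets=default_eat_targets(),
        burden=burden,
        rr_models=default_rr_models(),
        mf=MonetarizationFactors(),
        truth=truth,
        manifest={"seed": cfg.seed, "config": cfg_dict, "config_hash": config_hash(cfg_dict)},
    )
    return world.validate()


def _analytic_truth(
    supply: pd.DataFrame,
    catalog: pd.DataFrame,
    weights: pd.DataFrame,
    density: pd.Series,
) -> dict[str, pd.DataFrame]:
    """Analytic baseline accounting with plain numpy loops.

    Independent of the pandas pipeline: per (country, group, endpoint), the
    domestic channel uses the mean per-kg intensity over the country's own
    items (all group items when none exist) and the import channel the
    export-weighted mean; impacts scale the channels by supply mass.  The
    effective per-kcal intensity divides the annual impact by annual kcal.
    """
    cat = {}
    for (g, ep), tbl in catalog.groupby(["fbs_group", "endpoint"]):
        cat[(g, ep)] = list(zip(tbl["item"], tbl["country"], tbl["value"]))
    w_by_group = {g: dict(zip(t["item"], t["weight"])) for g, t in weights.groupby("fbs_group")}

    impact_rows, perkcal_rows = [], []
    endpoints = sorted(catalog["endpoint"].unique())
    for row in supply.itertuples(index=False):
        kcal_yr = row.energy_kcal * 365.0
        for ep in endpoints:
            entries = cat[(row.fbs_group, ep)]
            own = [v for (_, holder, v) in entries if holder == row.country]
            pool = own if own else [v for (_, _, v) in entries]
            dom_i = float(np.mean(pool))
            w = w_by_group[row.fbs_group]
            wsum = sum(w.values())
            imp_i = sum(w.get(it, 0.0) * v for (it, _, v) in entries) / wsum
            impact = dom_i * row.domestic_kg + imp_i * row.import_kg
            impact_rows.append({
                "country": row.country, "fbs_group": row.fbs_group,
                "endpoint": ep, "value": impact,
            })
            perkcal_rows.append({
                "country": row.country, "fbs_group": row.fbs_group, "endpoint": ep,
                "perkcal": impact / kcal_yr if kcal_yr > 0 else 0.0,
                "kcal_yr": kcal_yr,
            })
    impacts = pd.DataFrame(impact_rows)
    totals = impacts.groupby(["country", "endpoint"], as_index=False)["value"].sum()
    return {
        "impacts": impacts,
        "totals": totals,
        "group_perkcal": pd.DataFrame(perkcal_rows),
    }


def generate_exposures(
    world: World,
    scenario_supply: pd.DataFrame,
    edible_portion: float | None = None,
) -> pd.DataFrame:
    """Mean dietary intake (g/day) per risk factor from a scenario supply.

    Intake of each risk factor is the mapped groups' supply energy divided
    by energy density, times an intake/supply edible-portion factor.  With
    no factor given, supply is used as a direct proxy for intake
    (edible portion 1.0), which overstates intake somewhat; a warning is
    logged.
    """
    if edible_portion is None:
        logger.warning(
            "no edible-portion factor supplied; using supply as a direct proxy for intake"
        )
        edible_portion = 1.0
    density = world.densities.set_index("fbs_group")["kcal_per_kg"]
    rows = []
    s = scenario_supply.set_index(["country", "fbs_group"])["energy_kcal"]
    for country in sorted(scenario_supply["country"].unique()):
        for rf, groups in RISK_FACTOR_GROUPS.items():
            grams = 0.0
            for g in groups:
                kcal = float(s.get((country, g), 0.0))
                if kcal == 0.0:
                    continue  # groups absent from this world contribute nothing
                if g not in density.index:
                    raise ConfigError(f"risk factor {rf!r} maps to unknown group {g!r}")
                grams += kcal / float(density[g]) * 1000.0  # kcal/day -> g/day
            rows.append({
                "country": country, "risk_factor": rf,
                "intake_g": grams * edible_portion,
            })
    return pd.DataFrame(rows)


def fixture_tiny() -> World:
    """A two-country, four-group world with integer intensities.

    All downstream results are hand-computable; the worked-answer table
    lives in ``docs/tiny_world.md``.  Intensity units are stylized (whole
    DALYs / species per kg) so the arithmetic stays mental; the
    monetarization factors are correspondingly tiny (2 USD per DALY,
    1 USD per species unit).
    """
    d = 3650.0  # kcal/kg chosen so kg/yr x 10 = kcal/day
    classes = pd.DataFrame(
        [
            ("wheat", defaults.CEREALS, "grains"),
            ("beans", defaults.WPP, "legumes"),
            ("fruits", defaults.FV, "fruits"),
            ("beef", defaults.RED_MEAT, "red-meat"),
        ],
        columns=["fbs_group", "food_class", "eat_category"],
    )
    densities = pd.DataFrame(
        [("wheat", d), ("beans", d), ("fruits", 365.0), ("beef", d)],
        columns=["fbs_group", "kcal_per_kg"],
    )
    eat_targets = pd.DataFrame(
        [("grains", 2063.0, 1.0), ("legumes", 284.0, 1.0),
         ("fruits", 126.0, 1.0), ("red-meat", 30.0, 1.0)],
        columns=["eat_category", "intake_kcal", "edible_portion"],
    )
    supply = pd.DataFrame(
        [
            ("AAA", "wheat", 40.0, 10.0, 500.0),
            ("AAA", "beans", 10.0, 0.0, 100.0),
            ("AAA", "fruits", 100.0, 0.0, 100.0),
            ("AAA", "beef", 20.0, 10.0, 300.0),
            ("BBB", "wheat", 48.0, 0.0, 480.0),
            ("BBB", "beans", 30.0, 10.0, 400.0),
            ("BBB", "fruits", 80.0, 20.0, 100.0),
            ("BBB", "beef", 2.0, 0.0, 20.0),
        ],
        columns=["country", "fbs_group", "domestic_kg", "import_kg", "energy_kcal"],
    )
    cat_rows = []
    for item, holder, g, hh, eco, gwp in [
        ("beef-GLO1", GLO, "beef", 4.0, 2.0, 30.0),
        ("beef-GLO2", GLO, "beef", 2.0, 2.0, 20.0),
        ("beef-AAA", "AAA", "beef", 3.0, 2.0, 25.0),
        ("beans-GLO", GLO, "beans", 1.0, 1.0, 2.0),
        ("fruits-GLO", GLO, "fruits", 1.0, 0.0, 1.0),
        ("wheat-GLO1", GLO, "wheat", 2.0, 1.0, 3.0),
        ("wheat-GLO2", GLO, "wheat", 0.0, 1.0, 1.0),
    ]:
        for ep, v in ((HH, hh), (ECO, eco), (GWP, gwp)):
            cat_rows.append({
                "item": item, "country": holder, "fbs_group": g, "endpoint": ep,
                "value": v, "lower": v, "upper": v, "gsd": 1.0,
            })
    catalog = pd.DataFrame(cat_rows)
    weights = pd.DataFrame(
        [
            ("beef", "beef-GLO1", 0.75), ("beef", "beef-GLO2", 0.25),
            ("beans", "beans-GLO", 1.0), ("fruits", "fruits-GLO", 1.0),
            ("wheat", "wheat-GLO1", 0.5), ("wheat", "wheat-GLO2", 0.5),
        ],
        columns=["fbs_group", "item", "weight"],
    )
    registry = pd.DataFrame(
        [
            ("AAA", "HIC", 1_000_000.0, 3150.0, 315.0),
            ("BBB", "LIC", 2_000_000.0, 2400.0, 240.0),
        ],
        columns=["country", "income_group", "population", "gdp_pc", "fce_pc"],
    )
    burden = pd.DataFrame(
        [
            ("AAA", "CHD", 1000.0), ("AAA", "stroke", 500.0),
            ("AAA", "cancer", 800.0), ("AAA", "T2D", 300.0),
            ("BBB", "CHD", 2000.0), ("BBB", "stroke", 800.0),
            ("BBB", "cancer", 1500.0), ("BBB", "T2D", 600.0),
        ],
        columns=["country", "disease", "dalys"],
    )
    mf = MonetarizationFactors(
        alpha=1.0, alpha_lower=0.5, alpha_upper=1.5,
        gdp_2018=1.0, ghp_fraction=1.0,
        mf_eco=1.0, mf_eco_lower=0.5, mf_eco_upper=2.0,
    )
    density = densities.set_index("fbs_group")["kcal_per_kg"]
    truth = _analytic_truth(supply, catalog, weights, density)
    world = World(
        supply=supply, catalog=catalog, weights=weights, registry=registry,
        classes=classes, densities=densities, eat_targets=eat_targets,
        burden=burden, rr_models=default_rr_models(), mf=mf, truth=truth,
        manifest={"seed": None, "config": "fixture_tiny", "config_hash": "fixture"},
    )
    return world.validate()
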