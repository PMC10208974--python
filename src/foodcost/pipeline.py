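"""End-to-end orchestration: baseline accounting, scenario comparison and
the production-vs-consumption health comparison.

Each ``run_*`` function consumes a :class:`~foodcost.world.World` bundle
read-only and returns tidy DataFrames; nothing here mutates inputs, so a
report is regenerable bit-identically from the bundle and its manifest.
"""
from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cra import avoided_dalys
from .errors import ConfigError
from .lcia import ECO, HH
from .monetize import COMBINED, monetize
from .scenarios import scenario_suite
from .supply import GLOBAL, compute_impacts, national_totals, per_1000kcal, total_impacts
from .synthetic import GWP, generate_exposures
from .uncertainty import UncertaintySpec, sample_intensities
from .world import World

logger = logging.getLogger(__name__)

MONETIZED_ENDPOINTS = (HH, ECO)


def _country_costs(world: World, supply: pd.DataFrame) -> pd.DataFrame:
    """Per-capita monetized endpoint costs by country (HH, ECO, COMBINED)."""
    impacts = compute_impacts(supply, world.catalog, world.weights, MONETIZED_ENDPOINTS)
    totals = total_impacts(impacts)
    return monetize(totals.drop(columns=["fbs_group"]), world.mf)


def _aggregate(costs_pc: pd.DataFrame, registry: pd.DataFrame):
    national, income, world_row = national_totals(costs_pc, registry)
    return national, income, world_row


def run_baseline(world: World) -> dict[str, pd.DataFrame]:
    """Baseline (current-diet) externality report.

    Returns tidy tables:

    ``impacts``        per-capita country x group x endpoint impacts
    ``costs_pc``       per-capita costs by country and endpoint (+COMBINED)
    ``costs_national`` national totals
    ``costs_income``   income-group totals (partition of the global row)
    ``costs_global``   one row per endpoint
    ``hidden_cost``    externality cost per USD of food expenditure, by
                       country, income group and globally (aggregate level
                       uses sum(cost)/sum(FCE))
    ``per_1000kcal``   combined cost per 1,000 kcal, same levels
    ``gdp_share``      combined national cost as % of GDP
    ``group_shares``   food-group contribution % of combined monetized
                       externalities, per income group and globally
                       (sums to 100 per aggregate)
    """
    impacts = compute_impacts(
        world.supply, world.catalog, world.weights,
        sorted(world.catalog["endpoint"].unique()),
    )
    logger.info("baseline impacts: %d rows (%d global-fallback)",
                len(impacts), int((impacts["provenance"] != "country-specific").sum()))
    costs_pc = _country_costs(world, world.supply)
    national, income, world_row = _aggregate(costs_pc, world.registry)

    reg = world.registry.set_index("country")
    energy = world.supply.groupby("country")["energy_kcal"].sum()

    comb_pc = costs_pc[costs_pc["endpoint"] == COMBINED].set_index("country")["value"]
    comb_nat = national[national["endpoint"] == COMBINED].set_index("country")["value"]

    hidden_rows, kcal_rows, gdp_rows = [], [], []
    for c in comb_pc.index:
        hidden_rows.append({"level": "country", "name": c,
                            "factor": comb_pc[c] / reg.loc[c, "fce_pc"]})
        kcal_rows.append({"level": "country", "name": c,
                          "cost_per_1000kcal": per_1000kcal(comb_pc[c], energy[c])})
        gdp_rows.append({"level": "country", "name": c,
                         "pct_gdp": 100.0 * comb_pc[c] / reg.loc[c, "gdp_pc"]})
    nat = comb_nat.to_frame("cost").join(reg[["income_group", "population", "fce_pc", "gdp_pc"]])
    nat["fce_nat"] = nat["fce_pc"] * nat["population"]
    nat["gdp_nat"] = nat["gdp_pc"] * nat["population"]
    nat["kcal_yr_nat"] = nat.index.map(energy) * 365.0 * nat["population"]
    by_ig = nat.groupby("income_group")[["cost", "fce_nat", "gdp_nat", "kcal_yr_nat"]].sum()
    for ig, row in by_ig.iterrows():
        hidden_rows.append({"level": "income_group", "name": ig,
                            "factor": row["cost"] / row["fce_nat"]})
        kcal_rows.append({"level": "income_group", "name": ig,
                          "cost_per_1000kcal": row["cost"] / row["kcal_yr_nat"] * 1000.0})
        gdp_rows.append({"level": "income_group", "name": ig,
                         "pct_gdp": 100.0 * row["cost"] / row["gdp_nat"]})
    tot = nat[["cost", "fce_nat", "gdp_nat", "kcal_yr_nat"]].sum()
    hidden_rows.append({"level": "global", "name": GLOBAL,
                        "factor": tot["cost"] / tot["fce_nat"]})
    kcal_rows.append({"level": "global", "name": GLOBAL,
                      "cost_per_1000kcal": tot["cost"] / tot["kcal_yr_nat"] * 1000.0})
    gdp_rows.append({"level": "global", "name": GLOBAL,
                     "pct_gdp": 100.0 * tot["cost"] / tot["gdp_nat"]})

    # food-group contribution shares of combined monetized externalities
    group_costs = monetize(
        impacts[impacts["endpoint"].isin(MONETIZED_ENDPOINTS)][
            ["country", "fbs_group", "endpoint", "value"]
        ],
        world.mf,
    )
    gc = group_costs[group_costs["endpoint"] == COMBINED].merge(
        reg[["income_group", "population"]], left_on="country", right_index=True
    )
    gc["national"] = gc["value"] * gc["population"]
    share_rows = []
    for level, frame in (("income_group", gc.groupby(["income_group", "fbs_group"])),
                         ("global", gc.groupby(["fbs_group"]))):
        sums = frame["national"].sum().reset_index()
        if level == "global":
            sums["income_group"] = GLOBAL
        for name, sub in sums.groupby("income_group"):
            total = sub["national"].sum()
            for _, r in sub.iterrows():
                share_rows.append({
                    "level": level, "name": name, "fbs_group": r["fbs_group"],
                    "share_pct": 100.0 * r["national"] / total,
                })

    return {
        "impacts": impacts,
        "costs_pc": costs_pc,
        "costs_national": national,
        "costs_income": income,
        "costs_global": world_row,
        "hidden_cost": pd.DataFrame(hidden_rows),
        "per_1000kcal": pd.DataFrame(kcal_rows),
        "gdp_share": pd.DataFrame(gdp_rows),
        "group_shares": pd.DataFrame(share_rows),
    }


def build_suite(world: World, names: Sequence[str] | None = None) -> dict[str, pd.DataFrame]:
    """All scenario supply tables (BASE, EAT and the eight substitutions)."""
    from .defaults import default_scenarios

    specs = default_scenarios()
    with_eat = True
    if names is not None:
        valid = {"BASE", "EAT"} | {s.name for s in specs}
        unknown = set(names) - valid
        if unknown:
            raise ConfigError(
                f"unknown scenario names {sorted(unknown)}; valid: {sorted(valid)}"
            )
        specs = [s for s in specs if s.name in names]
        with_eat = "EAT" in names
    return scenario_suite(
        world.supply, specs, world.classes, world.densities,
        eat_targets=world.eat_targets if with_eat else None,
    )


def _global_endpoint_totals(world: World, supply: pd.DataFrame, endpoints) -> pd.DataFrame:
    impacts = compute_impacts(supply, world.catalog, world.weights, endpoints)
    totals = total_impacts(impacts).drop(columns=["fbs_group"])
    _, income, world_row = national_totals(totals, world.registry)
    return income, world_row


def run_scenarios(
    world: World, names: Sequence[str] | None = None
) -> dict[str, pd.DataFrame]:
    """Scenario comparison report against BASE.

    ``savings``     global external-cost saving per scenario (2018 USD,
                    with bounds from impact CIs paired with factor bounds)
    ``savings_income``  the income-group decomposition (sums to global)
    ``ghg``         global GHG (GWP midpoint) percentage reduction vs BASE
    ``energy``      total kcal/capita/day per scenario and country
    """
    suite = build_suite(world, names)
    base_costs = _country_costs(world, suite["BASE"])
    base_nat, base_income, base_glob = _aggregate(base_costs, world.registry)

    has_gwp = GWP in set(world.catalog["endpoint"])
    if has_gwp:
        base_gwp_income, base_gwp = _global_endpoint_totals(world, suite["BASE"], [GWP])

    sav_rows, ig_rows, ghg_rows, energy_frames = [], [], [], []
    for name, supply in suite.items():
        energy = supply.groupby("country", as_index=False)["energy_kcal"].sum()
        energy.insert(0, "scenario", name)
        energy_frames.append(energy)
        if name == "BASE":
            continue
        costs = _country_costs(world, supply)
        nat, income, glob = _aggregate(costs, world.registry)

        for frame_base, frame_s, rows, keys in (
            (base_glob, glob, sav_rows, ["endpoint"]),
            (base_income, income, ig_rows, ["income_group", "endpoint"]),
        ):
            b = frame_base.set_index(keys)
            s = frame_s.set_index(keys)
            for idx in b.index:
                d_val = b.loc[idx, "value"] - s.loc[idx, "value"]
                d_lo, d_hi = sorted((
                    b.loc[idx, "lower"] - s.loc[idx, "lower"],
                    b.loc[idx, "upper"] - s.loc[idx, "upper"],
                ))
                rec = dict(zip(keys, idx if isinstance(idx, tuple) else (idx,)))
                rec.update({"scenario": name, "saving": d_val,
                            "lower": d_lo, "upper": d_hi})
                rows.append(rec)
        if has_gwp:
            _, gwp_glob = _global_endpoint_totals(world, supply, [GWP])
            b = float(base_gwp.loc[base_gwp["endpoint"] == GWP, "value"].iloc[0])
            s = float(gwp_glob.loc[gwp_glob["endpoint"] == GWP, "value"].iloc[0])
            ghg_rows.append({"scenario": name, "reduction_pct": 100.0 * (1.0 - s / b)})

    return {
        "savings": pd.DataFrame(sav_rows),
        "savings_income": pd.DataFrame(ig_rows),
        "ghg": pd.DataFrame(ghg_rows),
        "energy": pd.concat(energy_frames, ignore_index=True),
    }


def run_cra(
    world: World,
    names: Sequence[str] | None = None,
    edible_portion: float | None = None,
) -> pd.DataFrame:
    """Production- vs consumption-related avoided DALYs per scenario.

    Production-related avoided DALYs are the change in the global human-
    health endpoint impact (in DALYs) of food production; consumption-
    related avoided DALYs come from the comparative risk assessment of
    intake changes.  The two are reported side by side (total = production
    + consumption) and never mixed into the monetary accounting.  Bounds:
    production from intensity CIs, consumption from RR CIs, totals sum the
    bounds column-wise.
    """
    suite = build_suite(world, names)
    base_supply = suite["BASE"]
    _, base_glob = _global_endpoint_totals(world, base_supply, [HH])
    base_exp = generate_exposures(world, base_supply, edible_portion)
    base_hh = base_glob.set_index("endpoint").loc[HH]

    rows = []
    for name, supply in suite.items():
        if name == "BASE":
            continue
        _, glob = _global_endpoint_totals(world, supply, [HH])
        hh = glob.set_index("endpoint").loc[HH]
        prod = float(base_hh["value"] - hh["value"])
        prod_lo, prod_hi = sorted((
            float(base_hh["lower"] - hh["lower"]),
            float(base_hh["upper"] - hh["upper"]),
        ))
        cons = avoided_dalys(
            base_exp, generate_exposures(world, supply, edible_portion),
            world.rr_models, world.burden,
        )
        rows.append({
            "scenario": name,
            "total": prod + cons["value"],
            "total_lower": prod_lo + cons["lower"],
            "total_upper": prod_hi + cons["upper"],
            "production": prod, "production_lower": prod_lo, "production_upper": prod_hi,
            "consumption": cons["value"],
            "consumption_lower": cons["lower"], "consumption_upper": cons["upper"],
        })
    return pd.DataFrame(rows)


def mc_cost_bounds(
    world: World, spec: UncertaintySpec
) -> pd.DataFrame:
    """Monte-Carlo 95% CI on global combined external cost.

    Re-runs the full baseline cost accounting on perturbed intensity
    catalogs (lognormal, median 1) and percentiles the aggregate; the
    monetarization-factor range is then applied to the impact bounds as in
    the deterministic path.
    """
    from .uncertainty import propagate

    def closure(catalog: pd.DataFrame) -> pd.Series:
        impacts = compute_impacts(
            world.supply, catalog, world.weights, MONETIZED_ENDPOINTS, with_bounds=False
        )
        totals = total_impacts(impacts).drop(columns=["fbs_group"])
        _, _, glob = national_totals(totals, world.registry)
        return glob.set_index("endpoint")["value"]

    impact_ci = propagate(closure, world.catalog, spec)
    out = impact_ci.copy()
    for ep in MONETIZED_ENDPOINTS:
        lo, mid, up = world.mf.triple(ep)
        out.loc[ep, "value"] *= mid
        out.loc[ep, "lower"] *= lo
        out.loc[ep, "upper"] *= up
    combined = out.sum()
    combined.name = COMBINED
    return pd.concat([out, combined.to_frame().T])
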