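"""National supply accounting: from per-kg item intensities to per-capita
country x food-group x endpoint impacts.

The accounting is consumption-based: impacts of imported food accrue to the
importing country.  For each country c, food-balance-sheet group g and
endpoint e,

    Impact[c, g, e] = i_dom[c, g, e] * domestic_kg[c, g]
                      + i_star[g, e] * import_kg[c, g]

where ``i_dom`` is the unweighted arithmetic mean of per-kg endpoint
intensities over the country-specific food items of the group when any
exist, otherwise over all items of the group (global-average fallback), and
``i_star`` is the global export-weighted average intensity of the group's
items.  Country totals sum the groups; national, income-group and global
aggregates scale per-capita results by population.

Impact bounds propagate the catalog's per-item lower/upper intensity bounds
through the same linear combination.
"""
from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

#: Pseudo-group label for country totals.
TOTAL = "TOTAL"
#: Pseudo-country label for global aggregates.
GLOBAL = "GLOBAL"
GLO = "GLO"

INCOME_GROUPS = ("LIC", "LMIC", "UMIC", "HIC")

COUNTRY_SPECIFIC = "country-specific"
GLOBAL_FALLBACK = "global-fallback"

SUPPLY_COLS = ["country", "fbs_group", "domestic_kg", "import_kg", "energy_kcal"]
REGISTRY_COLS = ["country", "income_group", "population", "gdp_pc", "fce_pc"]
WEIGHTS_COLS = ["fbs_group", "item", "weight"]


def validate_supply(supply: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SUPPLY_COLS if c not in supply.columns]
    if missing:
        raise DataError(f"supply table missing columns: {missing}")
    for col in ("domestic_kg", "import_kg", "energy_kcal"):
        bad = supply.index[supply[col] < 0]
        if len(bad):
            raise DataError(f"supply column {col!r} negative at rows {list(bad[:5])}")
    dup = supply.duplicated(subset=["country", "fbs_group"])
    if dup.any():
        rows = supply.loc[dup, ["country", "fbs_group"]].head().to_dict("records")
        raise DataError(f"duplicate (country, fbs_group) rows in supply: {rows}")
    return supply


def validate_registry(registry: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REGISTRY_COLS if c not in registry.columns]
    if missing:
        raise DataError(f"country registry missing columns: {missing}")
    bad = registry.index[registry["population"] <= 0]
    if len(bad):
        raise DataError(f"non-positive population at rows {list(bad[:5])}")
    unknown = set(registry["income_group"]) - set(INCOME_GROUPS)
    if unknown:
        raise DataError(f"unknown income groups {sorted(unknown)}; expected {INCOME_GROUPS}")
    return registry


def normalize_weights(weights: pd.DataFrame) -> pd.DataFrame:
    """Normalize export weights to sum to 1 within each group."""
    missing = [c for c in WEIGHTS_COLS if c not in weights.columns]
    if missing:
        raise DataError(f"export weights missing columns: {missing}")
    if (weights["weight"] < 0).any():
        raise DataError("export weights must be >= 0")
    totals = weights.groupby("fbs_group")["weight"].transform("sum")
    zero = weights.loc[totals == 0, "fbs_group"].unique()
    if len(zero):
        raise DataError(f"all-zero export weights for groups: {sorted(zero)}")
    out = weights.copy()
    out["weight"] = out["weight"] / totals
    return out


def domestic_intensity(
    catalog: pd.DataFrame, country: str, group: str, endpoint: str
) -> tuple[float, str]:
    """Per-kg intensity for domestically produced supply of one group.

    Returns ``(intensity, provenance)`` where provenance is
    ``"country-specific"`` when country-specific items exist for the group
    and ``"global-fallback"`` otherwise (unweighted mean over all items of
    the group in both cases, per-item-set respectively).
    """
    rows = catalog[(catalog["fbs_group"] == group) & (catalog["endpoint"] == endpoint)]
    if rows.empty:
        raise DataError(f"no items anywhere for group {group!r} / endpoint {endpoint!r}")
    own = rows[rows["country"] == country]
    if len(own):
        return float(own["value"].mean()), COUNTRY_SPECIFIC
    return float(rows["value"].mean()), GLOBAL_FALLBACK


def import_intensity(
    catalog: pd.DataFrame, weights: pd.DataFrame, group: str, endpoint: str
) -> float:
    """Global export-weighted average per-kg intensity of a group."""
    w = normalize_weights(weights)
    w = w[w["fbs_group"] == group]
    if w.empty:
        raise DataError(f"no export weights for group {group!r}")
    rows = catalog[(catalog["fbs_group"] == group) & (catalog["endpoint"] == endpoint)]
    merged = w.merge(rows[["item", "value"]], on="item", how="inner")
    if merged.empty:
        raise DataError(f"no weighted items with intensities for group {group!r}")
    return float((merged["weight"] * merged["value"]).sum() / merged["weight"].sum())


def group_impact(
    supply: pd.DataFrame,
    catalog: pd.DataFrame,
    weights: pd.DataFrame,
    country: str,
    group: str,
    endpoint: str,
) -> float:
    """Per-capita impact of one (country, group, endpoint) cell."""
    row = supply[(supply["country"] == country) & (supply["fbs_group"] == group)]
    if row.empty:
        raise DataError(f"no supply row for ({country!r}, {group!r})")
    dom_i, _ = domestic_intensity(catalog, country, group, endpoint)
    imp_i = import_intensity(catalog, weights, group, endpoint)
    r = row.iloc[0]
    return dom_i * float(r["domestic_kg"]) + imp_i * float(r["import_kg"])


def _intensity_tables(
    catalog: pd.DataFrame, weights: pd.DataFrame, value_col: str
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Vectorized helpers: country-specific means, global means, export-weighted means."""
    spec = (
        catalog[catalog["country"] != GLO]
        .groupby(["country", "fbs_group", "endpoint"], as_index=False)[value_col]
        .mean()
        .rename(columns={value_col: "i_spec"})
    )
    glob = (
        catalog.groupby(["fbs_group", "endpoint"], as_index=False)[value_col]
        .mean()
        .rename(columns={value_col: "i_glob"})
    )
    w = normalize_weights(weights)
    merged = w.merge(
        catalog[["item", "endpoint", value_col]], on="item", how="inner"
    )
    merged["wi"] = merged["weight"] * merged[value_col]
    star = (
        merged.groupby(["fbs_group", "endpoint"], as_index=False)
        .agg(wi=("wi", "sum"), wsum=("weight", "sum"))
    )
    star["i_star"] = star["wi"] / star["wsum"]
    return spec, glob, star[["fbs_group", "endpoint", "i_star"]]


def compute_impacts(
    supply: pd.DataFrame,
    catalog: pd.DataFrame,
    weights: pd.DataFrame,
    endpoints: Iterable[str] | None = None,
    *,
    with_bounds: bool = True,
) -> pd.DataFrame:
    """Per-capita impacts for every (country, group, endpoint).

    Returns a tidy frame ``country, fbs_group, endpoint, value, lower,
    upper, provenance``.  Bounds come from pushing the catalog's per-item
    95% CI bounds through the same linear accounting; drop them with
    ``with_bounds=False``.
    """
    validate_supply(supply)
    if endpoints is None:
        endpoints = sorted(catalog["endpoint"].unique())
    endpoints = list(endpoints)

    cat = catalog[catalog["endpoint"].isin(endpoints)]
    groups_needed = set(supply["fbs_group"])
    have = set(cat["fbs_group"])
    missing = groups_needed - have
    if missing:
        raise DataError(f"groups with zero items anywhere: {sorted(missing)}")

    base = supply.merge(pd.DataFrame({"endpoint": endpoints}), how="cross")
    frames = {}
    for col, label in (("value", "value"), ("lower", "lower"), ("upper", "upper")):
        if not with_bounds and col != "value":
            continue
        spec, glob, star = _intensity_tables(cat, weights, col)
        m = base.merge(spec, on=["country", "fbs_group", "endpoint"], how="left")
        m = m.merge(glob, on=["fbs_group", "endpoint"], how="left")
        m = m.merge(star, on=["fbs_group", "endpoint"], how="left")
        if m["i_star"].isna().any():
            bad = sorted(m.loc[m["i_star"].isna(), "fbs_group"].unique())
            raise DataError(f"no export-weighted intensity for groups: {bad}")
        dom_i = m["i_spec"].fillna(m["i_glob"])
        m[label] = dom_i * m["domestic_kg"] + m["i_star"] * m["import_kg"]
        if col == "value":
            m["provenance"] = np.where(
                m["i_spec"].notna(), COUNTRY_SPECIFIC, GLOBAL_FALLBACK
            )
            frames["provenance"] = m["provenance"]
            frames["keys"] = m[["country", "fbs_group", "endpoint"]]
        frames[label] = m[label]

    out = frames["keys"].copy()
    out["value"] = frames["value"]
    if with_bounds:
        out["lower"] = frames["lower"]
        out["upper"] = frames["upper"]
    out["provenance"] = frames["provenance"]
    return out


def total_impacts(impacts: pd.DataFrame) -> pd.DataFrame:
    """Country totals over groups; returned with ``fbs_group == TOTAL``."""
    value_cols = [c for c in ("value", "lower", "upper") if c in impacts.columns]
    out = (
        impacts.groupby(["country", "endpoint"], as_index=False)[value_cols].sum()
    )
    out.insert(1, "fbs_group", TOTAL)
    return out


def national_totals(
    per_capita: pd.DataFrame, registry: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Scale per-capita results to national, income-group and global totals.

    ``per_capita`` must carry columns ``country, endpoint, value`` (and
    optionally ``lower``/``upper``).  Returns ``(national, income, world)``
    where income groups partition the countries, so the four income-group
    rows sum to the global row per endpoint.
    """
    validate_registry(registry)
    unknown = set(per_capita["country"]) - set(registry["country"])
    if unknown:
        raise DataError(f"countries missing from registry: {sorted(unknown)}")
    value_cols = [c for c in ("value", "lower", "upper") if c in per_capita.columns]
    m = per_capita.merge(registry[["country", "income_group", "population"]], on="country")
    national = m.copy()
    for c in value_cols:
        national[c] = national[c] * national["population"]
    keep = ["country", "income_group", "endpoint"] + value_cols
    national = national[keep]
    income = (
        national.groupby(["income_group", "endpoint"], as_index=False)[value_cols].sum()
    )
    world = national.groupby(["endpoint"], as_index=False)[value_cols].sum()
    world.insert(0, "country", GLOBAL)
    return national, income, world


def per_1000kcal(annual_value: float, energy_kcal_day: float) -> float:
    """Convert an annual per-capita quantity to a per-1,000-kcal rate.

    ``annual_value / (energy_kcal_day * 365) * 1000``; zero daily energy is
    an error.
    """
    if energy_kcal_day <= 0:
        raise DataError("per-1000-kcal metric undefined for non-positive energy")
    return annual_value / (energy_kcal_day * 365.0) * 1000.0
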