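"""Life-cycle impact assessment core.

Converts life-cycle inventory (LCI) flows of food items into midpoint
environmental impact intensities (per kg of food), and midpoints into
endpoint (externality) intensities via damage-pathway characterization
factors:

    midpoint intensity of item f, category m:
        i_IMP[f, m] = sum_j  LCI[f, j] * CF_IMP[j, m]

    endpoint intensity of item f, endpoint e:
        i_EXT[f, e] = sum_m  i_IMP[f, m] * CF_EXT[m, e]

Both steps are linear; the endpoint intensity of an item is the cumulative
damage over all of its midpoint impacts.  Characterization factors are
consumed as plain tables — the cause-effect models behind them (e.g. the
ReCiPe2016 hierarchic perspective) are upstream of this package.  The
system boundary (cradle-to-gate) is implicit in the inventories supplied;
no retail or use stage is ever modelled here.

Endpoint identifiers are free-form, but the pipeline's fixed vocabulary is
``HH`` (human health, DALY per kg) and ``ECO`` (ecosystem quality, species
loss per kg).  Midpoints with no endpoint link legally contribute zero.
"""
from __future__ import annotations

import logging

import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

#: Endpoint vocabulary used by the monetarization stage.
HH = "HH"
ECO = "ECO"
ENDPOINTS = (HH, ECO)

INVENTORY_COLS = ["item", "flow", "amount"]
MIDPOINT_CF_COLS = ["flow", "midpoint", "factor"]
ENDPOINT_CF_COLS = ["midpoint", "endpoint", "factor"]


def validate_inventory(inventory: pd.DataFrame) -> pd.DataFrame:
    """Check an InventoryTable: finite amounts, unique (item, flow) pairs."""
    missing = [c for c in INVENTORY_COLS if c not in inventory.columns]
    if missing:
        raise DataError(f"inventory table missing columns: {missing}")
    amounts = pd.to_numeric(inventory["amount"], errors="coerce")
    bad = inventory.index[~amounts.notna() | ~amounts.abs().lt(float("inf"))]
    if len(bad):
        raise DataError(f"inventory amounts not finite at rows {list(bad[:5])}")
    dup = inventory.duplicated(subset=["item", "flow"])
    if dup.any():
        rows = inventory.loc[dup, ["item", "flow"]].head().to_dict("records")
        raise DataError(f"duplicate (item, flow) pairs in inventory: {rows}")
    return inventory


def validate_cf(cf: pd.DataFrame, key_cols: list[str]) -> pd.DataFrame:
    """Check a characterization-factor table for finiteness and uniqueness."""
    missing = [c for c in key_cols + ["factor"] if c not in cf.columns]
    if missing:
        raise DataError(f"CF table missing columns: {missing}")
    factors = pd.to_numeric(cf["factor"], errors="coerce")
    bad = cf.index[~factors.notna() | ~factors.abs().lt(float("inf"))]
    if len(bad):
        raise DataError(f"CF factors not finite at rows {list(bad[:5])}")
    dup = cf.duplicated(subset=key_cols)
    if dup.any():
        rows = cf.loc[dup, key_cols].head().to_dict("records")
        raise DataError(f"duplicate {tuple(key_cols)} pairs in CF table: {rows}")
    return cf


def midpoint_from_inventory(
    inventory: pd.DataFrame,
    cf: pd.DataFrame,
    *,
    strict: bool = True,
) -> pd.DataFrame:
    """Convert inventory flows to per-item midpoint intensities.

    Parameters
    ----------
    inventory
        Columns ``item, flow, amount`` — amount of elementary flow per kg of
        the food item.
    cf
        Columns ``flow, midpoint, factor`` — unit midpoint impact per unit
        flow.
    strict
        If True, an inventory flow absent from ``cf`` raises
        :class:`~foodcost.errors.DataError` naming the flow; if False such
        flows are logged and skipped (real LCI dialects differ in flow
        nomenclature).

    Returns
    -------
    DataFrame with columns ``item, midpoint, value`` — one row per (item,
    midpoint) pair with a nonzero-support contribution.  Items absent from
    the inventory yield no rows.
    """
    validate_inventory(inventory)
    validate_cf(cf, ["flow", "midpoint"])
    if inventory.empty:
        return pd.DataFrame(columns=["item", "midpoint", "value"])

    known = set(cf["flow"])
    unknown = sorted(set(inventory["flow"]) - known)
    if unknown:
        if strict:
            raise DataError(f"inventory flows not present in midpoint CF table: {unknown}")
        logger.warning("skipping %d unknown flows: %s", len(unknown), unknown)
        inventory = inventory[inventory["flow"].isin(known)]

    merged = inventory.merge(cf, on="flow", how="inner")
    merged["value"] = merged["amount"] * merged["factor"]
    out = (
        merged.groupby(["item", "midpoint"], as_index=False, sort=True)["value"]
        .sum()
    )
    return out


def endpoint_from_midpoint(midpoints: pd.DataFrame, cf: pd.DataFrame) -> pd.DataFrame:
    """Translate per-item midpoint intensities into endpoint intensities.

    ``midpoints`` has columns ``item, midpoint, value``; ``cf`` has columns
    ``midpoint, endpoint, factor`` with factors >= 0.  Midpoints without an
    endpoint link contribute zero (this is legal, not an error).  Items with
    no linked midpoint at all are still reported, with zero at every
    endpoint present in ``cf`` — the cumulative damage of an unlinked
    inventory is zero, not undefined.

    Returns a DataFrame ``item, endpoint, value``.
    """
    validate_cf(cf, ["midpoint", "endpoint"])
    if (cf["factor"] < 0).any():
        raise DataError("endpoint CF factors must be >= 0")
    if midpoints.empty:
        return pd.DataFrame(columns=["item", "endpoint", "value"])

    endpoints = sorted(cf["endpoint"].unique())
    merged = midpoints.merge(cf, on="midpoint", how="inner")
    merged["value"] = merged["value"] * merged["factor"]
    contrib = (
        merged.groupby(["item", "endpoint"], as_index=False, sort=True)["value"].sum()
    )
    # items whose midpoints all lack links still get explicit zero rows
    full = pd.MultiIndex.from_product(
        [sorted(midpoints["item"].unique()), endpoints], names=["item", "endpoint"]
    )
    out = (
        contrib.set_index(["item", "endpoint"])
        .reindex(full, fill_value=0.0)
        .reset_index()
    )
    return out


def intensities_from_inventory(
    inventory: pd.DataFrame,
    midpoint_cf: pd.DataFrame,
    endpoint_cf: pd.DataFrame,
    *,
    strict: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run both LCIA stages; returns (midpoint, endpoint) intensity tables."""
    mid = midpoint_from_inventory(inventory, midpoint_cf, strict=strict)
    end = endpoint_from_midpoint(mid, endpoint_cf)
    return mid, end


def validate_catalog(catalog: pd.DataFrame) -> pd.DataFrame:
    """Check an IntensityCatalog (long format).

    Required columns: ``item, country, fbs_group, endpoint, value, lower,
    upper``.  ``country`` is an ISO-3166 alpha-3 code or ``GLO`` for global
    (non-country-specific) items.  Bounds must satisfy lower <= value <=
    upper row-wise.
    """
    required = ["item", "country", "fbs_group", "endpoint", "value", "lower", "upper"]
    missing = [c for c in required if c not in catalog.columns]
    if missing:
        raise DataError(f"intensity catalog missing columns: {missing}")
    bad = catalog.index[
        (catalog["lower"] > catalog["value"]) | (catalog["value"] > catalog["upper"])
    ]
    if len(bad):
        raise DataError(f"catalog bounds not ordered (lower <= value <= upper) at rows {list(bad[:5])}")
    dup = catalog.duplicated(subset=["item", "endpoint"])
    if dup.any():
        rows = catalog.loc[dup, ["item", "endpoint"]].head().to_dict("records")
        raise DataError(f"duplicate (item, endpoint) rows in catalog: {rows}")
    return catalog
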