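"""Dietary-change scenario engine.

Transforms a baseline per-capita supply table into counterfactual diets by
removing animal-sourced food (ASF) classes and redistributing the lost
calories to substitute classes under calorie-basis substitution rules,
e.g. "no red meat": remove beef, lamb and pork, replace 2/3 of the lost
calories with whole-food plant protein (beans, legumes, soybeans) and 1/3
with fruits and vegetables.  Variants route part of the calories to insects
or to processed plant-based meat/milk alternatives.

Rules enforced throughout:

* calorie conservation — total kcal per capita per day is identical to the
  baseline for every non-EAT scenario;
* within a substitute class, added calories are distributed across the
  class's constituent food groups in proportion to their baseline supply
  (uniformly when the whole class has zero baseline supply, logged);
* added calories are converted to mass via per-group energy densities and
  split between domestic and import channels at the baseline ratio, so the
  constant import/domestic proportion assumption holds by construction;
* impact intensities are never touched — no supply-side feedback.

The EAT reference diet is handled separately: per-capita supply is rescaled
per food category so that intake (supply x edible portion) matches the
category targets, preserving within-category group proportions, for a total
modelled intake of 2,503 kcal per day.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigError, DataError
from .supply import validate_supply

logger = logging.getLogger(__name__)

#: Total daily energy of the EAT reference intake pattern (kcal/capita/day).
EAT_TOTAL_KCAL = 2503.0

CLASSES_COLS = ["fbs_group", "food_class", "eat_category"]
DENSITY_COLS = ["fbs_group", "kcal_per_kg"]
EAT_TARGET_COLS = ["eat_category", "intake_kcal", "edible_portion"]


@dataclass(frozen=True)
class ScenarioSpec:
    """One dietary-change scenario.

    ``removed_classes`` are food-class labels whose groups are zeroed;
    ``shares`` maps substitute class -> calorie fraction of the removed
    total.  ``routed_share`` is an additional fraction distributed by
    *source* class: calories removed from source class s go to
    ``routing[s]`` (falling back to ``routing['default']``), which is how
    the vegan-with-processed-substitutes diet sends dairy calories to milk
    alternatives and meat/seafood/egg calories to meat alternatives.
    Fractions (shares plus routed_share) must sum to 1.
    """

    name: str
    removed_classes: frozenset[str] = frozenset()
    shares: dict[str, float] = field(default_factory=dict)
    routed_share: float = 0.0
    routing: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.shares.values()) or self.routed_share < 0:
            raise ConfigError(f"scenario {self.name!r}: substitution shares must be >= 0")
        total = sum(self.shares.values()) + self.routed_share
        if self.removed_classes and abs(total - 1.0) > 1e-9:
            raise ConfigError(
                f"scenario {self.name!r}: substitution shares sum to {total}, not 1"
            )
        if self.routed_share > 0 and "default" not in self.routing:
            raise ConfigError(f"scenario {self.name!r}: routing needs a 'default' entry")
        subs = set(self.shares) | set(self.routing.values())
        overlap = subs & self.removed_classes
        if overlap:
            raise ConfigError(
                f"scenario {self.name!r}: classes {sorted(overlap)} both removed and substitute"
            )


def validate_classes(classes: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CLASSES_COLS if c not in classes.columns]
    if missing:
        raise DataError(f"class roster missing columns: {missing}")
    dup = classes.duplicated(subset=["fbs_group"])
    if dup.any():
        raise DataError(
            f"groups mapped to multiple classes: {sorted(classes.loc[dup, 'fbs_group'])}"
        )
    return classes


def validate_densities(densities: pd.DataFrame, groups: set[str]) -> pd.DataFrame:
    missing = [c for c in DENSITY_COLS if c not in densities.columns]
    if missing:
        raise DataError(f"energy-density table missing columns: {missing}")
    if (densities["kcal_per_kg"] <= 0).any():
        raise DataError("energy densities must be > 0")
    absent = groups - set(densities["fbs_group"])
    if absent:
        raise DataError(f"energy density missing for groups: {sorted(absent)}")
    return densities


def validate_eat_targets(
    targets: pd.DataFrame, total_kcal: float | None = EAT_TOTAL_KCAL
) -> pd.DataFrame:
    missing = [c for c in EAT_TARGET_COLS if c not in targets.columns]
    if missing:
        raise DataError(f"EAT target table missing columns: {missing}")
    if (targets["intake_kcal"] < 0).any():
        raise DataError("EAT intake targets must be >= 0")
    if ((targets["edible_portion"] <= 0) | (targets["edible_portion"] > 1)).any():
        raise DataError("edible portion factors must lie in (0, 1]")
    if total_kcal is not None:
        got = float(targets["intake_kcal"].sum())
        if abs(got - total_kcal) > 1e-6:
            raise DataError(f"EAT intake targets sum to {got}, expected {total_kcal}")
    return targets


def _class_groups(classes: pd.DataFrame, cls: str) -> list[str]:
    return sorted(classes.loc[classes["food_class"] == cls, "fbs_group"])


def build_standard_scenario(
    base: pd.DataFrame,
    spec: ScenarioSpec,
    classes: pd.DataFrame,
    densities: pd.DataFrame,
) -> pd.DataFrame:
    """Apply a removal-and-substitution scenario to a baseline supply table.

    Returns a new supply table with identical total kcal per capita per day
    for every country.  A spec removing nothing returns the baseline
    unchanged.
    """
    validate_supply(base)
    validate_classes(classes)
    if not spec.removed_classes:
        return base.copy()
    density = validate_densities(densities, set(base["fbs_group"])).set_index("fbs_group")[
        "kcal_per_kg"
    ]
    cls_of = classes.set_index("fbs_group")["food_class"]

    sub_classes = set(spec.shares) | set(spec.routing.values())
    for cls in sub_classes:
        if not _class_groups(classes, cls):
            raise ConfigError(
                f"scenario {spec.name!r}: substitute class {cls!r} has no food groups"
            )

    out_frames = []
    for country, tbl in base.groupby("country", sort=False):
        tbl = tbl.set_index("fbs_group")
        group_cls = cls_of.reindex(tbl.index)
        removed_mask = group_cls.isin(spec.removed_classes)
        removed_kcal_by_class = (
            tbl.loc[removed_mask, "energy_kcal"].groupby(group_cls[removed_mask]).sum()
        )
        total_removed = float(removed_kcal_by_class.sum())

        new = tbl.copy()
        new.loc[removed_mask, ["domestic_kg", "import_kg", "energy_kcal"]] = 0.0

        # calorie allotment per substitute class
        added = {cls: share * total_removed for cls, share in spec.shares.items()}
        if spec.routed_share > 0:
            for src, kcal in removed_kcal_by_class.items():
                dest = spec.routing.get(src, spec.routing["default"])
                added[dest] = added.get(dest, 0.0) + spec.routed_share * float(kcal)

        for cls, kcal_add in added.items():
            if kcal_add == 0.0:
                continue
            groups = _class_groups(classes, cls)
            present = [g for g in groups if g in new.index]
            base_kcal = tbl.loc[present, "energy_kcal"] if present else pd.Series(dtype=float)
            if float(base_kcal.sum()) > 0:
                weights = base_kcal / base_kcal.sum()
            else:
                logger.info(
                    "scenario %s, country %s: class %r has zero baseline supply; "
                    "splitting uniformly over %d groups",
                    spec.name, country, cls, len(groups),
                )
                for g in groups:
                    if g not in new.index:
                        new.loc[g] = {"country": country, "domestic_kg": 0.0,
                                      "import_kg": 0.0, "energy_kcal": 0.0}
                weights = pd.Series(1.0 / len(groups), index=groups)
            for g, w in weights.items():
                kcal_g = kcal_add * float(w)
                if g not in density.index:
                    raise DataError(f"energy density missing for group {g!r}")
                kg_g = kcal_g * 365.0 / float(density[g])
                dom = float(tbl.loc[g, "domestic_kg"]) if g in tbl.index else 0.0
                imp = float(tbl.loc[g, "import_kg"]) if g in tbl.index else 0.0
                dom_frac = dom / (dom + imp) if (dom + imp) > 0 else 1.0
                new.loc[g, "domestic_kg"] += kg_g * dom_frac
                new.loc[g, "import_kg"] += kg_g * (1.0 - dom_frac)
                new.loc[g, "energy_kcal"] += kcal_g
        new["country"] = country
        out_frames.append(new.reset_index())

    out = pd.concat(out_frames, ignore_index=True)
    return out[["country", "fbs_group", "domestic_kg", "import_kg", "energy_kcal"]]


def build_eat_scenario(
    base: pd.DataFrame,
    targets: pd.DataFrame,
    classes: pd.DataFrame,
    densities: pd.DataFrame,
    *,
    total_kcal: float | None = EAT_TOTAL_KCAL,
) -> pd.DataFrame:
    """Rescale a baseline supply table to the EAT reference intake targets.

    Per food category, supply kcal is scaled so that intake (supply x
    edible portion) hits the category target while preserving the baseline
    proportions of the category's constituent groups.  Categories with zero
    baseline supply but a positive target are filled uniformly over the
    category's registered groups (logged).
    """
    validate_supply(base)
    validate_classes(classes)
    validate_eat_targets(targets, total_kcal)
    density = validate_densities(densities, set(base["fbs_group"])).set_index("fbs_group")[
        "kcal_per_kg"
    ]
    cat_of = classes.set_index("fbs_group")["eat_category"]
    unmapped = set(base["fbs_group"]) - set(cat_of.index)
    if unmapped:
        raise DataError(f"baseline groups not mapped to an EAT category: {sorted(unmapped)}")
    tgt = targets.set_index("eat_category")

    out_frames = []
    for country, tbl in base.groupby("country", sort=False):
        new = tbl.set_index("fbs_group").copy()
        for cat, row in tgt.iterrows():
            groups = sorted(cat_of.index[cat_of == cat])
            present = [g for g in groups if g in new.index]
            ep = float(row["edible_portion"])
            target_supply_kcal = float(row["intake_kcal"]) / ep
            cur = float(new.loc[present, "energy_kcal"].sum()) if present else 0.0
            if cur > 0:
                factor = target_supply_kcal / cur
                new.loc[present, ["domestic_kg", "import_kg", "energy_kcal"]] *= factor
            elif target_supply_kcal > 0:
                if not groups:
                    raise DataError(
                        f"EAT category {cat!r} has a positive target but no registered groups"
                    )
                logger.info(
                    "EAT scenario, country %s: category %r empty at baseline; "
                    "distributing uniformly over %d groups", country, cat, len(groups),
                )
                kcal_g = target_supply_kcal / len(groups)
                for g in groups:
                    if g not in density.index:
                        raise DataError(f"energy density missing for group {g!r}")
                    if g not in new.index:
                        new.loc[g] = {"country": country, "domestic_kg": 0.0,
                                      "import_kg": 0.0, "energy_kcal": 0.0}
                    new.loc[g, "energy_kcal"] += kcal_g
                    new.loc[g, "domestic_kg"] += kcal_g * 365.0 / float(density[g])
        new["country"] = country
        out_frames.append(new.reset_index())
    out = pd.concat(out_frames, ignore_index=True)
    return out[["country", "fbs_group", "domestic_kg", "import_kg", "energy_kcal"]]


def modelled_intake_kcal(
    scenario_supply: pd.DataFrame, targets: pd.DataFrame, classes: pd.DataFrame
) -> pd.DataFrame:
    """Per-country modelled intake (supply kcal x edible portion), by category."""
    cat_of = classes.set_index("fbs_group")["eat_category"]
    ep = targets.set_index("eat_category")["edible_portion"]
    s = scenario_supply.copy()
    s["eat_category"] = s["fbs_group"].map(cat_of)
    s["intake_kcal"] = s["energy_kcal"] * s["eat_category"].map(ep).fillna(1.0)
    return s.groupby(["country", "eat_category"], as_index=False)["intake_kcal"].sum()


def scenario_suite(
    base: pd.DataFrame,
    specs: list[ScenarioSpec],
    classes: pd.DataFrame,
    densities: pd.DataFrame,
    eat_targets: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Build every scenario plus the BASE passthrough.

    Returns an ordered mapping name -> supply table.  Deterministic given
    its inputs; duplicate scenario names are an error.
    """
    names = ["BASE"] + (["EAT"] if eat_targets is not None else []) + [s.name for s in specs]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ConfigError(f"duplicate scenario names: {sorted(dupes)}")
    suite: dict[str, pd.DataFrame] = {"BASE": base.copy()}
    if eat_targets is not None:
        suite["EAT"] = build_eat_scenario(base, eat_targets, classes, densities)
    for spec in specs:
        suite[spec.name] = build_standard_scenario(base, spec, classes, densities)
    return suite
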