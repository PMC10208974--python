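"""Shipped default configuration: food-group roster, energy densities,
scenario definitions, EAT reference targets and relative-risk parameters.

Everything here is editable configuration, not algorithm.  The scenario
suite covers nine diets: the EAT reference pattern plus four progressive
ASF-removal stages (no red meat, pescatarian, vegetarian, vegan) each with
a variant substituting part of the lost calories with insects or processed
plant-based alternatives.  Removal sets are nested:
NRM < PESC < VEG < VGN.

The relative-risk parameters are literature-plausible placeholder values
(see docs/methods.md); any real analysis should substitute the user's own
meta-analytic estimates.
"""
from __future__ import annotations

import pandas as pd

from .scenarios import ScenarioSpec

# ---------------------------------------------------------------------------
# food classes
# ---------------------------------------------------------------------------

RED_MEAT = "red-meat"
POULTRY = "poultry"
SEAFOOD = "seafood"
DAIRY = "dairy"
EGGS = "eggs"
ANIMAL_FAT = "animal-fat"
WPP = "whole-plant-protein"
FV = "fruits-vegetables"
INSECTS = "insects"
MEAT_ALT = "processed-meat-alternatives"
MILK_ALT = "processed-milk-alternatives"
CEREALS = "cereals"
OTHER_PLANT = "other-plant"

ASF_CLASSES = (RED_MEAT, POULTRY, SEAFOOD, DAIRY, EGGS, ANIMAL_FAT)
SUBSTITUTE_CLASSES = (WPP, FV, INSECTS, MEAT_ALT, MILK_ALT)

# fbs_group, food_class, eat_category, kcal_per_kg (edible-supply basis)
_ROSTER = [
    ("wheat", CEREALS, "grains", 3000.0),
    ("rice", CEREALS, "grains", 3600.0),
    ("maize", CEREALS, "grains", 3500.0),
    ("potatoes", OTHER_PLANT, "tubers", 700.0),
    ("vegetables", FV, "vegetables", 250.0),
    ("fruits", FV, "fruits", 500.0),
    ("beans", WPP, "legumes", 3300.0),
    ("soybeans", WPP, "legumes", 4000.0),
    ("nuts", OTHER_PLANT, "nuts", 6000.0),
    ("vegetable-oils", OTHER_PLANT, "added-fats", 8800.0),
    ("sugar", OTHER_PLANT, "added-sugars", 3900.0),
    ("beverages", OTHER_PLANT, "beverages", 300.0),
    ("beef", RED_MEAT, "red-meat", 2500.0),
    ("lamb", RED_MEAT, "red-meat", 2300.0),
    ("pork", RED_MEAT, "red-meat", 2600.0),
    ("poultry", POULTRY, "poultry", 1700.0),
    ("eggs", EGGS, "eggs", 1400.0),
    ("dairy", DAIRY, "dairy", 600.0),
    ("fish", SEAFOOD, "fish", 1100.0),
    ("animal-fat", ANIMAL_FAT, "added-fats", 8000.0),
    ("insects", INSECTS, "other", 2000.0),
    ("meat-alternatives", MEAT_ALT, "other", 1800.0),
    ("milk-alternatives", MILK_ALT, "other", 500.0),
]


def default_classes() -> pd.DataFrame:
    """Food-group roster: group -> scenario class and EAT category."""
    return pd.DataFrame(
        [(g, c, e) for g, c, e, _ in _ROSTER],
        columns=["fbs_group", "food_class", "eat_category"],
    )


def default_densities() -> pd.DataFrame:
    """Energy density per group (kcal per kg, edible-supply basis)."""
    return pd.DataFrame(
        [(g, d) for g, _, _, d in _ROSTER], columns=["fbs_group", "kcal_per_kg"]
    )


# ---------------------------------------------------------------------------
# scenario specifications
# ---------------------------------------------------------------------------

_WHOLE = {WPP: 2.0 / 3.0, FV: 1.0 / 3.0}
_THIRDS = {WPP: 1.0 / 3.0, FV: 1.0 / 3.0}


def default_scenarios() -> list[ScenarioSpec]:
    """The eight removal-and-substitution diets (EAT is built separately)."""
    nrm = frozenset({RED_MEAT})
    pesc = nrm | {POULTRY}
    veg = pesc | {SEAFOOD}
    vgn = veg | {DAIRY, EGGS, ANIMAL_FAT}
    return [
        ScenarioSpec("NRM", nrm, dict(_WHOLE)),
        ScenarioSpec("NRM-I", nrm, {**_THIRDS, INSECTS: 1.0 / 3.0}),
        ScenarioSpec("PESC", pesc, dict(_WHOLE)),
        ScenarioSpec("PESC-I", pesc, {**_THIRDS, INSECTS: 1.0 / 3.0}),
        ScenarioSpec("VEG", veg, dict(_WHOLE)),
        ScenarioSpec("VEG-P", veg, {**_THIRDS, MEAT_ALT: 1.0 / 3.0}),
        ScenarioSpec("VGN", vgn, dict(_WHOLE)),
        ScenarioSpec(
            "VGN-P",
            vgn,
            dict(_THIRDS),
            routed_share=1.0 / 3.0,
            routing={DAIRY: MILK_ALT, "default": MEAT_ALT},
        ),
    ]


# ---------------------------------------------------------------------------
# EAT reference targets (15 categories, 2,503 kcal/day total intake)
# ---------------------------------------------------------------------------

_EAT_TARGETS = [
    # category, intake kcal/day, edible-portion factor (intake -> supply)
    ("grains", 821.0, 0.95),
    ("tubers", 39.0, 0.80),
    ("vegetables", 78.0, 0.85),
    ("fruits", 126.0, 0.77),
    ("dairy", 153.0, 1.00),
    ("red-meat", 30.0, 0.90),
    ("poultry", 62.0, 0.85),
    ("eggs", 19.0, 0.88),
    ("fish", 40.0, 0.85),
    ("legumes", 284.0, 1.00),
    ("nuts", 291.0, 1.00),
    ("added-fats", 414.0, 1.00),
    ("added-sugars", 120.0, 1.00),
    ("beverages", 26.0, 1.00),
    ("other", 0.0, 1.00),
]


def default_eat_targets() -> pd.DataFrame:
    """EAT reference diet aggregated into 15 categories (sum = 2,503 kcal)."""
    return pd.DataFrame(_EAT_TARGETS, columns=["eat_category", "intake_kcal", "edible_portion"])


# ---------------------------------------------------------------------------
# relative-risk parameters (placeholders; flagged in docs/methods.md)
# ---------------------------------------------------------------------------

#: risk factor -> food-class whose intake defines the exposure
RISK_FACTOR_CLASSES = {
    "fruit": FV,          # fruits component handled via group mapping below
    "vegetable": FV,
    "legume": WPP,
    "red-meat": RED_MEAT,
}

#: risk factor -> FBS groups whose supply defines mean intake
RISK_FACTOR_GROUPS = {
    "fruit": ("fruits",),
    "vegetable": ("vegetables",),
    "legume": ("beans", "soybeans"),
    "red-meat": ("beef", "lamb", "pork"),
}

DISEASES = ("CHD", "stroke", "cancer", "T2D")

# (risk_factor, disease, rr, rr_lo, rr_hi, serving g/day, tmrel g/day, direction)
_RR_TABLE = [
    ("fruit", "CHD", 0.93, 0.89, 0.96, 100.0, 250.0, "protective"),
    ("fruit", "stroke", 0.90, 0.84, 0.95, 100.0, 250.0, "protective"),
    ("vegetable", "CHD", 0.89, 0.83, 0.94, 100.0, 300.0, "protective"),
    ("vegetable", "stroke", 0.92, 0.86, 0.97, 100.0, 300.0, "protective"),
    ("legume", "CHD", 0.90, 0.82, 0.97, 50.0, 60.0, "protective"),
    ("red-meat", "stroke", 1.13, 1.03, 1.23, 100.0, 25.0, "harmful"),
    ("red-meat", "cancer", 1.17, 1.05, 1.31, 100.0, 25.0, "harmful"),
    ("red-meat", "T2D", 1.19, 1.04, 1.37, 100.0, 25.0, "harmful"),
]


def default_rr_models() -> list["RelativeRiskModel"]:
    from .cra import RelativeRiskModel

    return [RelativeRiskModel(*row) for row in _RR_TABLE]
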