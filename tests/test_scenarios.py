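"""Dietary-change scenario engine: substitution rules, EAT rescaling."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import foodcost as fc
from foodcost import defaults
from foodcost.scenarios import EAT_TOTAL_KCAL, modelled_intake_kcal


def toy_world():
    """One country, red meat 300 kcal/day plus legumes/fruit/veg baseline."""
    classes = pd.DataFrame(
        [
            ("beef", defaults.RED_MEAT, "red-meat"),
            ("beans", defaults.WPP, "legumes"),
            ("fruits", defaults.FV, "fruits"),
            ("vegetables", defaults.FV, "vegetables"),
            ("insects", defaults.INSECTS, "other"),
        ],
        columns=["fbs_group", "food_class", "eat_category"],
    )
    densities = pd.DataFrame(
        [("beef", 3650.0), ("beans", 3650.0), ("fruits", 365.0),
         ("vegetables", 365.0), ("insects", 1825.0)],
        columns=["fbs_group", "kcal_per_kg"],
    )
    supply = pd.DataFrame(
        [
            ("C", "beef", 20.0, 10.0, 300.0),
            ("C", "beans", 10.0, 0.0, 100.0),
            ("C", "fruits", 300.0, 100.0, 400.0),
            ("C", "vegetables", 100.0, 100.0, 200.0),
        ],
        columns=["country", "fbs_group", "domestic_kg", "import_kg", "energy_kcal"],
    )
    return supply, classes, densities


def kcal_by_group(supply):
    return supply.set_index("fbs_group")["energy_kcal"]


class TestStandardScenarios:
    def test_no_red_meat_two_thirds_one_third(self):
        supply, classes, densities = toy_world()
        spec = fc.ScenarioSpec("NRM", frozenset({defaults.RED_MEAT}),
                               {defaults.WPP: 2 / 3, defaults.FV: 1 / 3})
        out = fc.build_standard_scenario(supply, spec, classes, densities)
        e = kcal_by_group(out)
        assert e["beef"] == 0.0
        assert e["beans"] == pytest.approx(100.0 + 200.0)
        # fruits+vegetables gain 100 kcal split by baseline proportion 400:200
        assert e["fruits"] == pytest.approx(400.0 + 100.0 * 400.0 / 600.0)
        assert e["vegetables"] == pytest.approx(200.0 + 100.0 * 200.0 / 600.0)
        assert e.sum() == pytest.approx(1000.0, rel=1e-12)

    def test_insect_variant_thirds(self):
        supply, classes, densities = toy_world()
        spec = fc.ScenarioSpec(
            "NRM-I", frozenset({defaults.RED_MEAT}),
            {defaults.WPP: 1 / 3, defaults.FV: 1 / 3, defaults.INSECTS: 1 / 3},
        )
        out = fc.build_standard_scenario(supply, spec, classes, densities)
        e = kcal_by_group(out)
        assert e["beans"] == pytest.approx(200.0)
        assert e["insects"] == pytest.approx(100.0)  # uniform fallback, zero baseline
        assert e.sum() == pytest.approx(1000.0, rel=1e-12)

    def test_empty_spec_is_identity(self):
        supply, classes, densities = toy_world()
        out = fc.build_standard_scenario(supply, fc.ScenarioSpec("ID"), classes, densities)
        pd.testing.assert_frame_equal(out, supply)

    def test_mass_conversion_via_density(self):
        supply, classes, densities = toy_world()
        spec = fc.ScenarioSpec("NRM", frozenset({defaults.RED_MEAT}),
                               {defaults.WPP: 2 / 3, defaults.FV: 1 / 3})
        out = fc.build_standard_scenario(supply, spec, classes, densities)
        beans = out.set_index("fbs_group").loc["beans"]
        # +200 kcal/day at 3650 kcal/kg -> +20 kg/yr, all domestic at baseline
        assert beans["domestic_kg"] == pytest.approx(30.0)
        assert beans["import_kg"] == 0.0

    def test_import_ratio_preserved(self):
        supply, classes, densities = toy_world()
        spec = fc.ScenarioSpec("NRM", frozenset({defaults.RED_MEAT}),
                               {defaults.WPP: 2 / 3, defaults.FV: 1 / 3})
        out = fc.build_standard_scenario(supply, spec, classes, densities).set_index("fbs_group")
        base = supply.set_index("fbs_group")
        for g in ("fruits", "vegetables"):
            r0 = base.loc[g, "domestic_kg"] / (base.loc[g, "domestic_kg"] + base.loc[g, "import_kg"])
            r1 = out.loc[g, "domestic_kg"] / (out.loc[g, "domestic_kg"] + out.loc[g, "import_kg"])
            assert r1 == pytest.approx(r0, rel=1e-12)

    def test_missing_density_errors(self):
        supply, classes, densities = toy_world()
        spec = fc.ScenarioSpec("NRM", frozenset({defaults.RED_MEAT}),
                               {defaults.WPP: 2 / 3, defaults.FV: 1 / 3})
        with pytest.raises(fc.DataError):
            fc.build_standard_scenario(supply, spec, classes, densities.iloc[:1])

    def test_shares_must_sum_to_one(self):
        with pytest.raises(fc.ConfigError):
            fc.ScenarioSpec("bad", frozenset({defaults.RED_MEAT}), {defaults.WPP: 0.5})

    def test_removed_and_substitute_disjoint(self):
        with pytest.raises(fc.ConfigError):
            fc.ScenarioSpec("bad", frozenset({defaults.WPP}), {defaults.WPP: 1.0})


class TestVganProcessedRouting:
    def test_dairy_to_milk_alternatives(self):
        """Removed dairy kcal route to milk alternatives; meat kcal to meat alts."""
        classes = pd.DataFrame(
            [
                ("beef", defaults.RED_MEAT, "red-meat"),
                ("dairy", defaults.DAIRY, "dairy"),
                ("beans", defaults.WPP, "legumes"),
                ("fruits", defaults.FV, "fruits"),
                ("meat-alternatives", defaults.MEAT_ALT, "other"),
                ("milk-alternatives", defaults.MILK_ALT, "other"),
            ],
            columns=["fbs_group", "food_class", "eat_category"],
        )
        densities = pd.DataFrame(
            [(g, 3650.0) for g in classes["fbs_group"]],
            columns=["fbs_group", "kcal_per_kg"],
        )
        supply = pd.DataFrame(
            [
                ("C", "beef", 30.0, 0.0, 300.0),
                ("C", "dairy", 15.0, 0.0, 150.0),
                ("C", "beans", 10.0, 0.0, 100.0),
                ("C", "fruits", 45.0, 0.0, 450.0),
            ],
            columns=["country", "fbs_group", "domestic_kg", "import_kg", "energy_kcal"],
        )
        spec = fc.ScenarioSpec(
            "VGN-P", frozenset({defaults.RED_MEAT, defaults.DAIRY}),
            {defaults.WPP: 1 / 3, defaults.FV: 1 / 3},
            routed_share=1 / 3,
            routing={defaults.DAIRY: defaults.MILK_ALT, "default": defaults.MEAT_ALT},
        )
        out = fc.build_standard_scenario(supply, spec, classes, densities)
        e = kcal_by_group(out)
        assert e["milk-alternatives"] == pytest.approx(150.0 / 3.0)
        assert e["meat-alternatives"] == pytest.approx(300.0 / 3.0)
        assert e.sum() == pytest.approx(1000.0, rel=1e-12)


class TestShippedSuite:
    def test_removal_sets_are_nested(self):
        spec = {s.name: s.removed_classes for s in defaults.default_scenarios()}
        assert spec["NRM"] < spec["PESC"] < spec["VEG"] < spec["VGN"]

    def test_vgn_zeroes_all_asf_groups(self, world_small):
        suite = fc.build_suite(world_small, ["VGN"])
        cls_of = world_small.classes.set_index("fbs_group")["food_class"]
        vgn = suite["VGN"]
        asf = vgn[vgn["fbs_group"].map(cls_of).isin(defaults.ASF_CLASSES)]
        assert (asf[["domestic_kg", "import_kg", "energy_kcal"]] == 0.0).all().all()

    def test_calorie_conservation_all_non_eat(self, world_small):
        suite = fc.build_suite(world_small)
        base = suite["BASE"].groupby("country")["energy_kcal"].sum()
        for name, s in suite.items():
            if name in ("BASE", "EAT"):
                continue
            e = s.groupby("country")["energy_kcal"].sum()
            assert ((e - base).abs() / base).max() < 1e-9, name

    def test_duplicate_names_error(self, world_small):
        specs = defaults.default_scenarios()
        with pytest.raises(fc.ConfigError):
            fc.scenario_suite(world_small.supply, specs + [specs[0]],
                              world_small.classes, world_small.densities)

    def test_unknown_scenario_name_lists_valid(self, world_small):
        with pytest.raises(fc.ConfigError, match="VGN"):
            fc.build_suite(world_small, ["NOPE"])


class TestEatScenario:
    def test_total_modelled_intake(self, world_small):
        w = world_small
        eat = fc.build_eat_scenario(w.supply, w.eat_targets, w.classes, w.densities)
        intake = modelled_intake_kcal(eat, w.eat_targets, w.classes)
        totals = intake.groupby("country")["intake_kcal"].sum()
        assert np.allclose(totals, EAT_TOTAL_KCAL, rtol=1e-12)

    def test_proportional_scaling_halves_double_category(self):
        supply, classes, densities = toy_world()
        targets = pd.DataFrame(
            [("red-meat", 150.0, 1.0), ("legumes", 100.0, 1.0),
             ("fruits", 400.0, 1.0), ("vegetables", 200.0, 1.0), ("other", 0.0, 1.0)],
            columns=["eat_category", "intake_kcal", "edible_portion"],
        )
        out = fc.build_eat_scenario(supply, targets, classes, densities, total_kcal=None)
        e = kcal_by_group(out)
        assert e["beef"] == pytest.approx(150.0)  # halved from 300
        b = supply.set_index("fbs_group")
        o = out.set_index("fbs_group")
        assert o.loc["beef", "domestic_kg"] == pytest.approx(b.loc["beef", "domestic_kg"] / 2)

    def test_edible_portion_scales_supply(self):
        supply, classes, densities = toy_world()
        targets = pd.DataFrame(
            [("red-meat", 150.0, 0.5), ("legumes", 100.0, 1.0),
             ("fruits", 400.0, 1.0), ("vegetables", 200.0, 1.0), ("other", 0.0, 1.0)],
            columns=["eat_category", "intake_kcal", "edible_portion"],
        )
        out = fc.build_eat_scenario(supply, targets, classes, densities, total_kcal=None)
        # supply kcal = intake / edible portion
        assert kcal_by_group(out)["beef"] == pytest.approx(300.0)

    def test_empty_category_uniform_fill(self):
        supply, classes, densities = toy_world()
        targets = pd.DataFrame(
            [("red-meat", 0.0, 1.0), ("legumes", 100.0, 1.0),
             ("fruits", 400.0, 1.0), ("vegetables", 200.0, 1.0), ("other", 150.0, 1.0)],
            columns=["eat_category", "intake_kcal", "edible_portion"],
        )
        out = fc.build_eat_scenario(supply, targets, classes, densities, total_kcal=None)
        e = kcal_by_group(out)
        assert e["insects"] == pytest.approx(150.0)
        assert e["beef"] == 0.0

    def test_targets_must_sum_when_total_given(self):
        bad = pd.DataFrame(
            [("grains", 100.0, 1.0)], columns=["eat_category", "intake_kcal", "edible_portion"]
        )
        with pytest.raises(fc.DataError):
            fc.scenarios.validate_eat_targets(bad)

    def test_shipped_targets_sum_to_reference_total(self):
        assert defaults.default_eat_targets()["intake_kcal"].sum() == EAT_TOTAL_KCAL


@given(st.integers(0, 10_000))
def test_calorie_conservation_random_baselines(seed):
    """Removal+substitution conserves kcal on random single-country tables."""
    rng = np.random.default_rng(seed)
    supply, classes, densities = toy_world()
    supply = supply.copy()
    supply["energy_kcal"] = rng.uniform(0.0, 500.0, len(supply))
    d = densities.set_index("fbs_group")["kcal_per_kg"]
    supply["domestic_kg"] = supply.apply(
        lambda r: r["energy_kcal"] * 365.0 / d[r["fbs_group"]] * rng.uniform(0.2, 1.0), axis=1
    )
    supply["import_kg"] = supply["energy_kcal"] * 365.0 / supply["fbs_group"].map(d) - supply["domestic_kg"]
    spec = fc.ScenarioSpec(
        "NRM-I", frozenset({defaults.RED_MEAT}),
        {defaults.WPP: 1 / 3, defaults.FV: 1 / 3, defaults.INSECTS: 1 / 3},
    )
    out = fc.build_standard_scenario(supply, spec, classes, densities)
    assert out["energy_kcal"].sum() == pytest.approx(supply["energy_kcal"].sum(), rel=1e-9)
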