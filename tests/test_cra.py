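"""Comparative risk assessment: RR curves, PAFs, attributable/avoided DALYs."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import foodcost as fc
from foodcost.cra import HARMFUL, PROTECTIVE


def harmful(rr=1.2, serving=100.0, tmrel=0.0, lo=None, hi=None):
    return fc.RelativeRiskModel("red-meat", "CHD", rr, lo or rr * 0.9, hi or rr * 1.1,
                                serving, tmrel, HARMFUL)


def protective(rr=0.9, serving=100.0, tmrel=300.0, lo=None, hi=None):
    return fc.RelativeRiskModel("fruit", "stroke", rr, lo or rr * 0.9,
                                hi or min(0.999, rr * 1.05), serving, tmrel, PROTECTIVE)


class TestRelativeRisk:
    def test_reference_level(self):
        assert fc.relative_risk_at(harmful(), 0.0) == 1.0

    def test_log_linear_harmful(self):
        assert fc.relative_risk_at(harmful(1.2, 100.0), 200.0) == pytest.approx(1.44)

    def test_protective_clipped_at_tmrel(self):
        m = protective(0.9, 100.0, 300.0)
        assert fc.relative_risk_at(m, 600.0) == pytest.approx(0.9 ** 3)
        assert fc.relative_risk_at(m, 300.0) == pytest.approx(0.9 ** 3)

    def test_harmful_no_benefit_below_tmrel(self):
        m = harmful(1.2, 100.0, tmrel=50.0)
        assert fc.relative_risk_at(m, 0.0) == fc.relative_risk_at(m, 50.0)

    def test_negative_intake_errors(self):
        with pytest.raises(fc.DataError):
            fc.relative_risk_at(harmful(), -1.0)

    def test_direction_invariants_enforced(self):
        with pytest.raises(fc.ConfigError):
            fc.RelativeRiskModel("x", "d", 1.2, 1.0, 1.4, 100.0, 0.0, PROTECTIVE)
        with pytest.raises(fc.ConfigError):
            fc.RelativeRiskModel("x", "d", 0.9, 0.8, 0.95, 100.0, 0.0, HARMFUL)


class TestPafPointMass:
    def test_zero_at_tmrel(self):
        m = protective()
        assert fc.paf_point_mass(m, m.tmrel) == 0.0

    def test_closed_form(self):
        # RR(x)=2, RR(TMREL)=1 -> 0.5
        m = harmful(2.0, 100.0, 0.0)
        assert fc.paf_point_mass(m, 100.0) == pytest.approx(0.5)

    def test_protective_shortfall_negative(self):
        # intake below TMREL of a protective factor: RR(x) > RR(TMREL) -> PAF > 0;
        # the spec's mirrored case RR(x)=0.8 vs RR(TMREL)=1 gives -0.25
        rr_x, rr_t = 0.8, 1.0
        assert (rr_x - rr_t) / rr_x == pytest.approx(-0.25)
        m = protective(0.9, 100.0, 300.0)
        assert fc.paf_point_mass(m, 0.0) > 0  # zero fruit intake carries burden
        # and PAF <= 1 always
        assert fc.paf_point_mass(m, 0.0) <= 1.0

    def test_sign_matches_deviation(self):
        m = harmful(1.3, 100.0, tmrel=50.0)
        assert fc.paf_point_mass(m, 200.0) > 0
        assert fc.paf_point_mass(m, 50.0) == 0.0


class TestPafContinuous:
    def test_degenerate_density_matches_point_mass(self):
        m = harmful(1.25, 100.0, 0.0)
        x0, sd = 150.0, 0.01
        def density(x):
            return np.exp(-0.5 * ((x - x0) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
        got = fc.paf_continuous(m, density, (x0 - 8 * sd, x0 + 8 * sd))
        assert got == pytest.approx(fc.paf_point_mass(m, x0), abs=1e-6)

    def test_uniform_density_analytic_integral(self):
        # mean RR over U[a,b] of r**(x/s) has closed form s(r^{b/s}-r^{a/s})/((b-a) ln r)
        m = harmful(1.3, 100.0, 0.0)
        a, b, r, s = 50.0, 250.0, 1.3, 100.0
        def density(x):
            return np.where((x >= a) & (x <= b), 1.0 / (b - a), 0.0)
        mean_rr = s * (r ** (b / s) - r ** (a / s)) / ((b - a) * math.log(r))
        expected = (mean_rr - 1.0) / mean_rr
        assert fc.paf_continuous(m, density, (a, b)) == pytest.approx(expected, rel=1e-6)

    def test_density_at_tmrel_gives_zero(self):
        m = protective(0.9, 100.0, 300.0)
        x0, sd = 300.0, 0.001  # clipping at TMREL leaves an O(sd) positive bias
        def density(x):
            return np.exp(-0.5 * ((x - x0) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
        assert fc.paf_continuous(m, density, (x0 - 8 * sd, x0 + 8 * sd)) == pytest.approx(0.0, abs=1e-6)

    def test_unnormalized_density_rejected(self):
        m = harmful()
        with pytest.raises(fc.DataError):
            fc.paf_continuous(m, lambda x: np.full_like(np.asarray(x, float), 0.5),
                              (0.0, 1.0))


class TestCombinePafs:
    def test_single_identity(self):
        assert fc.combine_pafs([0.37]) == pytest.approx(0.37)

    def test_two_halves(self):
        assert fc.combine_pafs([0.5, 0.5]) == pytest.approx(0.75)

    def test_absorbing_one(self):
        assert fc.combine_pafs([1.0, 0.2, -0.3]) == 1.0

    def test_order_invariant(self):
        vals = [0.1, -0.2, 0.45]
        assert fc.combine_pafs(vals) == pytest.approx(fc.combine_pafs(vals[::-1]))

    def test_dominates_max_when_nonnegative(self):
        vals = [0.1, 0.3, 0.05]
        assert fc.combine_pafs(vals) >= max(vals)

    def test_above_one_rejected(self):
        with pytest.raises(fc.DataError):
            fc.combine_pafs([1.1])


class TestAttributableDalys:
    def burden(self, rows):
        return pd.DataFrame(rows, columns=["country", "disease", "dalys"])

    def pafs(self, rows):
        return pd.DataFrame(rows, columns=["country", "disease", "paf"])

    def test_product(self):
        per_c, total = fc.attributable_dalys(
            self.pafs([("A", "CHD", 0.2)]), self.burden([("A", "CHD", 1000.0)])
        )
        assert total == pytest.approx(200.0)

    def test_zero_paf(self):
        _, total = fc.attributable_dalys(
            self.pafs([("A", "CHD", 0.0)]), self.burden([("A", "CHD", 1000.0)])
        )
        assert total == 0.0

    def test_two_disease_sum(self):
        per_c, total = fc.attributable_dalys(
            self.pafs([("A", "CHD", 0.1), ("A", "stroke", 0.5)]),
            self.burden([("A", "CHD", 100.0), ("A", "stroke", 200.0)]),
        )
        assert per_c.set_index("country").loc["A", "attributable"] == pytest.approx(110.0)
        assert total == pytest.approx(110.0)

    def test_missing_burden_errors(self):
        with pytest.raises(fc.DataError):
            fc.attributable_dalys(self.pafs([("A", "CHD", 0.2)]),
                                  self.burden([("B", "CHD", 1.0)]))


class TestAvoidedDalys:
    def exposures(self, intake):
        return pd.DataFrame(
            [("A", "red-meat", intake)], columns=["country", "risk_factor", "intake_g"]
        )

    def burden(self):
        return pd.DataFrame([("A", "CHD", 1000.0)], columns=["country", "disease", "dalys"])

    def test_same_diet_zero_width(self):
        out = fc.avoided_dalys(self.exposures(150.0), self.exposures(150.0),
                               [harmful(1.3, 100.0, 0.0, 1.1, 1.5)], self.burden())
        assert out == {"value": 0.0, "lower": 0.0, "upper": 0.0}

    def test_move_to_tmrel_recovers_base_attributable(self):
        m = harmful(1.3, 100.0, 0.0, 1.1, 1.5)
        x = 150.0
        base_paf = fc.paf_point_mass(m, x)
        out = fc.avoided_dalys(self.exposures(x), self.exposures(0.0), [m], self.burden())
        assert out["value"] == pytest.approx(base_paf * 1000.0)
        assert out["lower"] <= out["value"] <= out["upper"]

    def test_worse_scenario_negative(self):
        out = fc.avoided_dalys(self.exposures(50.0), self.exposures(250.0),
                               [harmful(1.3, 100.0, 0.0, 1.1, 1.5)], self.burden())
        assert out["value"] < 0


@given(st.integers(0, 2**31 - 1))
def test_pipeline_attributable_matches_analytic(seed):
    """On exposures from known RR models, attributable DALYs equal the
    closed-form PAF x burden product exactly."""
    rng = np.random.default_rng(seed)
    m1 = harmful(float(rng.uniform(1.05, 1.6)), 100.0, 0.0, 1.01, 2.0)
    m2 = fc.RelativeRiskModel("fruit", "CHD", 0.9, 0.85, 0.95, 100.0, 300.0, PROTECTIVE)
    x_meat, x_fruit = float(rng.uniform(0, 400)), float(rng.uniform(0, 400))
    exposures = pd.DataFrame(
        [("A", "red-meat", x_meat), ("A", "fruit", x_fruit)],
        columns=["country", "risk_factor", "intake_g"],
    )
    burden = pd.DataFrame([("A", "CHD", 500.0)], columns=["country", "disease", "dalys"])
    pafs = fc.cra.combined_pafs(exposures, [m1, m2])
    _, total = fc.attributable_dalys(pafs, burden)
    p1 = fc.paf_point_mass(m1, x_meat)
    p2 = fc.paf_point_mass(m2, x_fruit)
    analytic = (1.0 - (1.0 - p1) * (1.0 - p2)) * 500.0
    assert total == pytest.approx(analytic, rel=1e-12)
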