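import numpy as np
import pytest

from shc import grids
from shc.impact import (TCP0, TCP1, TCP2, TCP3, PolicySpec, paf,
                        project_scenarios, sad, total_deaths)
from shc.mortality import ExpandedMortality
from shc.state import PopulationState


def _mort(dn, dc, df):
    return ExpandedMortality(
        delta_N=np.full(grids.N_AGES, dn),
        delta_C=np.full((3, grids.N_AGES), dc),
        delta_F=np.full((3, grids.N_AGES, grids.C_MAX), df),
    )


class TestSadPaf:
    def test_zero_without_excess_risk(self):
        st = PopulationState(t=2000)
        st.C[1, 50] = 1000.0
        st.F[0, 60, 5] = 500.0
        m = _mort(0.01, 0.01, 0.01)
        assert sad(st, m) == 0.0
        assert paf(sad(st, m), total_deaths(st, m)) == 0.0

    def test_hand_computed_excess(self):
        # 1000 smokers with excess 0.01 plus 500 former with excess 0.005
        st = PopulationState(t=2000)
        st.C[1, 50] = 1000.0
        st.F[0, 60, 5] = 500.0
        m = _mort(0.01, 0.02, 0.015)
        assert sad(st, m) == pytest.approx(12.5)
        assert total_deaths(st, m) == pytest.approx(1000 * 0.02 + 500 * 0.015)

    def test_age_band_additivity(self, male_truth):
        st = male_truth.initial_state()
        m = male_truth.mortality
        assert sad(st, m, (35, 100)) == pytest.approx(
            sad(st, m, (65, 100)) + sad(st, m, (35, 64)))

    def test_paf_ratio_and_zero_deaths_rejected(self):
        assert paf(180.0, 1000.0) == pytest.approx(0.18)
        with pytest.raises(ValueError):
            paf(1.0, 0.0)

    def test_paf_monotone_in_rr(self, male_truth):
        from shc.mortality import RelativeRisks, expand_mortality
        st = male_truth.initial_state()
        base = male_truth.rr
        lo = expand_mortality(male_truth.delta_n_true, base)
        hi = expand_mortality(male_truth.delta_n_true, RelativeRisks(
            rr_current=base.rr_current * 1.5,
            rr_former=1.0 + (base.rr_former - 1.0) * 1.5))
        assert (paf(sad(st, hi, (35, 100)), total_deaths(st, hi, (35, 100)))
                > paf(sad(st, lo, (35, 100)), total_deaths(st, lo, (35, 100))))


class TestPolicySchedules:
    def test_linear_ramp_hits_printed_values(self):
        assert TCP1.start_multiplier(1) == pytest.approx(0.975)
        assert TCP1.start_multiplier(10) == pytest.approx(0.75)
        assert TCP1.start_multiplier(15) == pytest.approx(0.75)
        assert TCP2.stop_multiplier(1) == pytest.approx(1.025)
        assert TCP2.stop_multiplier(10) == pytest.approx(1.25)
        assert TCP2.stop_multiplier(30) == pytest.approx(1.25)

    def test_null_policy_is_identity(self):
        g = np.random.default_rng(0).uniform(0, 0.3, grids.N_AGES)
        e = np.random.default_rng(1).uniform(0, 0.3, grids.N_AGES)
        g2, e2 = TCP0.modify(g, e, 2030)
        np.testing.assert_array_equal(g, g2)
        np.testing.assert_array_equal(e, e2)

    def test_before_start_year_unmodified(self):
        g = np.full(grids.N_AGES, 0.1)
        e = np.full(grids.N_AGES, 0.2)
        for policy in (TCP1, TCP2, TCP3):
            g2, e2 = policy.modify(g, e, 2022)
            np.testing.assert_array_equal(g, g2)
            np.testing.assert_array_equal(e, e2)

    def test_multiplier_acts_on_rate_scale(self):
        g = np.zeros(grids.N_AGES)
        g[20] = 0.4
        g2, _ = TCP1.modify(g, np.zeros(grids.N_AGES), 2032)  # year 10: m=0.75
        expected = 1 - (1 - 0.4) ** 0.75  # rate scaling, not 0.75 * 0.4
        assert g2[20] == pytest.approx(expected)
        assert g2[20] != pytest.approx(0.75 * 0.4)

    def test_age_ranges_respected(self):
        g = np.full(grids.N_AGES, 0.1)
        e = np.full(grids.N_AGES, 0.2)
        g1, _ = TCP1.modify(g, e, 2030)
        assert g1[13] == 0.1 and g1[35] == 0.1 and g1[20] < 0.1
        _, e2 = TCP2.modify(g, e, 2030)
        assert e2[24] == 0.2 and e2[25] > 0.2 and e2[100] > 0.2

    def test_cohort_ban_zeroes_initiation(self):
        g = np.full(grids.N_AGES, 0.1)
        g3, _ = TCP3.modify(g, np.zeros(grids.N_AGES), 2030)
        # cohorts born >= 2009 are aged <= 21 in 2030
        assert np.all(g3[:22] == 0.0)
        assert np.all(g3[22:] == 0.1)


@pytest.fixture(scope="module")
def projections(male_truth):
    return project_scenarios(
        male_truth.theta, male_truth.initial_state(), male_truth.mortality,
        male_truth.fixed, until=2043)


class TestPolicyFile:
    def test_yaml_round_trip_matches_builtins(self, tmp_path):
        from shc.impact import load_policies
        f = tmp_path / "policies.yaml"
        f.write_text(
            "TCP1:\n  start_rate_change: -0.025\n  ramp_years: 10\n"
            "custom:\n  stop_rate_change: 0.05\n  stop_ages: [30, 90]\n")
        pols = load_policies(f)
        assert pols["TCP1"].start_multiplier(4) == TCP1.start_multiplier(4)
        assert pols["custom"].stop_ages == (30, 90)

    def test_unknown_policy_field_rejected(self, tmp_path):
        from shc.impact import load_policies
        f = tmp_path / "bad.yaml"
        f.write_text("p:\n  frobnicate: 1\n")
        with pytest.raises(ValueError, match="unknown fields"):
            load_policies(f)


class TestScenarioProjection:
    def test_identical_before_policy_start(self, projections):
        prev, _ = projections
        pre = prev[prev.year < 2023].pivot_table(
            index="year", columns="policy", values="current")
        for name in ("TCP1", "TCP2", "TCP3"):
            np.testing.assert_array_equal(pre["TCP0"], pre[name])

    def test_tcp3_dominance_on_never_prevalence(self, projections):
        prev, _ = projections
        piv = prev.pivot_table(index="year", columns="policy", values="never")
        assert np.all(piv["TCP3"] >= piv["TCP0"] - 1e-12)
        cur = prev.pivot_table(index="year", columns="policy", values="current")
        assert np.all(cur["TCP3"] <= cur["TCP0"] + 1e-12)

    def test_tcp2_reduces_attributable_deaths(self, projections, male_truth):
        # quitting only lowers risk when former RR stays below current RR
        assert np.all(male_truth.rr.rr_former_full()
                      <= male_truth.rr.rr_current[:, None] + 1e-12)
        _, imp = projections
        piv = imp[imp.age_band == "35+"].pivot_table(
            index="year", columns="policy", values="sad")
        post = piv.loc[2023:]
        assert np.all(post["TCP2"] <= post["TCP0"] + 1e-9)

    def test_avoided_deaths_reference_difference(self, projections):
        _, imp = projections
        piv = imp[imp.age_band == "65+"].pivot_table(
            index="year", columns="policy", values=["sad", "avoided_vs_ref"])
        diff = piv["sad"]["TCP0"] - piv["sad"]["TCP2"]
        np.testing.assert_allclose(piv["avoided_vs_ref"]["TCP2"], diff, atol=1e-9)
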