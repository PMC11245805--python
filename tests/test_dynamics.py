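import numpy as np
import pytest

from shc import grids
from shc.dynamics import (check_conservation, simulate, simulate_class_counts,
                          step, step_reference)
from shc.mortality import ExpandedMortality
from shc.params import FixedParameters, TransitionCurves
from shc.state import PopulationState


def _fixed(nu=0.0, pi=(0.5, 0.3, 0.2)):
    return FixedParameters(pi=np.array(pi), nu=nu,
                           intensity_dist=np.array([1 / 3, 1 / 3, 1 / 3]),
                           cessation_dist=np.full(10, 0.1))


def _mortality(dn=0.0, dc=0.0, df=0.0):
    return ExpandedMortality(
        delta_N=np.full(grids.N_AGES, dn),
        delta_C=np.full((3, grids.N_AGES), dc),
        delta_F=np.full((3, grids.N_AGES, grids.C_MAX), df),
    )


def _curves(g=0.0, e=0.0, eta=0.0):
    gamma = np.zeros(grids.N_AGES)
    gamma[14:35] = g
    eps = np.zeros(grids.N_AGES)
    eps[20:] = e
    et = np.full(grids.C_MAX, eta)
    et[0] = 0.0
    return TransitionCurves(gamma=gamma, epsilon=eps, eta=et)


def random_valid_state(rng, scale=1000.0):
    st = PopulationState(t=0)
    st.N[:] = rng.uniform(0, scale, grids.N_AGES)
    st.C[:, 14:] = rng.uniform(0, scale / 3, (3, grids.N_AGES - 14))
    mask = grids.admissible_cessation_mask()
    F = rng.uniform(0, scale / 10, (3, grids.N_AGES, grids.C_MAX))
    st.F[:] = np.where(mask[None, :, :], F, 0.0)
    st.C[:, 0] = 0
    return st


def random_curves_and_mortality(rng):
    gamma = np.zeros(grids.N_AGES)
    gamma[14:35] = rng.uniform(0, 0.3, 21)
    eps = np.zeros(grids.N_AGES)
    eps[20:] = rng.uniform(0, 0.5, 81)
    eta = rng.uniform(0, 0.8, grids.C_MAX)
    eta[0] = 0.0
    curves = TransitionCurves(gamma=gamma, epsilon=eps, eta=eta)
    dn = rng.uniform(0, 0.2, grids.N_AGES)
    mort = ExpandedMortality(
        delta_N=dn,
        delta_C=np.clip(np.broadcast_to(dn, (3, grids.N_AGES))
                        * rng.uniform(1, 3, (3, 1)), 0, 1).copy(),
        delta_F=np.clip(np.broadcast_to(dn[None, :, None],
                                        (3, grids.N_AGES, grids.C_MAX))
                        * rng.uniform(1, 3, (3, 1, 1)), 0, 1).copy(),
    )
    return curves, mort


class TestStepExamples:
    def test_no_transitions_no_deaths_just_ageing(self):
        st = random_valid_state(np.random.default_rng(0))
        out = step(st, _curves(), _mortality(), _fixed(nu=0.0))
        np.testing.assert_allclose(out.N[1:], st.N[:-1])
        np.testing.assert_allclose(out.C[:, 1:], st.C[:, :-1])
        np.testing.assert_allclose(out.F[:, 1:, 1:], st.F[:, :-1, :-1])
        assert out.N[0] == 0.0

    def test_initiation_split_hand_computed(self):
        # 1000 never smokers aged 20, death risk 0.1, starting prob 0.2
        st = PopulationState(t=0)
        st.N[20] = 1000.0
        out = step(st, _curves(g=0.2), _mortality(dn=0.1), _fixed())
        # gamma has support 14..34 only, so age 20 uses gamma=0.2
        assert out.deaths_N[20] == pytest.approx(100.0)
        np.testing.assert_allclose(out.C[:, 21], [90.0, 54.0, 36.0])
        assert out.N[21] == pytest.approx(720.0)

    def test_relapse_hand_computed(self):
        # 500 medium-intensity former smokers aged 40, 2 years since quitting
        st = PopulationState(t=0)
        st.F[1, 40, 2] = 500.0
        eta = np.zeros(grids.C_MAX)
        eta[2] = 0.1
        curves = TransitionCurves(gamma=np.zeros(101), epsilon=np.zeros(101), eta=eta)
        out = step(st, curves, _mortality(df=0.02), _fixed())
        assert out.C[1, 41] == pytest.approx(49.0)
        assert out.F[1, 41, 3] == pytest.approx(441.0)
        assert out.deaths_F[1, 40, 2] == pytest.approx(10.0)

    def test_quitting_enters_cessation_zero(self):
        st = PopulationState(t=0)
        st.C[2, 30] = 100.0
        out = step(st, _curves(e=0.25), _mortality(), _fixed())
        assert out.F[2, 31, 0] == pytest.approx(25.0)
        assert out.C[2, 31] == pytest.approx(75.0)


class TestKernelAgainstReference:
    def test_compiled_step_matches_numpy_reference(self, rng):
        for trial in range(5):
            st = random_valid_state(rng)
            curves, mort = random_curves_and_mortality(rng)
            fx = _fixed(nu=rng.uniform(0, 500))
            a = step(st, curves, mort, fx)
            b = step_reference(st, curves, mort, fx)
            np.testing.assert_allclose(a.N, b.N, rtol=1e-12)
            np.testing.assert_allclose(a.C, b.C, rtol=1e-12)
            np.testing.assert_allclose(a.F, b.F, rtol=1e-12)
            np.testing.assert_allclose(a.deaths_total(), b.deaths_total(), rtol=1e-12)
            assert a.exited == pytest.approx(b.exited, rel=1e-12)

    def test_class_counts_match_full_trajectory(self, male_truth):
        init = male_truth.initial_state()
        counts = simulate_class_counts(init, male_truth.theta, male_truth.mortality,
                                       male_truth.fixed, 5)
        traj = simulate(init, male_truth.theta, male_truth.mortality,
                        male_truth.fixed, 5)
        from shc.state import aggregate_prevalence
        for y, st in enumerate(traj):
            p, n = aggregate_prevalence(st)
            np.testing.assert_allclose(counts[y].sum(axis=1), n, rtol=1e-9)
            np.testing.assert_allclose(counts[y] / n[:, None], p, rtol=1e-9)


class TestConservation:
    def test_every_year_balances(self, rng):
        for trial in range(20):
            st = random_valid_state(rng)
            curves, mort = random_curves_and_mortality(rng)
            fx = _fixed(nu=rng.uniform(0, 1000))
            for _ in range(5):
                new = step(st, curves, mort, fx)
                assert check_conservation(st, new, fx.nu) < 1e-6
                st = new

    def test_non_negative_compartments(self, rng):
        st = random_valid_state(rng)
        curves, mort = random_curves_and_mortality(rng)
        for st_next in simulate(st, curves, mort, _fixed(nu=10.0), 10)[1:]:
            assert st_next.N.min() >= 0 and st_next.C.min() >= 0 and st_next.F.min() >= 0


class TestClosedFormLimits:
    def test_pure_survival_cohort_when_gamma_zero(self):
        rng = np.random.default_rng(5)
        st = PopulationState(t=0)
        st.N[:] = rng.uniform(100, 1000, grids.N_AGES)
        dn = rng.uniform(0, 0.1, grids.N_AGES)
        mort = ExpandedMortality(delta_N=dn, delta_C=np.zeros((3, 101)),
                                 delta_F=np.zeros((3, 101, grids.C_MAX)))
        k = 6
        traj = simulate(st, _curves(g=0.0, e=0.3), mort, _fixed(nu=0.0), k)
        for a in range(k, grids.N_AGES):
            expected = st.N[a - k] * np.prod(1 - dn[a - k:a])
            assert traj[k].N[a] == pytest.approx(expected, rel=1e-10)

    def test_former_absorbing_when_eta_zero(self, rng):
        st = random_valid_state(rng)
        # keep cohorts away from the terminal age so nobody exits the grid
        st.N[90:] = 0
        st.C[:, 90:] = 0
        st.F[:, 90:, :] = 0
        curves = _curves(g=0.1, e=0.2, eta=0.0)
        traj = simulate(st, curves, _mortality(), _fixed(nu=0.0), 8)
        f_totals = [s.F.sum() for s in traj]
        assert np.all(np.diff(f_totals) >= -1e-9)

    def test_geometric_decay_of_closed_cohort(self):
        st = PopulationState(t=0)
        st.N[30] = 1000.0
        traj = simulate(st, _curves(), _mortality(dn=0.1), _fixed(nu=0.0), 4)
        for k, s in enumerate(traj):
            assert s.alive() == pytest.approx(1000.0 * 0.9**k)


class TestSimulateContract:
    def test_zero_horizon_returns_only_initial(self, male_truth):
        traj = simulate(male_truth.initial_state(), male_truth.theta,
                        male_truth.mortality, male_truth.fixed, 0)
        assert len(traj) == 1

    def test_negative_horizon_rejected(self, male_truth):
        with pytest.raises(ValueError):
            simulate(male_truth.initial_state(), male_truth.theta,
                     male_truth.mortality, male_truth.fixed, -1)
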