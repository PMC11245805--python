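import numpy as np
import pytest

from shc import build_problem, sexdata_from_truth
from shc.calibration import (CalibrationProblem, SurveyPrevalence, calibrate,
                             calibrate_window, hellinger, sample_start)
from shc.params import ThetaVector


class TestHellinger:
    def test_identity(self):
        assert hellinger([0.2, 0.5, 0.3], [0.2, 0.5, 0.3]) == 0.0

    def test_disjoint_support_maximum(self):
        assert hellinger([1, 0, 0], [0, 1, 0]) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        assert hellinger([0.5, 0.3, 0.2], [0.4, 0.4, 0.2]) == pytest.approx(0.07985, abs=1e-5)

    def test_symmetry(self):
        p, q = [0.7, 0.2, 0.1], [0.1, 0.6, 0.3]
        assert hellinger(p, q) == pytest.approx(hellinger(q, p))

    @pytest.mark.parametrize("bad", [[0.5, 0.6, 0.2], [-0.1, 0.6, 0.5]])
    def test_off_simplex_rejected(self, bad):
        with pytest.raises(ValueError):
            hellinger(bad, [1 / 3, 1 / 3, 1 / 3])


class TestObjective:
    def test_zero_at_generating_parameters_on_noiseless_data(self, noiseless_data,
                                                             male_truth):
        problem = build_problem(noiseless_data)
        assert problem.objective(male_truth.theta) == pytest.approx(0.0, abs=1e-12)

    def test_mean_over_cells(self, male_truth):
        # distort one second-year cell out of 20 noiseless ones (the first
        # year also seeds the initial state, so it is left untouched):
        # Obj = H(cell) / (T * A)
        obs = male_truth.noiseless_prevalence[:2].copy()
        h0 = hellinger(obs[1, 0], [0.5, 0.25, 0.25])
        obs[1, 0] = [0.5, 0.25, 0.25]
        problem = build_problem(sexdata_from_truth(
            male_truth, SurveyPrevalence(male_truth.years[:2], obs,
                                         np.full((2, 10), 100.0))),
            mortality=male_truth.mortality)
        assert problem.objective(male_truth.theta) == pytest.approx(h0 / 20)

    def test_bounded_and_permutation_invariant(self, male_problem, male_truth, rng):
        v = male_problem.objective(male_truth.theta)
        assert 0.0 <= v <= 1.0
        x = sample_start(rng)
        assert 0.0 <= male_problem.objective_packed(x) <= 1.0

    def test_missing_cells_reduce_divisor(self, male_truth):
        obs = male_truth.noiseless_prevalence.copy()
        T, A = obs.shape[:2]
        distorted = obs.copy()
        distorted[3, 4] = [0.5, 0.25, 0.25]
        n = np.full((T, A), 100.0)
        full = build_problem(sexdata_from_truth(
            male_truth, SurveyPrevalence(male_truth.years, distorted, n)),
            mortality=male_truth.mortality)
        v_full = full.objective(male_truth.theta)
        # blank everything except the first year (needed to seed the initial
        # state; its distances are 0) and the distorted cell
        blanked = np.full_like(obs, np.nan)
        blanked[0] = obs[0]
        blanked[3, 4] = distorted[3, 4]
        only = build_problem(sexdata_from_truth(
            male_truth, SurveyPrevalence(male_truth.years, blanked, n)),
            mortality=male_truth.mortality)
        v_only = only.objective(male_truth.theta)
        assert v_only == pytest.approx(v_full * T * A / (A + 1))

    def test_initial_year_mismatch_rejected(self, male_data, male_problem):
        with pytest.raises(ValueError, match="initial state year"):
            CalibrationProblem(male_data.observed.window(1994, 2000),
                               male_problem.initial, male_data.fixed,
                               male_problem.mortality)


class TestCalibrate:
    def test_determinism_same_seed_same_result(self, male_problem):
        kw = dict(n_starts=2, seed=9, maxiter=150, n_restarts=0)
        a = calibrate(male_problem, **kw)
        b = calibrate(male_problem, **kw)
        np.testing.assert_array_equal(a.theta_hat.pack(), b.theta_hat.pack())
        assert a.objective_value == b.objective_value

    def test_optimum_beats_every_start(self, male_problem):
        fit = calibrate(male_problem, n_starts=3, seed=4, maxiter=200, n_restarts=0)
        for trace in fit.traces:
            start_val = male_problem.objective_packed(trace.start)
            assert fit.objective_value <= start_val + 1e-12

    def test_objective_value_consistent_with_theta_hat(self, male_problem):
        fit = calibrate(male_problem, n_starts=2, seed=1, maxiter=150, n_restarts=0)
        assert male_problem.objective(fit.theta_hat) == pytest.approx(
            fit.objective_value, abs=1e-12)

    def test_grid_oracle_two_year_toy(self, male_truth):
        """On a 2-year, 2-class toy, a dense lattice around the optimizer's
        start finds no point better than the optimizer's result."""
        p = np.full((2, 10, 3), np.nan)
        p[:, 3:5] = male_truth.noiseless_prevalence[:2, 3:5]
        obs = SurveyPrevalence(male_truth.years[:2], p, np.full((2, 10), 1000.0))
        problem = build_problem(sexdata_from_truth(male_truth, obs),
                                initial=male_truth.initial_state())
        x_ref = sample_start(np.random.default_rng(6))
        fit = calibrate(problem, n_starts=0, extra_starts=[x_ref],
                        maxiter=1500, n_restarts=1, seed=0)
        best_lattice = np.inf
        for d_psi0 in np.linspace(-2, 2, 9):
            for d_phi0 in np.linspace(-2, 2, 9):
                x = x_ref.copy()
                x[0] += d_psi0
                x[4] += d_phi0
                best_lattice = min(best_lattice, problem.objective_packed(x))
        assert fit.objective_value <= best_lattice + 1e-9

    def test_single_year_window_is_flagged(self, male_data):
        fit = calibrate_window(male_data.observed, build_problem(male_data).initial,
                               male_data.fixed, build_problem(male_data).mortality,
                               years=(1993, 1993), n_starts=1, seed=0,
                               maxiter=50, n_restarts=0)
        assert fit.weakly_identified

    def test_window_equal_to_full_period_matches_calibrate(self, male_data):
        problem = build_problem(male_data)
        kw = dict(n_starts=2, seed=3, maxiter=120, n_restarts=0)
        full = calibrate(problem, **kw)
        window = calibrate_window(male_data.observed, problem.initial,
                                  male_data.fixed, problem.mortality,
                                  years=(1993, 2002), **kw)
        np.testing.assert_array_equal(full.theta_hat.pack(), window.theta_hat.pack())

    def test_empty_window_rejected(self, male_data, male_problem):
        with pytest.raises(ValueError):
            male_data.observed.window(2005, 2010)
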