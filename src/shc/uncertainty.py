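"""Parametric bootstrap for sampling variability.

Each replicate resamples the survey prevalences from a Dirichlet distribution
centered at the fitted values with the survey sample sizes as concentration
mass, then re-runs the FULL two-step estimation (never-smoker mortality, then
theta) on the resampled data.  90% intervals are the 5th/95th percentiles of
the replicate estimates; for curves and trajectories they are pointwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import grids
from .calibration import CalibrationResult, SurveyPrevalence, calibrate
from .params import ThetaVector
from .pipeline import SexData, build_problem

log = logging.getLogger(__name__)

#: concentration components below this are floored so the Dirichlet stays proper
CONCENTRATION_FLOOR = 1e-6


@dataclass
class BootstrapEnsemble:
    """Replicate estimates from the parametric bootstrap."""

    theta: np.ndarray                 # (B_ok, 10) packed replicate estimates
    delta_n: np.ndarray               # (B_ok, 101) replicate never-smoker risks
    objective: np.ndarray             # (B_ok,)
    n_failed: int = 0
    seed: int | None = None

    @property
    def B(self) -> int:
        return self.theta.shape[0]

    def thetas(self) -> list[ThetaVector]:
        return [ThetaVector.unpack(x) for x in self.theta]


def sample_bootstrap_prevalence(
    p_hat: np.ndarray, n: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One Dirichlet draw per (year, class) cell around the fitted prevalences.

    The concentration vector is ordered (current, never, former) as the
    procedure is stated; draws are mapped back to the stored (never, current,
    former) layout.  Cells with NaN fitted prevalence stay NaN.
    """
    p_hat = np.asarray(p_hat, dtype=float)
    n = np.asarray(n, dtype=float)
    out = np.full_like(p_hat, np.nan)
    order = [1, 0, 2]  # (C, N, F) as printed
    inverse = np.argsort(order)
    ok = ~np.isnan(p_hat).any(axis=-1)
    for idx in np.argwhere(ok):
        cell = tuple(idx)
        alpha = np.maximum(p_hat[cell][order] * n[cell], CONCENTRATION_FLOOR)
        out[cell] = rng.dirichlet(alpha)[inverse]
    return out


def bootstrap(
    fit: CalibrationResult,
    data: SexData,
    B: int = 1000,
    seed: int = 0,
    n_fresh_starts: int = 2,
    maxiter: int = 600,
    window: tuple[int, int] | None = None,
    **calib_kwargs,
) -> BootstrapEnsemble:
    """B full two-step refits on Dirichlet-resampled prevalences.

    The point fit is reused as one optimizer start per replicate;
    ``n_fresh_starts`` additional starts are drawn per replicate.
    Non-converging replicates are flagged and excluded, not fatal.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    obs = data.observed if window is None else data.observed.window(*window)
    problem = build_problem(data, window=window)
    p_fit = problem.model_prevalence(fit.theta_hat)
    # survey cells that were missing stay missing in the replicates
    p_fit = np.where(np.isnan(obs.p), np.nan, p_fit)

    rng = np.random.default_rng(seed)
    thetas, deltas, objs = [], [], []
    n_failed = 0
    warm = fit.theta_hat.pack()
    for b in range(B):
        p_b = sample_bootstrap_prevalence(p_fit, obs.n, rng)
        rep_seed = int(rng.integers(2**31 - 1))
        data_b = SexData(
            sex=data.sex,
            observed=SurveyPrevalence(obs.years, p_b, obs.n),
            delta_pop=data.delta_pop, baseline_pop=data.baseline_pop,
            fixed=data.fixed, rr=data.rr,
        )
        try:
            prob_b = build_problem(data_b, window=window)
            fit_b = calibrate(prob_b, n_starts=n_fresh_starts, seed=rep_seed,
                              maxiter=maxiter, extra_starts=[warm], **calib_kwargs)
        except RuntimeError:
            n_failed += 1
            continue
        thetas.append(fit_b.theta_hat.pack())
        deltas.append(prob_b.mortality.delta_N)
        objs.append(fit_b.objective_value)
    if n_failed:
        log.warning("bootstrap: %d of %d replicates failed and were excluded",
                    n_failed, B)
    if not thetas:
        raise RuntimeError("all bootstrap replicates failed")
    return BootstrapEnsemble(
        theta=np.array(thetas), delta_n=np.array(deltas),
        objective=np.array(objs), n_failed=n_failed, seed=seed,
    )


def percentile_interval(samples, level: float = 90.0) -> tuple[float, float]:
    """Empirical central interval (linear-interpolation percentiles)."""
    samples = np.asarray(samples, dtype=float)
    samples = samples[~np.isnan(samples)]
    if samples.size < 2:
        raise ValueError("need at least two valid samples")
    half = (100.0 - level) / 2.0
    lo, hi = np.percentile(samples, [half, 100.0 - half])
    return float(lo), float(hi)


def pointwise_band(curves: np.ndarray, level: float = 90.0
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise percentile band over axis 0 (replicates) of a curve sample."""
    curves = np.asarray(curves, dtype=float)
    if curves.shape[0] < 2:
        raise ValueError("need at least two replicates")
    half = (100.0 - level) / 2.0
    lo, hi = np.percentile(curves, [half, 100.0 - half], axis=0)
    return lo, hi
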