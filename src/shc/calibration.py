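"""Second estimation step: calibrate theta = (psi, phi, omega) on survey prevalences.

The objective is the mean Hellinger distance between observed and
model-implied (never, current, former) prevalences over all observed
(year, age-class) cells,

    Obj(theta) = 1 / (T * A) * sum_{t, a*} H(p(t; a*, theta), p_obs(t; a*)),

minimized by multi-start derivative-free local search (Nelder-Mead with a
restart polish per start).  omega is optimized on the log scale so positivity
is structural.  Cells with an undefined prevalence (empty class, missing
survey cell) are excluded and the divisor reduced accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import grids
from .dynamics import _CLS_INDEX, _classcounts_kernel, simulate_class_counts
from .mortality import ExpandedMortality
from .params import FixedParameters, ThetaVector, curves_from_packed
from .state import PopulationState

SQRT2 = np.sqrt(2.0)


def hellinger(p, q) -> float:
    """Hellinger distance between two points of the 3-simplex, in [0, 1]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    for v in (p, q):
        if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-8:
            raise ValueError("arguments must lie on the probability simplex")
    return float(np.sqrt(((np.sqrt(p) - np.sqrt(q)) ** 2).sum()) / SQRT2)


@dataclass(frozen=True)
class SurveyPrevalence:
    """Observed status prevalences by year and survey age class.

    years: (T,) consecutive calendar years; p: (T, n_classes, 3) proportions
    (never, current, former); n: (T, n_classes) survey denominators.  Missing
    cells are NaN rows in ``p`` with n = 0.
    """

    years: np.ndarray
    p: np.ndarray
    n: np.ndarray

    def __post_init__(self):
        years = np.asarray(self.years, dtype=int)
        p = np.asarray(self.p, dtype=float)
        n = np.asarray(self.n, dtype=float)
        T = len(years)
        if np.any(np.diff(years) != 1):
            raise ValueError("years must be consecutive")
        if p.shape != (T, grids.N_CLASSES, 3) or n.shape != (T, grids.N_CLASSES):
            raise ValueError("prevalence arrays do not match (T, n_classes)")
        obs = ~np.isnan(p).any(axis=2)
        if np.any(p[obs] < 0) or np.any(np.abs(p[obs].sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("observed prevalences must sum to 1 per cell")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "n", n)

    def window(self, first: int, last: int) -> "SurveyPrevalence":
        if first < self.years[0] or last > self.years[-1] or first > last:
            raise ValueError(f"window {first}:{last} outside coverage "
                             f"{self.years[0]}:{self.years[-1]}")
        sel = (self.years >= first) & (self.years <= last)
        return SurveyPrevalence(self.years[sel], self.p[sel], self.n[sel])


@dataclass
class CalibrationProblem:
    """Everything needed to evaluate Obj(theta) for one sex."""

    observed: SurveyPrevalence
    initial: PopulationState
    fixed: FixedParameters
    mortality: ExpandedMortality

    def __post_init__(self):
        if self.initial.t != int(self.observed.years[0]):
            raise ValueError("initial state year must match the first observed year")
        self._horizon = len(self.observed.years) - 1
        self._obs_ok = ~np.isnan(self.observed.p).any(axis=2)
        self._sqrt_obs = np.sqrt(np.where(np.isnan(self.observed.p), 0.0, self.observed.p))

    def model_prevalence(self, theta: ThetaVector) -> np.ndarray:
        """(T, n_classes, 3) model-implied prevalences (NaN where class empty)."""
        counts = simulate_class_counts(
            self.initial, theta, self.mortality, self.fixed, self._horizon)
        denom = counts.sum(axis=2, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, counts / denom, np.nan)

    def _mean_hellinger(self, pm: np.ndarray) -> float:
        ok = self._obs_ok & ~np.isnan(pm).any(axis=2)
        if not ok.any():
            raise RuntimeError("no valid (year, class) cells to compare")
        diff = np.sqrt(np.where(ok[:, :, None], pm, 0.0)) - self._sqrt_obs
        h = np.sqrt((diff ** 2).sum(axis=2)) / SQRT2
        return float(h[ok].mean())

    def objective(self, theta: ThetaVector) -> float:
        return self._mean_hellinger(self.model_prevalence(theta))

    def objective_packed(self, x: np.ndarray) -> float:
        """Validation-free fast path used by the optimizer inner loop."""
        gamma, eps, eta = curves_from_packed(x)
        counts = _classcounts_kernel(
            self.initial.N, self.initial.C, self.initial.F,
            self.mortality.delta_N, self.mortality.delta_C, self.mortality.delta_F,
            gamma, eps, eta, self.fixed.pi, float(self.fixed.nu),
            self._horizon, _CLS_INDEX, grids.N_CLASSES)
        denom = counts.sum(axis=2, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pm = np.where(denom > 0, counts / denom, np.nan)
        return self._mean_hellinger(pm)


@dataclass
class StartTrace:
    start: np.ndarray
    value: float
    iterations: int
    converged: bool


@dataclass
class CalibrationResult:
    theta_hat: ThetaVector
    objective_value: float
    traces: list[StartTrace] = field(default_factory=list)
    window: tuple[int, int] | None = None
    weakly_identified: bool = False


def sample_start(rng: np.random.Generator) -> np.ndarray:
    """One optimizer start in packed coordinates.

    Intercepts uniform on [-4, 0] (probability scale roughly 2%..50%), the
    remaining spline coefficients uniform on [-2, 2], log omega uniform on
    [-2, 1].
    """
    psi = np.concatenate([rng.uniform(-4, 0, 1), rng.uniform(-2, 2, 3)])
    phi = np.concatenate([rng.uniform(-4, 0, 1), rng.uniform(-2, 2, 3)])
    logw = rng.uniform(-2, 1, 2)
    return np.concatenate([psi, phi, logw])


def _local_search(problem, x0, maxiter, ftol, n_restarts=2, simplex_scale=None):
    """Nelder-Mead with restart polish: re-simplex at the incumbent until the
    improvement per round drops below ftol.

    ``simplex_scale`` sets the radius of the initial simplex (used to make
    warm starts converge in few iterations, e.g. inside the bootstrap).
    """
    best = None
    x = np.asarray(x0, dtype=float)
    iters = 0
    for _ in range(n_restarts + 1):
        options = {"maxiter": maxiter, "fatol": ftol, "xatol": 1e-6}
        if simplex_scale is not None:
            simplex = np.vstack([x, x + simplex_scale * np.eye(len(x))])
            options["initial_simplex"] = simplex
        res = minimize(problem.objective_packed, x, method="Nelder-Mead",
                       options=options)
        iters += res.nit
        if best is not None and best - res.fun < ftol:
            best, x = min(best, res.fun), res.x if res.fun < best else x
            break
        best, x = res.fun, res.x
    return x, float(best), iters


def calibrate(
    problem: CalibrationProblem,
    n_starts: int = 20,
    seed: int = 0,
    maxiter: int = 2000,
    ftol: float = 1e-8,
    n_restarts: int = 2,
    extra_starts: list[np.ndarray] | None = None,
    simplex_scale: float | None = None,
) -> CalibrationResult:
    """Multi-start minimization of the Hellinger objective; argmin across starts.

    ``extra_starts`` are tried in addition to the ``n_starts`` sampled ones
    (used e.g. to warm-start bootstrap replicates at the point fit).
    Deterministic for a given seed.
    """
    if n_starts < 1 and not extra_starts:
        raise ValueError("need at least one start")
    rng = np.random.default_rng(seed)
    starts = [sample_start(rng) for _ in range(n_starts)]
    if extra_starts:
        starts = [np.asarray(s, dtype=float) for s in extra_starts] + starts

    traces = []
    best_x, best_val = None, np.inf
    for x0 in starts:
        try:
            x, val, nit = _local_search(problem, x0, maxiter, ftol, n_restarts,
                                        simplex_scale)
        except (FloatingPointError, RuntimeError):
            traces.append(StartTrace(start=x0, value=np.nan, iterations=0, converged=False))
            continue
        traces.append(StartTrace(start=x0, value=val, iterations=nit, converged=True))
        if val < best_val:
            best_x, best_val = x, val
    if best_x is None:
        raise RuntimeError(f"all {len(starts)} optimizer starts failed; traces: {traces}")

    years = problem.observed.years
    return CalibrationResult(
        theta_hat=ThetaVector.unpack(best_x),
        objective_value=best_val,
        traces=traces,
        window=(int(years[0]), int(years[-1])),
        weakly_identified=len(years) < 2,
    )


def calibrate_window(
    observed: SurveyPrevalence,
    initial: PopulationState,
    fixed: FixedParameters,
    mortality: ExpandedMortality,
    years: tuple[int, int],
    **kwargs,
) -> CalibrationResult:
    """Calibrate on a sub-window of the observed period.

    The initial state must refer to the first year of the window (for the
    second-period re-calibration it is rebuilt from that year's surveys).
    """
    first, last = years
    data = observed.window(first, last)
    problem = CalibrationProblem(data, initial, fixed, mortality)
    return calibrate(problem, **kwargs)
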