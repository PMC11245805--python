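"""Variance-based global sensitivity analysis (total-order Sobol indices).

The inputs are grouped into blocks — the starting-curve coefficients psi, the
quitting-curve coefficients phi, the relapse parameters omega, the intensity
mix pi of new smokers, the annual births nu, and the relative-risk tables —
treated as mutually independent.  For each block the total variance index

    S_tot_i = E[Var(Y | X_~i)] / Var(Y)

is estimated with the Jansen formula on a quasi-random (scrambled Sobol)
design: base matrices A and B plus one hybrid matrix per block in which only
that block's columns are taken from B.  The model output Y is the mean
Hellinger distance between observed and simulated prevalences, so the indices
measure how much each input drives the calibration discrepancy.  Population
mortality is treated as known and is not an input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .calibration import CalibrationProblem
from .mortality import RelativeRisks, expand_mortality
from .params import ThetaVector

DEFAULT_BLOCKS = ("psi", "phi", "omega", "pi", "nu", "rr")


@dataclass(frozen=True)
class UniformBlock:
    """Independent uniforms on [low_j, high_j] for each dimension of the block."""

    low: np.ndarray
    high: np.ndarray
    log_scale: bool = False

    def __post_init__(self):
        low = np.atleast_1d(np.asarray(self.low, dtype=float))
        high = np.atleast_1d(np.asarray(self.high, dtype=float))
        if low.shape != high.shape or np.any(high <= low):
            raise ValueError("invalid uniform bounds")
        object.__setattr__(self, "low", low)
        object.__setattr__(self, "high", high)

    @property
    def dim(self) -> int:
        return len(self.low)

    def transform(self, u: np.ndarray) -> np.ndarray:
        x = self.low + (self.high - self.low) * u
        return np.exp(x) if self.log_scale else x


@dataclass(frozen=True)
class SimplexBlock:
    """Dirichlet(kappa * center) via inverse-CDF gamma transform of uniforms.

    Independent Gamma(alpha_k) variates normalized to the simplex are exactly
    Dirichlet; applying the gamma inverse CDF to quasi-uniform columns keeps
    the low-discrepancy structure.
    """

    center: np.ndarray
    kappa: float = 100.0

    @property
    def dim(self) -> int:
        return len(self.center)

    def transform(self, u: np.ndarray) -> np.ndarray:
        alpha = np.asarray(self.center, dtype=float) * self.kappa
        u = np.clip(u, 1e-12, 1 - 1e-12)
        g = stats.gamma.ppf(u, alpha[None, :])
        return g / g.sum(axis=1, keepdims=True)


@dataclass
class InputDistributionSet:
    """One distribution per input block, mutually independent."""

    blocks: dict[str, UniformBlock | SimplexBlock]

    @property
    def dim(self) -> int:
        return sum(b.dim for b in self.blocks.values())

    def slices(self) -> dict[str, slice]:
        out, start = {}, 0
        for name, b in self.blocks.items():
            out[name] = slice(start, start + b.dim)
            start += b.dim
        return out

    def transform(self, U: np.ndarray) -> dict[str, np.ndarray]:
        return {name: b.transform(U[:, sl])
                for (name, b), sl in zip(self.blocks.items(), self.slices().values())}


def default_distributions(fixed, rr: RelativeRisks) -> InputDistributionSet:
    """Defaults: calibration start-box uniforms for theta, +/-25% uniforms for
    nu and the RR scale factors, Dirichlet spread around the nominal pi."""
    spline = UniformBlock(low=np.array([-4, -2, -2, -2]), high=np.array([0, 2, 2, 2]))
    return InputDistributionSet(blocks={
        "psi": spline,
        "phi": spline,
        "omega": UniformBlock(low=np.array([-2, -2]), high=np.array([1, 1]),
                              log_scale=True),
        "pi": SimplexBlock(center=fixed.pi),
        "nu": UniformBlock(low=np.array([0.75 * fixed.nu]),
                           high=np.array([1.25 * fixed.nu])),
        # one multiplicative factor per status applied to the whole RR table
        "rr": UniformBlock(low=np.array([0.75, 0.75]), high=np.array([1.25, 1.25])),
    })


def quasi_random_design(dists: InputDistributionSet, K: int, seed: int = 0
                        ) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Scrambled-Sobol base matrices A, B and the per-block hybrids A_B^(i).

    A and B are the two halves of a single 2d-dimensional low-discrepancy
    sample (the usual way to obtain independent base matrices); in A_B^(i)
    the columns of block i come from B and all others from A.  Matrices are
    returned in uniform [0,1) coordinates.
    """
    if K < 8:
        raise ValueError("K must be at least 8")
    d = dists.dim
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # non-power-of-2 sample size
        U = qmc.Sobol(2 * d, scramble=True, seed=seed).random(K)
    A, B = U[:, :d], U[:, d:]
    hybrids = {}
    for name, sl in dists.slices().items():
        AB = A.copy()
        AB[:, sl] = B[:, sl]
        hybrids[name] = AB
    return A, B, hybrids


def total_order_indices(Y_A: np.ndarray, Y_B: np.ndarray,
                        Y_AB: dict[str, np.ndarray],
                        n_boot: int = 200, seed: int = 0) -> pd.DataFrame:
    """Jansen total-index estimator with bootstrap-over-rows standard errors.

    S_tot_i = sum((Y_A - Y_AB_i)^2) / (2 K Var(Y)), Var(Y) from (Y_A, Y_B).
    """
    Y_A = np.asarray(Y_A, dtype=float)
    Y_B = np.asarray(Y_B, dtype=float)
    K = len(Y_A)
    var = np.var(np.concatenate([Y_A, Y_B]))
    if var <= 0:
        raise ValueError("output is constant; total indices undefined")
    rng = np.random.default_rng(seed)
    idx_boot = rng.integers(0, K, size=(n_boot, K))
    rows = []
    for name, y_ab in Y_AB.items():
        y_ab = np.asarray(y_ab, dtype=float)
        if len(y_ab) != K:
            raise ValueError("evaluation vectors must have equal length")
        d2 = (Y_A - y_ab) ** 2
        s = d2.mean() / (2.0 * var)
        reps = np.empty(n_boot)
        for r in range(n_boot):
            i = idx_boot[r]
            v = np.var(np.concatenate([Y_A[i], Y_B[i]]))
            reps[r] = d2[i].mean() / (2.0 * v) if v > 0 else np.nan
        rows.append({"input": name, "S_tot": float(s),
                     "se": float(np.nanstd(reps)), "K": K})
    return pd.DataFrame(rows)


def first_order_indices(Y_A: np.ndarray, Y_B: np.ndarray,
                        Y_AB: dict[str, np.ndarray]) -> dict[str, float]:
    """Jansen first-order estimator on the same design (internal diagnostic:
    S_i <= S_tot_i up to Monte-Carlo error)."""
    Y_A = np.asarray(Y_A, dtype=float)
    Y_B = np.asarray(Y_B, dtype=float)
    var = np.var(np.concatenate([Y_A, Y_B]))
    return {name: float(1.0 - ((Y_B - np.asarray(y)) ** 2).mean() / (2.0 * var))
            for name, y in Y_AB.items()}


@dataclass
class GsaResult:
    table: pd.DataFrame
    first_order: dict[str, float]
    K: int
    n_runs: int
    var_y: float
    failed_rows: int = 0


def _evaluate_rows(problem: CalibrationProblem, data_sex, X: dict[str, np.ndarray],
                   K: int) -> np.ndarray:
    """Hellinger objective for each design row (full pipeline per row)."""
    from .params import FixedParameters  # local to avoid cycle at import time

    Y = np.full(K, np.nan)
    base_fixed = data_sex.fixed
    for r in range(K):
        try:
            theta = ThetaVector(psi=X["psi"][r], phi=X["phi"][r], omega=X["omega"][r])
            rr = RelativeRisks(rr_current=data_sex.rr.rr_current * X["rr"][r, 0],
                               rr_former=1.0 + (data_sex.rr.rr_former - 1.0) * X["rr"][r, 1])
            fixed = FixedParameters(pi=X["pi"][r], nu=float(X["nu"][r, 0]),
                                    intensity_dist=base_fixed.intensity_dist,
                                    cessation_dist=base_fixed.cessation_dist)
            mort = expand_mortality(problem.mortality.delta_N, rr)
            prob_r = CalibrationProblem(problem.observed, problem.initial, fixed, mort)
            Y[r] = prob_r.objective(theta)
        except (ValueError, RuntimeError):
            pass  # row stays NaN and is counted as failed
    return Y


def run_gsa(data_sex, K: int = 10_000, seed: int = 0,
            dists: InputDistributionSet | None = None,
            max_failures: float = 0.01) -> GsaResult:
    """Total-order indices of the Hellinger objective for one sex's data.

    Cost is K * (n_blocks + 2) model runs.  The never-smoker mortality
    schedule is estimated once from the observed data; RR variations rescale
    the excess-risk expansion on top of it.
    """
    from .pipeline import build_problem

    problem = build_problem(data_sex)
    if dists is None:
        dists = default_distributions(data_sex.fixed, data_sex.rr)
    A, B, hybrids = quasi_random_design(dists, K, seed=seed)

    def evaluate(U):
        return _evaluate_rows(problem, data_sex, dists.transform(U), len(U))

    Y_A = evaluate(A)
    Y_B = evaluate(B)
    Y_AB = {name: evaluate(M) for name, M in hybrids.items()}

    # drop rows where any evaluation failed so the estimator stays paired
    ok = ~np.isnan(Y_A) & ~np.isnan(Y_B)
    for y in Y_AB.values():
        ok &= ~np.isnan(y)
    failed = int(K - ok.sum())
    if failed > max_failures * K:
        raise RuntimeError(f"{failed} of {K} GSA rows failed; aborting")
    Y_A, Y_B = Y_A[ok], Y_B[ok]
    Y_AB = {name: y[ok] for name, y in Y_AB.items()}

    table = total_order_indices(Y_A, Y_B, Y_AB, seed=seed)
    first = first_order_indices(Y_A, Y_B, Y_AB)
    var_y = float(np.var(np.concatenate([Y_A, Y_B])))
    return GsaResult(table=table, first_order=first, K=K,
                     n_runs=K * (len(dists.blocks) + 2), var_y=var_y,
                     failed_rows=failed)
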