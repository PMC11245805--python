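"""Rolling-origin cross-validation of predictive performance, scored by MAPE.

The first split trains on the first three observed years; each subsequent
split extends the training window by one year.  Every split forecasts the
``q`` years after its training end; the last training window ends ``q`` years
before the end of the observed period.  Forecast errors are absolute
percentage errors on the class prevalences, averaged over every
(split, year, class, status) cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import calibrate
from .pipeline import SexData, build_problem

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RollingSplit:
    train_years: tuple[int, int]
    test_years: tuple[int, int]

    def __post_init__(self):
        if self.train_years[1] - self.train_years[0] + 1 < 3:
            raise ValueError("training window must span at least 3 years")
        if self.test_years[0] != self.train_years[1] + 1:
            raise ValueError("test window must start right after training")


def rolling_splits(period: tuple[int, int], q: int, initial_train: int = 3
                   ) -> list[RollingSplit]:
    """All expanding-window splits for the period with forecast horizon ``q``."""
    first, last = period
    if q < 1:
        raise ValueError("horizon q must be >= 1")
    if last - first + 1 < initial_train + q:
        raise ValueError(f"period too short for initial_train={initial_train}, q={q}")
    splits = []
    for train_end in range(first + initial_train - 1, last - q + 1):
        splits.append(RollingSplit((first, train_end), (train_end + 1, train_end + q)))
    return splits


def mape(observed: np.ndarray, expected: np.ndarray) -> float:
    """100/n * sum(|O - E| / O); cells with O = 0 are excluded (logged)."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError("observed and expected must have the same shape")
    ok = np.isfinite(observed) & np.isfinite(expected) & (observed > 0)
    n_excl = int(observed.size - ok.sum())
    if n_excl:
        log.info("mape: excluded %d zero/invalid observed cells", n_excl)
    if not ok.any():
        raise ValueError("no valid cells for MAPE")
    return float(100.0 * (np.abs(observed[ok] - expected[ok]) / observed[ok]).mean())


def _absolute_percentage_errors(observed, expected) -> np.ndarray:
    ok = np.isfinite(observed) & np.isfinite(expected) & (observed > 0)
    return 100.0 * np.abs(observed[ok] - expected[ok]) / observed[ok]


def cross_validate(
    data: SexData,
    horizons: tuple[int, ...] = (3, 6, 9, 12),
    n_starts: int = 10,
    seed: int = 0,
    maxiter: int = 1000,
    extra_start=None,
    **calib_kwargs,
) -> tuple[dict[int, float], pd.DataFrame]:
    """Grand MAPE per horizon plus a per-split detail table.

    For each split the two-step estimation is redone on the training window
    (window-consistent mortality), the fitted model is projected over the test
    years, and absolute percentage errors are pooled over all cells with equal
    weight.  ``extra_start`` (packed theta) is offered to every split's
    optimizer in addition to its sampled starts.
    """
    years = data.observed.years
    period = (int(years[0]), int(years[-1]))
    extra = [np.asarray(extra_start, dtype=float)] if extra_start is not None else None

    rows = []
    grand: dict[int, float] = {}
    # splits with the same training window share one calibration
    fits: dict[int, object] = {}
    for q in horizons:
        errors = []
        for split in rolling_splits(period, q):
            train_end = split.train_years[1]
            if train_end not in fits:
                problem = build_problem(data, window=(period[0], train_end))
                try:
                    fit_te = calibrate(
                        problem, n_starts=n_starts, seed=seed + train_end,
                        maxiter=maxiter, extra_starts=extra, **calib_kwargs)
                    fits[train_end] = (fit_te, problem.mortality)
                except RuntimeError:
                    log.warning("cv: calibration failed for training end %d", train_end)
                    fits[train_end] = None
            if fits[train_end] is None:
                continue
            fit, train_mortality = fits[train_end]
            # project with train-window mortality from the shared baseline state
            full = build_problem(data, mortality=train_mortality)
            pm = full.model_prevalence(fit.theta_hat)
            t0 = split.test_years[0] - period[0]
            t1 = split.test_years[1] - period[0] + 1
            obs = data.observed.p[t0:t1]
            pred = pm[t0:t1]
            ape = _absolute_percentage_errors(obs, pred)
            errors.append(ape)
            rows.append({
                "q": q, "train_start": split.train_years[0], "train_end": train_end,
                "test_start": split.test_years[0], "test_end": split.test_years[1],
                "objective": fit.objective_value, "n_cells": ape.size,
                "mape": float(ape.mean()) if ape.size else np.nan,
            })
        pooled = np.concatenate(errors) if errors else np.array([])
        grand[q] = float(pooled.mean()) if pooled.size else np.nan
    return grand, pd.DataFrame(rows)
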