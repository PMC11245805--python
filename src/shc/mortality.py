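"""First estimation step: compartment-specific death risks.

Population mortality delta_pop(t; a) mixes never, current and former smokers.
Given observed status prevalences (by survey age class) and literature
relative risks, the never-smoker risk is back-calculated as

    delta_N(t; a) = delta_pop(t; a) / (p_N + RR_C * p_C + RR_F * p_F),

with each single age using the prevalence of its enclosing age class, then
averaged over the years of the calibration window.  Current/former risks are
re-expanded by intensity- and cessation-specific relative risks:
delta_Ci(a) = RR_Ci * delta_N(a), delta_Fi(a, c) = RR_Fi(c) * delta_N(a).
Ages 0-13 hold no smokers, so delta_N = delta_pop there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import grids

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RelativeRisks:
    """RR of death versus never smokers.

    rr_current: (3,) by intensity.
    rr_former: (3, L) by intensity and years since cessation; tables shorter
        than the cessation axis carry their last value forward.
    """

    rr_current: np.ndarray
    rr_former: np.ndarray

    def __post_init__(self):
        rc = np.atleast_1d(np.asarray(self.rr_current, dtype=float))
        rf = np.atleast_2d(np.asarray(self.rr_former, dtype=float))
        if rc.shape != (grids.N_INT,) or rf.shape[0] != grids.N_INT:
            raise ValueError("RR tables must cover the three intensity levels")
        if np.any(rc < 0) or np.any(rf < 0):
            raise ValueError("relative risks must be non-negative")
        object.__setattr__(self, "rr_current", rc)
        object.__setattr__(self, "rr_former", rf)

    def rr_former_full(self) -> np.ndarray:
        """(3, C_MAX) former-smoker RR with the last column carried forward."""
        L = self.rr_former.shape[1]
        if L >= grids.C_MAX:
            return self.rr_former[:, : grids.C_MAX]
        pad = np.repeat(self.rr_former[:, -1:], grids.C_MAX - L, axis=1)
        return np.hstack([self.rr_former, pad])

    def aggregate(self, intensity_dist: np.ndarray, cessation_dist: np.ndarray
                  ) -> tuple[float, float]:
        """Prevalence-weighted aggregate (RR_C, RR_F) used in the back-calculation."""
        w_i = np.asarray(intensity_dist, dtype=float)
        w_c = np.asarray(cessation_dist, dtype=float)[: grids.C_MAX]
        w_c = w_c / w_c.sum()
        rr_c = float(w_i @ self.rr_current)
        rr_f = float(w_i @ (self.rr_former_full()[:, : len(w_c)] @ w_c))
        return rr_c, rr_f


@dataclass(frozen=True)
class ExpandedMortality:
    """Per-compartment annual death probabilities on the model grids."""

    delta_N: np.ndarray            # (101,)
    delta_C: np.ndarray            # (3, 101)
    delta_F: np.ndarray            # (3, 101, C_MAX)

    def __post_init__(self):
        shapes = {
            "delta_N": (self.delta_N, (grids.N_AGES,)),
            "delta_C": (self.delta_C, (grids.N_INT, grids.N_AGES)),
            "delta_F": (self.delta_F, (grids.N_INT, grids.N_AGES, grids.C_MAX)),
        }
        for name, (arr, want) in shapes.items():
            arr = np.ascontiguousarray(arr, dtype=float)
            if arr.shape != want:
                raise ValueError(f"{name} must have shape {want}, got {arr.shape}")
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{name} must hold probabilities in [0, 1]")
            object.__setattr__(self, name, arr)


def never_smoker_mortality_year(
    delta_pop: np.ndarray,
    class_prevalence: np.ndarray,
    rr_c: float,
    rr_f: float,
) -> np.ndarray:
    """delta_N(t; a) for one year from delta_pop (by single age) and class prevalences."""
    delta_pop = np.asarray(delta_pop, dtype=float)
    p = np.asarray(class_prevalence, dtype=float)
    if delta_pop.shape != (grids.N_AGES,):
        raise ValueError("delta_pop must cover ages 0..100")
    if p.shape != (grids.N_CLASSES, 3):
        raise ValueError("class_prevalence must be (n_classes, 3)")
    if rr_c < 0 or rr_f < 0:
        raise ValueError("relative risks must be non-negative")
    cls = grids.age_class_index()
    denom = np.ones(grids.N_AGES)
    smokers = cls >= 0
    pk = p[cls[smokers]]
    denom[smokers] = pk[:, 0] + rr_c * pk[:, 1] + rr_f * pk[:, 2]
    if np.any(denom <= 0):
        raise ValueError("zero denominator in the never-smoker back-calculation")
    return delta_pop / denom


def average_over_years(delta_by_year: np.ndarray) -> np.ndarray:
    """Unweighted mean over the year axis (axis 0)."""
    arr = np.asarray(delta_by_year, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("need at least one year of delta_N(t; a)")
    return arr.mean(axis=0)


def expand_mortality(delta_n: np.ndarray, rr: RelativeRisks) -> ExpandedMortality:
    """delta_Ci(a) and delta_Fi(a, c) from delta_N(a), clipped into [0, 1]."""
    delta_n = np.asarray(delta_n, dtype=float)
    dc = rr.rr_current[:, None] * delta_n[None, :]
    df = rr.rr_former_full()[:, None, :] * delta_n[None, :, None]
    n_clip = int((dc > 1).sum() + (df > 1).sum())
    if n_clip:
        log.warning("expand_mortality: clipped %d risks above 1", n_clip)
    return ExpandedMortality(
        delta_N=np.clip(delta_n, 0.0, 1.0),
        delta_C=np.clip(dc, 0.0, 1.0),
        delta_F=np.clip(df, 0.0, 1.0),
    )


def estimate_mortality(
    delta_pop: np.ndarray,
    observed_prevalence: np.ndarray,
    rr: RelativeRisks,
    intensity_dist: np.ndarray,
    cessation_dist: np.ndarray,
    years: slice | None = None,
) -> ExpandedMortality:
    """Full first step over a window of years.

    delta_pop: (T, 101) population risks per year; observed_prevalence:
    (T, n_classes, 3).  ``years`` restricts the averaging window.
    """
    delta_pop = np.asarray(delta_pop, dtype=float)
    obs = np.asarray(observed_prevalence, dtype=float)
    if years is not None:
        delta_pop = delta_pop[years]
        obs = obs[years]
    if delta_pop.shape[0] != obs.shape[0]:
        raise ValueError("delta_pop and prevalence must cover the same years")
    rr_c, rr_f = rr.aggregate(intensity_dist, cessation_dist)
    per_year = np.stack([
        never_smoker_mortality_year(delta_pop[t], obs[t], rr_c, rr_f)
        for t in range(delta_pop.shape[0])
    ])
    return expand_mortality(average_over_years(per_year), rr)
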