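"""Population state: compartment sizes on the (age, intensity, cessation) grid."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import grids


@dataclass
class PopulationState:
    """Compartment sizes in one model year.

    N[a]            never smokers by single age 0..100
    C[i, a]         current smokers by intensity and age
    F[i, a, c]      former smokers by intensity, age, years since cessation
    deaths_*        deaths occurred during the PREVIOUS model year (annual, not
                    cumulative), indexed by compartment of origin and the age at
                    which the person was exposed
    exited          people who completed their year at age 100 and left the grid
    """

    t: int
    sex: str = "total"
    N: np.ndarray = field(default_factory=lambda: np.zeros(grids.N_AGES))
    C: np.ndarray = field(default_factory=lambda: np.zeros((grids.N_INT, grids.N_AGES)))
    F: np.ndarray = field(
        default_factory=lambda: np.zeros((grids.N_INT, grids.N_AGES, grids.C_MAX))
    )
    deaths_N: np.ndarray = field(default_factory=lambda: np.zeros(grids.N_AGES))
    deaths_C: np.ndarray = field(default_factory=lambda: np.zeros((grids.N_INT, grids.N_AGES)))
    deaths_F: np.ndarray = field(
        default_factory=lambda: np.zeros((grids.N_INT, grids.N_AGES, grids.C_MAX))
    )
    exited: float = 0.0

    def alive(self) -> float:
        return float(self.N.sum() + self.C.sum() + self.F.sum())

    def deaths_total(self) -> float:
        return float(self.deaths_N.sum() + self.deaths_C.sum() + self.deaths_F.sum())

    def alive_by_age(self) -> np.ndarray:
        return self.N + self.C.sum(axis=0) + self.F.sum(axis=(0, 2))

    def validate(self) -> None:
        for name, arr in (("N", self.N), ("C", self.C), ("F", self.F)):
            if np.any(~np.isfinite(arr)) or np.any(arr < -1e-9):
                raise ValueError(f"compartment {name} has negative or non-finite entries")
        bad = ~grids.admissible_cessation_mask()
        if np.any(np.abs(self.F[:, bad]) > 1e-9):
            raise ValueError("former smokers present at inadmissible (age, cessation) cells")
        if np.any(np.abs(self.C[:, 0]) > 0) or np.any(np.abs(self.F[:, 0]) > 0):
            raise ValueError("newborns must all be never smokers")

    def copy(self) -> "PopulationState":
        return PopulationState(
            t=self.t, sex=self.sex, N=self.N.copy(), C=self.C.copy(), F=self.F.copy(),
            deaths_N=self.deaths_N.copy(), deaths_C=self.deaths_C.copy(),
            deaths_F=self.deaths_F.copy(), exited=self.exited,
        )


def _cessation_weights(cessation_dist: np.ndarray, age: int) -> np.ndarray:
    """Renormalize the cessation distribution onto the admissible c range for ``age``."""
    w = np.zeros(grids.C_MAX)
    cmax = grids.max_cessation(age)
    if cmax < 0:
        return w  # no former smokers possible at this age
    mass = cessation_dist[: cmax + 1]
    total = mass.sum()
    if total <= 0:  # degenerate tail: put everything at c = 0
        w[0] = 1.0
    else:
        w[: cmax + 1] = mass / total
    return w


def init_state(
    baseline_pop: np.ndarray,
    status_prevalence: np.ndarray,
    intensity_dist: np.ndarray,
    cessation_dist: np.ndarray,
    year: int,
    sex: str = "total",
) -> PopulationState:
    """Build the baseline state from population counts and survey prevalences.

    baseline_pop: counts by single age (length 101).
    status_prevalence: (n_classes, 3) proportions (never, current, former) per
        survey age class; ages below 14 are all never smokers.
    """
    baseline_pop = np.asarray(baseline_pop, dtype=float)
    status_prevalence = np.asarray(status_prevalence, dtype=float)
    if baseline_pop.shape != (grids.N_AGES,):
        raise ValueError(f"baseline_pop must cover ages 0..{grids.A_MAX}")
    if status_prevalence.shape != (grids.N_CLASSES, 3):
        raise ValueError("status_prevalence must be (n_classes, 3)")
    if np.any(status_prevalence < 0) or np.any(
        np.abs(status_prevalence.sum(axis=1) - 1.0) > 1e-6
    ):
        raise ValueError("status prevalences must sum to 1 per age class")

    cessation_dist = np.asarray(cessation_dist, dtype=float)
    if len(cessation_dist) < grids.C_MAX:
        cessation_dist = np.pad(cessation_dist, (0, grids.C_MAX - len(cessation_dist)))
    intensity_dist = np.asarray(intensity_dist, dtype=float)

    st = PopulationState(t=year, sex=sex)
    cls = grids.age_class_index()
    child = cls < 0
    adult = ~child
    p = np.zeros((grids.N_AGES, 3))
    p[child, 0] = 1.0
    p[adult] = status_prevalence[cls[adult]]

    # ages below 21 cannot hold former smokers (quitting starts at 20).  Within
    # each class the former-smoker mass is shifted onto the admissible ages,
    # compensated from the never compartment, so the class-aggregated
    # prevalence still reproduces the survey cell exactly.  Classes entirely
    # below 21 fold their former mass into never.
    young = grids.AGES < grids.EPSILON_MIN_AGE + 1
    for k in range(grids.N_CLASSES):
        in_class = cls == k
        adm = in_class & ~young
        p_class = baseline_pop[in_class].sum()
        p_adm = baseline_pop[adm].sum()
        pf = status_prevalence[k, 2]
        if pf == 0 or p_class == 0:
            continue
        if p_adm == 0:
            p[in_class, 0] += pf
            p[in_class, 2] = 0.0
            continue
        w = p_class / p_adm
        fold = in_class & young
        p[fold, 0] += pf
        p[fold, 2] = 0.0
        p[adm, 2] = pf * w
        p[adm, 0] -= pf * (w - 1.0)
        if np.any(p[adm, 0] < 0):
            raise ValueError(
                f"class {grids.AGE_CLASS_LABELS[k]}: former-smoker share too "
                "large to place on ages >= 21 without negative never counts")

    # cessation weights renormalized per age onto the admissible c range
    mask = grids.admissible_cessation_mask()
    W = np.where(mask, cessation_dist[None, :grids.C_MAX], 0.0)
    rowsum = W.sum(axis=1)
    degenerate = (rowsum <= 0) & mask.any(axis=1)
    W[degenerate, 0] = 1.0  # admissible range holds no mass: put it at c = 0
    rowsum = W.sum(axis=1)
    W[rowsum > 0] /= rowsum[rowsum > 0, None]

    st.N[:] = baseline_pop * p[:, 0]
    st.C[:] = intensity_dist[:, None] * (baseline_pop * p[:, 1])[None, :]
    st.F[:] = intensity_dist[:, None, None] * (baseline_pop * p[:, 2])[None, :, None] * W[None, :, :]
    st.C[:, child] = 0.0
    return st


def aggregate_prevalence(state: PopulationState) -> tuple[np.ndarray, np.ndarray]:
    """Survey-class prevalences of (never, current, former) and denominators.

    Single ages are aggregated population-weighted within each class; classes
    with nobody alive get NaN prevalences and denominator 0.
    """
    cls = grids.age_class_index()
    n_by_age = state.N
    c_by_age = state.C.sum(axis=0)
    f_by_age = state.F.sum(axis=(0, 2))
    p = np.full((grids.N_CLASSES, 3), np.nan)
    denom = np.zeros(grids.N_CLASSES)
    for k in range(grids.N_CLASSES):
        sel = cls == k
        counts = np.array([n_by_age[sel].sum(), c_by_age[sel].sum(), f_by_age[sel].sum()])
        denom[k] = counts.sum()
        if denom[k] > 0:
            p[k] = counts / denom[k]
    return p, denom
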