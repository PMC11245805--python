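"""Self-consistent synthetic input bundles for the whole pipeline.

The generator emulates the data landscape the model is built for — yearly
status prevalences by sex and ten age classes with survey denominators,
population mortality by single age, a baseline population, constant births,
literature relative risks, and baseline intensity / time-since-cessation
distributions — by running a known ground-truth model forward and drawing
survey observations as multinomial noise at realistic cell sizes.

Ground truth is constructed so that every estimation stage has an exact
recovery limit: the true starting/quitting curves are least-squares
projections of smooth targets onto the model's own spline family (hence
exactly representable), and population mortality is assembled from the
never-smoker schedule and the aggregate relative risks through the same
mixing identity the first estimation step inverts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logit

from . import grids
from .calibration import SurveyPrevalence
from .dynamics import simulate_class_counts
from .mortality import ExpandedMortality, RelativeRisks, expand_mortality
from .params import (EPSILON_SPLINE, GAMMA_SPLINE, FixedParameters, ThetaVector,
                     transition_curves)
from .splines import fit_spline_to_curve
from .state import PopulationState, init_state

SEXES = ("male", "female")
DEFAULT_YEARS = (1993, 2019)

# baseline (never, current, former) proportions by survey class, male column
# shapes roughly matching an Italian region in the early 1990s
_BASE_PREV_MALE = np.array([
    [0.90, 0.10, 0.00],   # quitting starts at 20: no former smokers below 20-24
    [0.76, 0.24, 0.00],
    [0.55, 0.36, 0.09],
    [0.42, 0.40, 0.18],
    [0.36, 0.38, 0.26],
    [0.31, 0.36, 0.33],
    [0.29, 0.33, 0.38],
    [0.28, 0.29, 0.43],
    [0.30, 0.22, 0.48],
    [0.35, 0.12, 0.53],
])
_BASE_PREV_FEMALE = np.array([
    [0.92, 0.08, 0.00],
    [0.80, 0.20, 0.00],
    [0.64, 0.28, 0.08],
    [0.55, 0.30, 0.15],
    [0.52, 0.28, 0.20],
    [0.55, 0.25, 0.20],
    [0.60, 0.22, 0.18],
    [0.65, 0.18, 0.17],
    [0.72, 0.13, 0.15],
    [0.82, 0.06, 0.12],
])


@dataclass
class SexTruth:
    """Ground truth and generated inputs for one sex."""

    sex: str
    years: np.ndarray                    # observed calendar years
    theta: ThetaVector
    fixed: FixedParameters
    rr: RelativeRisks
    delta_n_true: np.ndarray             # (101,) never-smoker annual death risk
    mortality: ExpandedMortality
    baseline_pop: np.ndarray             # (101,) population on Jan 1 of years[0]
    baseline_prevalence: np.ndarray      # (n_classes, 3) noiseless at years[0]
    delta_pop: np.ndarray                # (T, 101) population death risk
    noiseless_prevalence: np.ndarray     # (T, n_classes, 3) model class prevalences

    def initial_state(self) -> PopulationState:
        return init_state(self.baseline_pop, self.baseline_prevalence,
                          self.fixed.intensity_dist, self.fixed.cessation_dist,
                          int(self.years[0]), sex=self.sex)


@dataclass
class TruthBundle:
    seed: int
    scale: float
    by_sex: dict[str, SexTruth]


def _population_age_profile(rng: np.random.Generator) -> np.ndarray:
    """Smooth plausible single-age population weights (flat-topped, old-age decline)."""
    a = grids.AGES.astype(float)
    shape = np.exp(-0.5 * ((a - 38.0) / 34.0) ** 2)
    shape *= 1.0 + 0.05 * np.sin(a / (7.0 + rng.uniform(0, 2)))  # mild cohort waviness
    return shape / shape.sum()


def _true_theta(rng: np.random.Generator, sex: str) -> ThetaVector:
    """Draw plausible transition curves and project them onto the spline family."""
    male = sex == "male"
    peak = rng.uniform(0.065, 0.095) if male else rng.uniform(0.045, 0.075)
    peak_age = rng.uniform(18.5, 21.5) if male else rng.uniform(18.0, 21.0)
    width = rng.uniform(3.2, 4.5)
    ages_g = np.arange(grids.GAMMA_MIN_AGE, grids.GAMMA_MAX_AGE + 1)
    gamma_target = 0.004 + peak * np.exp(-0.5 * ((ages_g - peak_age) / width) ** 2)
    psi = fit_spline_to_curve(GAMMA_SPLINE, ages_g, logit(gamma_target))

    eps_max = rng.uniform(0.22, 0.30) if male else rng.uniform(0.16, 0.26)
    mid = rng.uniform(58.0, 68.0)
    slope = rng.uniform(8.0, 12.0)
    ages_e = np.arange(grids.EPSILON_MIN_AGE, grids.A_MAX + 1)
    eps_target = 0.015 + eps_max / (1.0 + np.exp(-(ages_e - mid) / slope))
    phi = fit_spline_to_curve(EPSILON_SPLINE, ages_e, logit(eps_target))

    omega = np.array([rng.uniform(1.5, 2.5), rng.uniform(0.9, 1.5)])
    return ThetaVector(psi=psi, phi=phi, omega=omega)


def _true_delta_n(rng: np.random.Generator, sex: str) -> np.ndarray:
    """Gompertz-type never-smoker mortality, males slightly above females."""
    a = grids.AGES.astype(float)
    level = 3.2e-5 if sex == "male" else 2.2e-5
    level *= rng.uniform(0.9, 1.1)
    rate = level * np.exp(0.092 * a) + 2.0e-4 * np.exp(-a / 2.0)  # + infant component
    return -np.expm1(-rate)


def make_truth(seed: int = 0, scale: float = 1.0,
               years: tuple[int, int] = DEFAULT_YEARS,
               sexes: tuple[str, ...] = SEXES) -> TruthBundle:
    """Generate a complete ground-truth bundle, deterministically per seed.

    ``scale`` multiplies the baseline population and births (1.0 is roughly a
    1.7M-person region per sex); it does not affect the survey noise, which is
    governed by the cell sizes passed to :func:`simulate_surveys`.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    first, last = years
    year_grid = np.arange(first, last + 1)
    T = len(year_grid)
    by_sex = {}
    for s, sex in enumerate(sexes):
        rng = np.random.default_rng([seed, s])
        theta = _true_theta(rng, sex)
        delta_n = _true_delta_n(rng, sex)
        rr = RelativeRisks(
            rr_current=np.array([1.6, 2.1, 2.6]) * rng.uniform(0.95, 1.05),
            rr_former=1.0 + (np.array([1.6, 2.1, 2.6])[:, None] - 1.0)
            * np.exp(-0.15 * np.arange(16)[None, :]) * rng.uniform(0.95, 1.05),
        )
        pi = rng.dirichlet(np.array([0.25, 0.45, 0.30]) * 120)
        total_pop = 1.7e6 * scale
        baseline_pop = total_pop * _population_age_profile(rng)
        nu = float(baseline_pop[0])
        p_geo = 1.0 / 8.0  # truncated geometric, mean ~8 years since cessation
        cess = p_geo * (1 - p_geo) ** np.arange(grids.C_MAX)
        cess = cess / cess.sum()
        fixed = FixedParameters(pi=pi, nu=nu, intensity_dist=pi.copy(),
                                cessation_dist=cess)
        base_prev = (_BASE_PREV_MALE if sex == "male" else _BASE_PREV_FEMALE).copy()
        jitter = rng.uniform(0.97, 1.03, size=base_prev.shape)
        base_prev = base_prev * jitter
        base_prev /= base_prev.sum(axis=1, keepdims=True)

        mortality = expand_mortality(delta_n, rr)
        initial = init_state(baseline_pop, base_prev, fixed.intensity_dist,
                             fixed.cessation_dist, first, sex=sex)
        counts = simulate_class_counts(initial, theta, mortality, fixed, T - 1)
        noiseless = counts / counts.sum(axis=2, keepdims=True)

        # population mortality assembled through the same mixing identity the
        # first estimation step inverts, so noiseless data recover delta_n exactly
        rr_c, rr_f = rr.aggregate(fixed.intensity_dist, fixed.cessation_dist)
        cls = grids.age_class_index()
        delta_pop = np.tile(delta_n, (T, 1))
        adult = cls >= 0
        for t in range(T):
            pk = noiseless[t][cls[adult]]
            delta_pop[t, adult] = delta_n[adult] * (
                pk[:, 0] + rr_c * pk[:, 1] + rr_f * pk[:, 2])

        by_sex[sex] = SexTruth(
            sex=sex, years=year_grid, theta=theta, fixed=fixed, rr=rr,
            delta_n_true=delta_n, mortality=mortality, baseline_pop=baseline_pop,
            baseline_prevalence=base_prev, delta_pop=delta_pop,
            noiseless_prevalence=noiseless,
        )
    return TruthBundle(seed=seed, scale=scale, by_sex=by_sex)


def simulate_surveys(truth: SexTruth, n_per_cell: int | np.ndarray,
                     seed: int = 0) -> SurveyPrevalence:
    """Draw survey observations: one multinomial of size n per (year, class) cell.

    Multinomial sampling is the natural model for survey counts; the Dirichlet
    appears only in the parametric bootstrap.
    """
    T = len(truth.years)
    n = np.broadcast_to(np.asarray(n_per_cell), (T, grids.N_CLASSES)).astype(int)
    if np.any(n < 1):
        raise ValueError("survey cell sizes must be >= 1")
    rng = np.random.default_rng(seed)
    p = np.empty((T, grids.N_CLASSES, 3))
    for t in range(T):
        for k in range(grids.N_CLASSES):
            p[t, k] = rng.multinomial(n[t, k], truth.noiseless_prevalence[t, k]) / n[t, k]
    return SurveyPrevalence(years=truth.years, p=p, n=n.astype(float))


def default_survey_sizes(seed: int = 0) -> np.ndarray:
    """Per-class cell sizes around 300-900, mimicking a regional yearly survey."""
    rng = np.random.default_rng(seed)
    base = np.array([350, 300, 420, 800, 900, 850, 500, 480, 700, 650], dtype=float)
    return np.clip(base * rng.uniform(0.9, 1.1, size=base.shape), 300, 900).astype(int)
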