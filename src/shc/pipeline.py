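"""Glue between raw input tables and the estimation stages (one sex at a time)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import CalibrationProblem, SurveyPrevalence
from .mortality import ExpandedMortality, RelativeRisks, estimate_mortality
from .params import FixedParameters
from .state import PopulationState, init_state


@dataclass
class SexData:
    """All model inputs for one sex, as read from a bundle directory."""

    sex: str
    observed: SurveyPrevalence
    delta_pop: np.ndarray            # (T, 101)
    baseline_pop: np.ndarray         # (101,) at the first observed year
    fixed: FixedParameters
    rr: RelativeRisks

    def __post_init__(self):
        T = len(self.observed.years)
        if self.delta_pop.shape != (T, self.baseline_pop.shape[0]):
            raise ValueError("delta_pop must be (n_years, n_ages)")


def first_step(data: SexData, window: tuple[int, int] | None = None) -> ExpandedMortality:
    """Back-calculate never-smoker mortality and expand it, over ``window`` years."""
    years = data.observed.years
    sel = None
    if window is not None:
        first, last = window
        idx = np.where((years >= first) & (years <= last))[0]
        if len(idx) == 0:
            raise ValueError(f"window {window} outside observed years")
        sel = slice(int(idx[0]), int(idx[-1]) + 1)
    return estimate_mortality(
        data.delta_pop, data.observed.p, data.rr,
        data.fixed.intensity_dist, data.fixed.cessation_dist, years=sel,
    )


def build_initial_state(data: SexData) -> PopulationState:
    """Baseline state from the population counts and the first observed survey."""
    p0 = data.observed.p[0]
    if np.isnan(p0).any():
        raise ValueError("first-year survey prevalences are required to initialize")
    return init_state(data.baseline_pop, p0, data.fixed.intensity_dist,
                      data.fixed.cessation_dist, int(data.observed.years[0]),
                      sex=data.sex)


def build_problem(
    data: SexData,
    window: tuple[int, int] | None = None,
    initial: PopulationState | None = None,
    mortality: ExpandedMortality | None = None,
) -> CalibrationProblem:
    """Run the first estimation step and assemble the calibration problem.

    ``window`` restricts both the mortality averaging and the objective; when
    it does not start at the first observed year an explicit ``initial`` state
    for the window start must be supplied.
    """
    if mortality is None:
        mortality = first_step(data, window)
    obs = data.observed
    if window is not None:
        obs = obs.window(*window)
    if initial is None:
        if int(obs.years[0]) != int(data.observed.years[0]):
            raise ValueError("windows not starting at the first observed year "
                             "need an explicit initial state")
        data_w = SexData(data.sex, obs, data.delta_pop[: len(obs.years)],
                         data.baseline_pop, data.fixed, data.rr)
        initial = build_initial_state(data_w)
    return CalibrationProblem(obs, initial, data.fixed, mortality)


def sexdata_from_truth(truth, surveys: SurveyPrevalence) -> SexData:
    """Wrap a synthetic ground truth and its noisy surveys as estimator input.

    The survey years may be a leading sub-window of the truth's years; the
    population mortality schedule is aligned accordingly.
    """
    idx = np.searchsorted(truth.years, surveys.years)
    if not np.array_equal(truth.years[idx], surveys.years):
        raise ValueError("survey years must be a subset of the truth's years")
    return SexData(
        sex=truth.sex, observed=surveys, delta_pop=truth.delta_pop[idx],
        baseline_pop=truth.baseline_pop, fixed=truth.fixed, rr=truth.rr,
    )
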