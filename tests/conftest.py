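import numpy as np
import pytest

from shc import (build_problem, make_truth, sexdata_from_truth, simulate_surveys)
from shc.calibration import SurveyPrevalence


@pytest.fixture(scope="session")
def truth_small():
    """A 10-year two-sex ground truth, small enough for fast experiments."""
    return make_truth(seed=0, years=(1993, 2002))


@pytest.fixture(scope="session")
def male_truth(truth_small):
    return truth_small.by_sex["male"]


@pytest.fixture(scope="session")
def male_surveys(male_truth):
    return simulate_surveys(male_truth, 500, seed=11)


@pytest.fixture(scope="session")
def male_data(male_truth, male_surveys):
    return sexdata_from_truth(male_truth, male_surveys)


@pytest.fixture(scope="session")
def male_problem(male_data):
    return build_problem(male_data)


@pytest.fixture(scope="session")
def noiseless_data(male_truth):
    """Observed prevalences equal to the exact model output (huge denominators)."""
    T = len(male_truth.years)
    obs = SurveyPrevalence(male_truth.years, male_truth.noiseless_prevalence.copy(),
                           np.full((T, 10), 1e6))
    return sexdata_from_truth(male_truth, obs)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
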