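import numpy as np
import pytest

from snitr import StateVector
from snitr.presets import PRESETS, FIT_TRUTH


@pytest.fixture(scope="session")
def rumor_free_params():
    return PRESETS["rumor_free"]


@pytest.fixture(scope="session")
def infected_endemic_params():
    return PRESETS["infected_endemic"]


@pytest.fixture(scope="session")
def neglected_endemic_params():
    return PRESETS["neglected_endemic"]


@pytest.fixture(scope="session")
def fit_truth_params():
    return FIT_TRUTH


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def random_simplex_states(rng, n):
    """Uniform draws on the 5-state density simplex."""
    return rng.dirichlet(np.ones(5), size=n)


@pytest.fixture
def interior_start():
    return StateVector(0.85, 0.05, 0.05, 0.03, 0.02)
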