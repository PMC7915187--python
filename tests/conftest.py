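import numpy as np
import pytest

from surgevol.synthetic_data import SyntheticConfig, make_fixture_set
from surgevol.transition_estimation import TransitionChain, TransitionMatrix

#: A well-mixing banded truth matrix reused across recovery tests.
MIXING_P = np.array([
    [0.80, 0.20, 0.00, 0.00],
    [0.15, 0.70, 0.15, 0.00],
    [0.00, 0.20, 0.70, 0.10],
    [0.00, 0.00, 0.30, 0.70],
])

#: The four poll timepoints printed in the source report (percent/100).
PRINTED_POLL_ROWS = [
    ("2020-03-13", 0.892, 0.054, 0.036, 0.018),
    ("2020-04-27", 0.247, 0.378, 0.295, 0.080),
    ("2020-05-17", 0.389, 0.442, 0.115, 0.053),
    ("2020-08-14", 0.823, 0.084, 0.009, 0.084),
]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def mixing_matrix():
    return TransitionMatrix(MIXING_P.copy())


@pytest.fixture
def constant_chain(mixing_matrix):
    return TransitionChain([mixing_matrix] * 16)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_weeks=10, n_hospitals=150,
                           weekly_baseline_total=5000.0, seed=99)


@pytest.fixture(scope="session")
def small_fixture(small_config):
    return make_fixture_set(small_config)


@pytest.fixture(scope="session")
def default_fixture():
    """Full-size synthetic fixture (1989 hospitals, 4.45e4 cases/week)."""
    return make_fixture_set(SyntheticConfig(seed=2020))
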