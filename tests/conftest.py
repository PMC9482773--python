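import warnings

import numpy as np
import pytest

from symptomnet import (
    correlation_matrix,
    fit_directed,
    make_ground_truth,
    simulate_responses,
)


@pytest.fixture(scope="session")
def chain_spec():
    return make_ground_truth("chain", 9, (0.3, 0.3), seed=1, n_respondents=2000)


@pytest.fixture(scope="session")
def chain_table(chain_spec):
    return simulate_responses(chain_spec)


@pytest.fixture(scope="session")
def chain_polychoric(chain_table):
    return correlation_matrix(chain_table)


@pytest.fixture(scope="session")
def chain_network(chain_polychoric):
    return fit_directed(chain_polychoric)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_correlation():
    """A well-conditioned random 9x9 correlation matrix."""

    def factory(seed: int, p: int = 9) -> np.ndarray:
        r = np.random.default_rng(seed)
        A = r.standard_normal((p, p + 6))
        S = A @ A.T + p * np.eye(p)
        d = np.sqrt(np.diag(S))
        return S / np.outer(d, d)

    return factory


@pytest.fixture(autouse=True)
def _quiet_degenerate_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        yield
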