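import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


@pytest.fixture
def toy_dataset():
    """Six distinct patterns on two binary items with integer multiplicities."""
    from lctree import CategoricalDataset

    responses = np.array([
        [1, 1], [1, 2], [2, 1], [2, 2], [1, 1], [2, 2],
    ])
    weights = np.array([3.0, 1.0, 2.0, 4.0, 1.0, 2.0])
    return CategoricalDataset.from_arrays(responses, weights=weights)


def random_lc_params(rng, K, n_categories):
    """Draw a valid random parameter set (used across tests)."""
    from lctree import LCParameters

    pi = rng.dirichlet(np.ones(K) * 5)
    probs = tuple(rng.dirichlet(np.ones(c) * 2, size=K) for c in n_categories)
    return LCParameters(K, pi, probs)
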