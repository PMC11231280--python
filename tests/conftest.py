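import numpy as np
import pytest
from hypothesis import settings

from ordnet.glasso import select_network
from ordnet.polychoric import polychoric_matrix
from ordnet.simulate import recovery_cohort

settings.register_profile("deterministic", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def recovery():
    """7-node cohort with known truth: n=4000, density 0.5, fixed seed."""
    data, truth = recovery_cohort(n=4000, seed=1)
    return data, truth


@pytest.fixture(scope="session")
def recovery_fit(recovery):
    data, truth = recovery
    S = polychoric_matrix(data)
    net = select_network(S, n=data.n)
    return data, truth, S, net


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
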