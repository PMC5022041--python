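import numpy as np
import pytest

from cascnet import Network, make_network


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def er_net():
    """Small directed sparse random network, fixed seed."""
    return make_network("er", N=40, c=0.1, R0=0.2, rho=0.5, directed=True, seed=7)


@pytest.fixture
def chain2():
    """2-node directed chain: node 1 excites node 2 only."""
    A = np.zeros((2, 2))
    A[1, 0] = 0.4
    return Network(A, rho=np.array([0.5, 0.2]))
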