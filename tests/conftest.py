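import numpy as np
import pytest

from mxlink import EdgeSet, MultiplexNetwork, correlated_duplex, erdos_renyi_gnm


@pytest.fixture
def triangle_net():
    """Duplex on 4 nodes: a triangle layer and a single-edge layer."""
    return MultiplexNetwork(
        (0, 1, 2, 3),
        {
            "tri": EdgeSet.from_pairs([(0, 1), (1, 2), (0, 2)]),
            "pair": EdgeSet.from_pairs([(2, 3)]),
        },
    )


@pytest.fixture
def small_duplex():
    """Correlated 30-node duplex used across modules."""
    return correlated_duplex(30, 60, 0.3, seed=11)


@pytest.fixture
def random_adjacency():
    """Symmetric 0/1 adjacency of a G(20, 0.3)-style graph."""
    rng = np.random.default_rng(42)
    n = 20
    a = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    mask = rng.random(len(iu[0])) < 0.3
    a[iu[0][mask], iu[1][mask]] = 1.0
    return a + a.T


def random_net(n, m, seed):
    edges = erdos_renyi_gnm(n, m, seed=seed)
    return MultiplexNetwork(tuple(range(n)), {"layer": edges})
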