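import networkx as nx
import numpy as np
import pytest

from nmsis import Network, Weibull, erdos_renyi


@pytest.fixture(scope="session")
def ring_regular_200():
    """10-regular circulant ring on 200 nodes."""
    edges = [(i, (i + d) % 200) for i in range(200) for d in range(1, 6)]
    return Network(200, np.array(edges))


@pytest.fixture(scope="session")
def regular10_500():
    return Network.from_networkx(nx.random_regular_graph(10, 500, seed=5))


@pytest.fixture(scope="session")
def er1000():
    return erdos_renyi(1000, 10.0, seed=11)


@pytest.fixture(scope="session")
def er200():
    return erdos_renyi(200, 8.0, seed=3)


@pytest.fixture(scope="session")
def star5():
    return Network.from_networkx(nx.star_graph(5))


@pytest.fixture(scope="session")
def baseline_recovery():
    """The recovery law used throughout the experiments."""
    return Weibull(2.0, 0.5)
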