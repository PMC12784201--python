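import networkx as nx
import numpy as np
import pytest

from traitnet.netgen import SocialNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def as_net(g: nx.Graph, weighted: bool = False) -> SocialNetwork:
    return SocialNetwork(graph=g, weighted=weighted)


@pytest.fixture
def star10():
    return nx.star_graph(9)  # hub 0 + 9 leaves


@pytest.fixture
def path4():
    return nx.path_graph(4)


@pytest.fixture
def ring5():
    return nx.cycle_graph(5)


@pytest.fixture
def complete10():
    return nx.complete_graph(10)
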