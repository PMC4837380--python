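import networkx as nx
import numpy as np
import pytest

from noisyvoter import Graph, ModelParams, make_network


@pytest.fixture(scope="session")
def complete8():
    return make_network("complete", 8, seed=0)


@pytest.fixture(scope="session")
def star5():
    return Graph.from_networkx(nx.star_graph(4), "star")


@pytest.fixture(scope="session")
def dich_small():
    """Small dichotomous graph (N=12, degrees 2 and 6)."""
    return make_network("dichotomous", 12, seed=3, k1=2, k2=6)


@pytest.fixture(scope="session")
def ring10():
    return Graph.from_networkx(nx.cycle_graph(10), "ring")


@pytest.fixture
def params():
    return ModelParams(a=0.3, h=1.0)
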