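import numpy as np
import pytest

from edgeperc import (Graph, make_synthetic_tree, make_road_network)


@pytest.fixture
def p3():
    return Graph([("a", "b"), ("b", "c")])


@pytest.fixture
def p4():
    return Graph([("a", "b"), ("b", "c"), ("c", "d")])


@pytest.fixture
def tree8():
    return make_synthetic_tree()


@pytest.fixture
def road():
    return make_road_network()


@pytest.fixture
def square():
    """4-cycle: the smallest graph with multiple shortest paths per pair."""
    return Graph([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])


def random_graph(rng, n_max=8, p=0.5):
    """Random simple graph with at least 2 edges (for EPC's prefactor)."""
    import networkx as nx

    while True:
        n = int(rng.integers(3, n_max + 1))
        G = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if G.number_of_edges() >= 2:
            return Graph([(str(u), str(v)) for u, v in G.edges()],
                         vertices=[str(v) for v in G.nodes()])
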