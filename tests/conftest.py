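import networkx as nx
import numpy as np
import pytest


@pytest.fixture
def star5():
    """Hub 0 joined to leaves 1..5."""
    return nx.star_graph(5)


@pytest.fixture
def double_star():
    """Two hubs (0 and 10) with 3 leaves each, joined by a bridge edge."""
    g = nx.Graph()
    g.add_edges_from([(0, i) for i in (1, 2, 3)])
    g.add_edges_from([(10, i) for i in (11, 12, 13)])
    g.add_edge(0, 10)
    return g


def random_connected_graph(rng, n_max=12, p=0.4):
    """A small connected Erdos-Renyi-ish graph for oracle sweeps."""
    n = int(rng.integers(3, n_max + 1))
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
        if g.number_of_edges() and nx.is_connected(g):
            return g


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
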