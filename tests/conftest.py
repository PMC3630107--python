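import networkx as nx
import numpy as np
import pytest

from hsnet import tables


@pytest.fixture(scope="session")
def negative_records():
    return tables.load_negative_regulators()


@pytest.fixture(scope="session")
def positive_records():
    return tables.load_positive_regulators()


@pytest.fixture(scope="session")
def reporter_rows():
    return tables.load_reporter_table()


@pytest.fixture
def two_triangles():
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("c", "a")])
    g.add_edges_from([("d", "e"), ("e", "f"), ("f", "d")])
    return g


@pytest.fixture
def bridged_k4s():
    g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
    g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
    g.add_edge("n0", "n4")
    return g


@pytest.fixture
def clique_pair_bridge():
    """Two K6 cliques joined by a single bridge edge."""
    g = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(6))
    g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
    g.add_edge("n0", "n6")
    return g


@pytest.fixture
def triangle_ring():
    """Ring of three triangles joined by single inter-triangle edges."""
    g = nx.Graph()
    for t in range(3):
        a, b, c = f"t{t}a", f"t{t}b", f"t{t}c"
        g.add_edges_from([(a, b), (b, c), (c, a)])
    g.add_edges_from([("t0c", "t1a"), ("t1c", "t2a"), ("t2c", "t0a")])
    return g


def random_connected_graph(rng: np.random.Generator, n_min=4, n_max=8):
    """A random connected labelled graph with n_min <= n <= n_max nodes."""
    while True:
        n = int(rng.integers(n_min, n_max + 1))
        p = float(rng.uniform(0.3, 0.8))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if g.number_of_edges() >= 1 and nx.is_connected(g):
            return nx.relabel_nodes(g, {i: f"v{i}" for i in g.nodes})
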