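import networkx as nx
import numpy as np
import pytest

from netbackbone.community_slpa import CommunityCover
from netbackbone.synthetic_data import load_fixture


def make_weighted(edges):
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=float(w))
    return g


@pytest.fixture(scope="session")
def karate():
    return load_fixture("karate")


@pytest.fixture(scope="session")
def lesmis():
    return load_fixture("lesmis")


@pytest.fixture
def triangle():
    return make_weighted([("a", "b", 1), ("b", "c", 2), ("a", "c", 3)])


@pytest.fixture
def path3():
    return make_weighted([("a", "b", 2), ("b", "c", 1)])


@pytest.fixture
def star5():
    return make_weighted([("c", f"l{i}", 1) for i in range(4)])


def random_weighted_graph(rng, n=30, p=0.2, max_w=9, ensure_edge=True):
    g = nx.Graph()
    g.add_nodes_from(f"v{i:02d}" for i in range(n))
    names = sorted(g.nodes)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(names[i], names[j], weight=float(rng.integers(1, max_w + 1)))
    if ensure_edge and g.number_of_edges() == 0:
        g.add_edge(names[0], names[1], weight=1.0)
    return g


def random_cover(rng, g, n_labels=3):
    """Random cover with at least one overlapping node."""
    nodes = sorted(g.nodes)
    membership = {}
    for v in nodes:
        k = 2 if rng.random() < 0.25 else 1
        labs = rng.choice(n_labels, size=k, replace=False)
        membership[v] = frozenset(f"c{i}" for i in labs)
    forced = nodes[int(rng.integers(len(nodes)))]
    membership[forced] = frozenset({"c0", "c1"})
    return CommunityCover(membership)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
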