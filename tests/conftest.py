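import random

import networkx as nx
import pytest

from ppinet.synth import SynthConfig, simulate


@pytest.fixture(scope="session")
def bundle():
    """One synthetic replicate at the default study conditions."""
    return simulate(SynthConfig(rng_seed=11))


@pytest.fixture
def triangle():
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C"), ("A", "C")])
    return g


@pytest.fixture
def path3():
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C")])
    return g


@pytest.fixture
def star5():
    g = nx.Graph()
    g.add_edges_from(("HUB", f"L{i}") for i in range(5))
    return g


def random_connected_graph(n, p, seed):
    """Largest component of a G(n, p) draw, labelled with string names."""
    rng = random.Random(seed)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(i, j)
    biggest = max(nx.connected_components(g), key=lambda c: (len(c), -min(c)))
    sub = g.subgraph(biggest)
    return nx.relabel_nodes(sub, {v: f"N{v:02d}" for v in sub.nodes}, copy=True)
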