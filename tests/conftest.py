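import networkx as nx
import numpy as np
import pytest

from follinet.interaction_db import SignalingNetwork


def net_from_edges(*edges: tuple[str, str]) -> SignalingNetwork:
    g = nx.DiGraph()
    for u, v in edges:
        g.add_edge(u, v, interactions=[], species=[], pmids=[])
    return SignalingNetwork(g)


def random_connected_net(rng: np.random.Generator, n_max: int = 10) -> SignalingNetwork:
    """Random weakly connected digraph with 3..n_max string-labeled nodes."""
    while True:
        n = int(rng.integers(3, n_max + 1))
        p = float(rng.uniform(0.2, 0.6))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)), directed=True)
        if nx.is_weakly_connected(g):
            return SignalingNetwork(
                nx.relabel_nodes(nx.DiGraph(g), {i: f"n{i}" for i in g.nodes})
            )


@pytest.fixture
def chain():
    """Directed chain a->b->c->d->e."""
    return net_from_edges(("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"))


@pytest.fixture
def star():
    """Directed 5-node star, center c emitting to 4 leaves."""
    return net_from_edges(("c", "l1"), ("c", "l2"), ("c", "l3"), ("c", "l4"))


@pytest.fixture
def triangle():
    """Directed 3-cycle a->b->c->a."""
    return net_from_edges(("a", "b"), ("b", "c"), ("c", "a"))
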