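"""Centralities against hand enumeration and independent path-walking oracles."""

import numpy as np
import pytest

from follinet.centrality import (
    all_centralities,
    betweenness,
    bottleneck_score,
    bottleneck_scores,
    closeness,
)

from ._oracles import oracle_betweenness, oracle_bottleneck, oracle_closeness
from .conftest import net_from_edges, random_connected_net


class TestCloseness:
    def test_star_center_is_one(self, star):
        assert closeness(star, "c") == 1.0

    def test_star_leaf(self, star):
        assert closeness(star, "l1") == pytest.approx(4 / 7)

    def test_isolated_node_is_zero(self, star):
        star.graph.add_node("z")
        assert closeness(star, "z") == 0.0

    def test_path_endpoint(self):
        net = net_from_edges(("a", "b"), ("b", "c"))
        assert closeness(net, "a") == pytest.approx(2 / 3)

    def test_unknown_node_errors(self, star):
        with pytest.raises(KeyError):
            closeness(star, "nope")


class TestBetweenness:
    def test_path_middle_node_is_one(self):
        net = net_from_edges(("a", "b"), ("b", "c"))
        assert betweenness(net, "b") == 1.0

    def test_star_center_is_one(self, star):
        assert betweenness(star, "c") == 1.0

    def test_four_cycle_node_is_one_sixth(self):
        net = net_from_edges(("a", "b"), ("b", "c"), ("c", "d"), ("d", "a"))
        assert betweenness(net, "a") == pytest.approx(1 / 6)

    def test_two_node_graph_is_zero(self):
        net = net_from_edges(("a", "b"))
        assert betweenness(net, "a") == 0.0
        assert betweenness(net, "b") == 0.0


class TestBottleneckScore:
    def test_single_edge_settled_by_oracle(self):
        """Endpoint-inclusive counting: the opposite endpoint's 1 path > 2/4."""
        net = net_from_edges(("a", "b"))
        expected = oracle_bottleneck(net)
        assert bottleneck_scores(net) == expected
        assert expected == {"a": 1, "b": 1}
        strict = oracle_bottleneck(net, include_endpoint=False)
        assert bottleneck_scores(net, include_endpoint=False) == strict
        assert strict == {"a": 0, "b": 0}

    def test_star_center_scores_four(self, star):
        assert bottleneck_score(star, "c") == 4
        assert oracle_bottleneck(star)["c"] == 4

    def test_directed_chain_node_d(self, chain):
        assert bottleneck_score(chain, "d", directed=True) == 3
        assert oracle_bottleneck(chain, directed=True)["d"] == 3
        # undirected projection adds the path rooted at the far endpoint
        assert bottleneck_score(chain, "d") == 4
        assert oracle_bottleneck(chain)["d"] == 4

    def test_unknown_node_errors(self, star):
        with pytest.raises(KeyError):
            bottleneck_score(star, "nope")


@pytest.fixture(scope="module")
def suite():
    rng = np.random.default_rng(2024)
    return [random_connected_net(rng) for _ in range(60)]


class TestOracleAgreementOnRandomGraphs:
    """Exhaustive-oracle agreement on a random connected-graph suite."""

    def test_closeness_matches_oracle(self, suite):
        for net in suite:
            for node in net.nodes():
                assert closeness(net, node) == pytest.approx(oracle_closeness(net, node))

    def test_betweenness_matches_path_enumeration_oracle(self, suite):
        for net in suite:
            values = betweenness(net)
            for node in net.nodes():
                assert values[node] == pytest.approx(oracle_betweenness(net, node))

    def test_bottleneck_matches_tree_path_oracle(self, suite):
        for net in suite:
            for directed in (False, True):
                assert bottleneck_scores(net, directed=directed) == oracle_bottleneck(
                    net, directed=directed
                )

    def test_all_values_in_range(self, suite):
        for net in suite:
            table = all_centralities(net)
            assert ((table["closeness"] >= 0) & (table["closeness"] <= 1)).all()
            assert ((table["betweenness"] >= 0) & (table["betweenness"] <= 1)).all()
            assert (table["bn_score"] >= 0).all()
            assert (table["bn_score"] <= net.n_nodes - 1).all()


def test_label_invariance_under_permutation():
    """Relabeling nodes permutes every centrality identically."""
    import networkx as nx

    rng = np.random.default_rng(5)
    net = random_connected_net(rng)
    nodes = net.nodes()
    perm = list(rng.permutation(nodes))
    mapping = dict(zip(nodes, [f"x{p}" for p in perm]))
    relabeled = net.__class__(nx.relabel_nodes(net.graph, mapping))
    base = all_centralities(net)
    moved = all_centralities(relabeled)
    for node in nodes:
        for col in ("closeness", "betweenness", "degree"):
            assert moved.loc[mapping[node], col] == pytest.approx(base.loc[node, col])


def test_tree_tiebreak_sensitivity_is_recorded_not_hidden():
    """Reverse-lexicographic BFS may change BN scores; both are legal trees.

    The deterministic convention is lexicographic; this check documents that
    the alternative ordering stays a valid score vector (range, integrality)
    rather than asserting equality.
    """
    from collections import deque

    rng = np.random.default_rng(77)
    for _ in range(20):
        net = random_connected_net(rng)
        g = net.undirected()
        adj = {n: sorted(g.neighbors(n), reverse=True) for n in g}
        scores = {n: 0 for n in adj}
        for s in sorted(adj):
            parent, seen, queue = {}, {s}, deque([s])
            while queue:
                u = queue.popleft()
                for v in adj[u]:
                    if v not in seen:
                        seen.add(v)
                        parent[v] = u
                        queue.append(v)
            order = [s] + list(parent)
            subtree = {v: 1 for v in order}
            for v in reversed(order[1:]):
                subtree[parent[v]] += subtree[v]
            for v in order[1:]:
                if subtree[v] > len(order) / 4.0:
                    scores[v] += 1
        for n, score in bottleneck_scores(net).items():
            assert 0 <= scores[n] <= net.n_nodes - 1
            assert 0 <= score <= net.n_nodes - 1
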