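"""Node centralities: closeness, normalized betweenness, bottleneck score.

Closeness and betweenness follow the standard shortest-path definitions:
closeness is the reciprocal of the mean distance to reachable nodes (0 for
isolated nodes), betweenness the pair-wise shortest-path fraction through a
node, normalized by (N-1)(N-2)/2 with N the size of the node's connected
component, so both live in [0, 1].

The bottleneck score is the shortest-path-tree statistic used to find
information-flow chokepoints: one BFS tree T_s is grown from every root s,
and a node v earns a point from s when more than |V(T_s)|/4 of the tree
paths from s pass through v; the score BN(v) sums those points over all
roots.  Nodes combining a high bottleneck score with hub-level degree are
the candidate controllers of the network.
"""

from __future__ import annotations

from collections import deque
from typing import Mapping

import networkx as nx
import pandas as pd

from .interaction_db import SignalingNetwork


def _metric_graph(net: SignalingNetwork, directed: bool):
    return net.graph if directed else net.undirected()


def closeness(
    net: SignalingNetwork, node: str | None = None, directed: bool = False
) -> float | dict[str, float]:
    """Reciprocal of the mean shortest-path length to reachable nodes.

    Isolated nodes score 0.  With ``directed=True``, distances follow edge
    direction outward from the node.
    """
    g = _metric_graph(net, directed)
    if directed:
        g = g.reverse(copy=False)  # networkx measures distances *to* u
    if node is not None:
        if node not in g:
            raise KeyError(f"unknown node {node!r}")
        return float(nx.closeness_centrality(g, u=node, wf_improved=False))
    vals = nx.closeness_centrality(g, wf_improved=False)
    return {n: float(v) for n, v in vals.items()}


def betweenness(
    net: SignalingNetwork, node: str | None = None, directed: bool = False
) -> float | dict[str, float]:
    """Shortest-path betweenness, normalized within each connected component.

    The per-node sum over pairs {s, t} (s != n != t) of the fraction of
    shortest s-t paths through n is divided by (N-1)(N-2)/2, N being the
    node's component size, giving values in [0, 1].  Components with fewer
    than 3 nodes admit no interior pair, so their nodes score 0.
    """
    g = _metric_graph(net, directed)
    if node is not None and node not in g:
        raise KeyError(f"unknown node {node!r}")
    result: dict[str, float] = {}
    comps = (
        nx.weakly_connected_components(g) if directed else nx.connected_components(g)
    )
    for comp in comps:
        sub = g.subgraph(comp)
        if len(comp) < 3:
            result.update({n: 0.0 for n in comp})
        else:
            result.update(
                {n: float(v) for n, v in nx.betweenness_centrality(sub, normalized=True).items()}
            )
    return result[node] if node is not None else result


def _bfs_tree(adj: Mapping[str, list[str]], root: str) -> tuple[list[str], dict[str, str]]:
    """Deterministic BFS tree: neighbors visited in lexicographic order,
    parent = first discoverer.  Returns visit order (root first) and parents."""
    parent: dict[str, str] = {}
    order = [root]
    seen = {root}
    queue = deque([root])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                parent[v] = u
                order.append(v)
                queue.append(v)
    return order, parent


def _sorted_adjacency(net: SignalingNetwork, directed: bool) -> dict[str, list[str]]:
    g = _metric_graph(net, directed)
    if directed:
        return {n: sorted(g.successors(n)) for n in g}
    return {n: sorted(g.neighbors(n)) for n in g}


def bottleneck_scores(
    net: SignalingNetwork, directed: bool = False, include_endpoint: bool = True
) -> dict[str, int]:
    """BN(v) for every node.

    For each root s a single shortest-path tree is materialized (BFS,
    lexicographic neighbor order).  The number of tree paths s->w passing
    through v equals the size of the subtree rooted at v; with
    ``include_endpoint`` (default) the path's own endpoint w = v counts as
    passing through v, matching the subtree-size convention; the strict
    reading (v interior only) subtracts one.  v scores a point from s when
    that count exceeds |V(T_s)|/4.
    """
    adj = _sorted_adjacency(net, directed)
    nodes = sorted(adj)
    scores = {n: 0 for n in nodes}
    for s in nodes:
        order, parent = _bfs_tree(adj, s)
        tree_size = len(order)
        if tree_size < 2:
            continue
        subtree = {v: 1 for v in order}
        for v in reversed(order[1:]):  # children before parents
            subtree[parent[v]] += subtree[v]
        threshold = tree_size / 4.0
        for v in order[1:]:
            count = subtree[v] if include_endpoint else subtree[v] - 1
            if count > threshold:
                scores[v] += 1
    return scores


def bottleneck_score(
    net: SignalingNetwork,
    node: str,
    directed: bool = False,
    include_endpoint: bool = True,
) -> int:
    if node not in net.graph:
        raise KeyError(f"unknown node {node!r}")
    return bottleneck_scores(net, directed=directed, include_endpoint=include_endpoint)[node]


def all_centralities(net: SignalingNetwork, directed: bool = False) -> pd.DataFrame:
    """Degrees, closeness, betweenness and bottleneck score for every node."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    nodes = net.nodes()
    g = net.graph
    clo = closeness(net, directed=directed)
    bet = betweenness(net, directed=directed)
    bn = bottleneck_scores(net, directed=directed)
    return pd.DataFrame(
        {
            "node": nodes,
            "in_degree": [g.in_degree(n) for n in nodes],
            "out_degree": [g.out_degree(n) for n in nodes],
            "degree": [g.in_degree(n) + g.out_degree(n) for n in nodes],
            "closeness": [clo[n] for n in nodes],
            "betweenness": [bet[n] for n in nodes],
            "bn_score": [bn[n] for n in nodes],
        }
    ).set_index("node")
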