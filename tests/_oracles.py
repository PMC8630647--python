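"""Brute-force reference implementations, independent of the package.

Each oracle recomputes a quantity from first principles (explicit path
enumeration, dense Floyd-Warshall matrices, literal triangle counting) so
agreement with the fast implementations is informative.
"""

from itertools import combinations

import networkx as nx
import numpy as np

from follinet.interaction_db import SignalingNetwork


def oracle_closeness(net: SignalingNetwork, node: str) -> float:
    g = net.undirected()
    dists = nx.single_source_shortest_path_length(g, node)
    del dists[node]
    if not dists:
        return 0.0
    return 1.0 / (sum(dists.values()) / len(dists))


def oracle_betweenness(net: SignalingNetwork, node: str) -> float:
    """Sum over unordered pairs of enumerated-shortest-path fractions,
    normalized by (N-1)(N-2)/2 within the node's component."""
    g = net.undirected()
    comp = nx.node_connected_component(g, node)
    if len(comp) < 3:
        return 0.0
    sub = g.subgraph(comp)
    total = 0.0
    for s, t in combinations(sorted(comp), 2):
        if node in (s, t):
            continue
        paths = list(nx.all_shortest_paths(sub, s, t))
        through = sum(node in p for p in paths)
        total += through / len(paths)
    n = len(comp)
    return total / ((n - 1) * (n - 2) / 2)


def _lex_bfs_tree(adj: dict[str, list[str]], root: str) -> dict[str, str]:
    """Parents of the deterministic BFS tree (lexicographic neighbor order)."""
    from collections import deque

    parent: dict[str, str] = {}
    seen = {root}
    queue = deque([root])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                parent[v] = u
                queue.append(v)
    return parent


def oracle_bottleneck(
    net: SignalingNetwork, directed: bool = False, include_endpoint: bool = True
) -> dict[str, int]:
    """BN scores by literally materializing every tree path.

    For each root, every path root->w is walked node by node via parent
    pointers; a vertex's per-root count is how many such paths contain it.
    """
    g = net.graph if directed else net.undirected()
    if directed:
        adj = {n: sorted(g.successors(n)) for n in g}
    else:
        adj = {n: sorted(g.neighbors(n)) for n in g}
    nodes = sorted(adj)
    scores = {n: 0 for n in nodes}
    for s in nodes:
        parent = _lex_bfs_tree(adj, s)
        members = [s] + list(parent)
        tree_size = len(members)
        counts = {v: 0 for v in members}
        for w in parent:  # each non-root tree node defines one path s->w
            path = [w]
            while path[-1] != s:
                path.append(parent[path[-1]])
            for v in path:
                if v == s:
                    continue
                if v == w and not include_endpoint:
                    continue
                counts[v] += 1
        for v in members:
            if v != s and counts[v] > tree_size / 4.0:
                scores[v] += 1
    return scores


def oracle_path_length_and_components(net: SignalingNetwork) -> tuple[float | None, int]:
    """Floyd-Warshall on the dense undirected adjacency matrix."""
    nodes = net.nodes()
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for u, v in net.edges():
        dist[idx[u], idx[v]] = 1.0
        dist[idx[v], idx[u]] = 1.0
    for k in range(n):
        dist = np.minimum(dist, dist[:, [k]] + dist[[k], :])
    finite = np.isfinite(dist)
    reach = finite & ~np.eye(n, dtype=bool)
    mean = float(dist[reach].mean()) if reach.any() else None
    # components: union of reachability rows
    comps = len({tuple(row) for row in finite})
    return mean, comps


def oracle_clustering(net: SignalingNetwork) -> dict[str, float]:
    """Literal neighbor-pair counting on the undirected projection."""
    g = net.undirected()
    out = {}
    for v in g:
        nbrs = list(g.neighbors(v))
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(g.has_edge(a, b) for a, b in combinations(nbrs, 2))
        out[v] = 2.0 * links / (k * (k - 1))
    return out
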