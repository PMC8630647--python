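"""Global topology metrics and power-law fits of the degree distributions.

Distance-based quantities (components, characteristic path length, mean
neighbor count, clustering) are computed on the undirected projection;
degree-based quantities keep direction.  A directed layered network can
report a single connected component and nonzero closeness for every node
only under undirected distances, which is the convention the reference
numbers follow; ``directed_distances=True`` is available for sensitivity
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .interaction_db import SignalingNetwork


@dataclass
class PowerLawFit:
    """OLS fit of log10(frequency) against log10(degree).

    gamma is the slope (the power-law exponent on a degree-frequency plot),
    r the Pearson correlation of the fitted line, r2 its square, n_points
    the number of distinct positive degree values supporting the fit.
    """

    gamma: float
    r: float
    r2: float
    n_points: int


@dataclass
class TopologySummary:
    n_nodes: int
    n_links: int
    n_components: int
    clustering_coefficient: float
    char_path_length: Optional[float]
    avg_neighbors: float
    in_fit: Optional[PowerLawFit]
    out_fit: Optional[PowerLawFit]
    total_fit: Optional[PowerLawFit]

    def to_dict(self) -> dict:
        def fit(f: Optional[PowerLawFit]) -> Optional[dict]:
            return None if f is None else {
                "gamma": f.gamma, "r": f.r, "r2": f.r2, "n_points": f.n_points
            }

        return {
            "n_nodes": self.n_nodes,
            "n_links": self.n_links,
            "n_components": self.n_components,
            "clustering_coefficient": self.clustering_coefficient,
            "char_path_length": self.char_path_length,
            "avg_neighbors": self.avg_neighbors,
            "in_degree_fit": fit(self.in_fit),
            "out_degree_fit": fit(self.out_fit),
            "total_degree_fit": fit(self.total_fit),
        }


def degree_profile(net: SignalingNetwork) -> pd.DataFrame:
    """Per-node in-, out- and total degree (total = in + out)."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    nodes = net.nodes()
    g = net.graph
    return pd.DataFrame(
        {
            "node": nodes,
            "in_degree": [g.in_degree(n) for n in nodes],
            "out_degree": [g.out_degree(n) for n in nodes],
            "degree": [g.in_degree(n) + g.out_degree(n) for n in nodes],
        }
    ).set_index("node")


def clustering_coefficient(net: SignalingNetwork) -> tuple[dict[str, float], float]:
    """Local clustering on the undirected projection, and the network mean.

    Nodes with fewer than two neighbors contribute 0 and stay in the
    denominator of the mean.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    values = nx.clustering(net.undirected())
    return dict(values), float(np.mean(list(values.values())))


def characteristic_path_length(net: SignalingNetwork) -> float:
    """Mean shortest-path length over connected ordered node pairs.

    Pairs in different components are excluded rather than counted as
    infinite, so the value is defined for fragmented networks too.
    """
    g = net.undirected()
    total = 0
    pairs = 0
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())  # distance to self is 0
            pairs += len(comp) - 1
    if pairs == 0:
        raise ValueError("no connected pair of nodes")
    return total / pairs


def avg_neighbors(net: SignalingNetwork) -> float:
    """Mean count of distinct adjacent nodes (reciprocal edges count once)."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    g = net.undirected()
    return float(np.mean([d for _, d in g.degree()]))


def count_components(net: SignalingNetwork) -> int:
    """Number of weakly connected components."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    return nx.number_connected_components(net.undirected())


def powerlaw_fit(degrees: Iterable[int]) -> PowerLawFit:
    """Fit log10(count) = gamma * log10(k) + c over the degree-frequency table.

    Zero degrees are dropped (log-undefined); at least 3 distinct positive
    degree values are required.  This is the network-analysis convention of
    an ordinary least-squares line on the log-log frequency plot, not a
    maximum-likelihood tail fit; with a constant frequency vector the slope
    is 0 and r is reported as 0.
    """
    degs = np.asarray(list(degrees), dtype=int)
    ks, counts = np.unique(degs[degs > 0], return_counts=True)
    if len(ks) < 3:
        raise ValueError("insufficient support for fit: need >=3 distinct positive degrees")
    x = np.log10(ks)
    y = np.log10(counts)
    if np.ptp(y) == 0:  # flat frequency: slope 0, correlation undefined -> 0
        return PowerLawFit(gamma=0.0, r=0.0, r2=0.0, n_points=len(ks))
    res = stats.linregress(x, y)
    r = float(res.rvalue)
    return PowerLawFit(gamma=float(res.slope), r=r, r2=r * r, n_points=len(ks))


def topology_summary(
    net: SignalingNetwork, on_fit_error: str = "raise"
) -> TopologySummary:
    """Assemble the global topology report.

    ``on_fit_error="none"`` stores None instead of propagating power-law-fit
    failures — heavily damaged networks (post-attack) routinely lack the
    three distinct degree values a fit needs, and an unfittable degree
    distribution is itself informative there.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    prof = degree_profile(net)

    def fit(col: str) -> Optional[PowerLawFit]:
        try:
            return powerlaw_fit(prof[col])
        except ValueError:
            if on_fit_error == "none":
                return None
            raise

    try:
        cpl: Optional[float] = characteristic_path_length(net)
    except ValueError:
        if on_fit_error != "none":
            raise
        cpl = None

    _, mean_cc = clustering_coefficient(net)
    return TopologySummary(
        n_nodes=net.n_nodes,
        n_links=net.n_links,
        n_components=count_components(net),
        clustering_coefficient=mean_cc,
        char_path_length=cpl,
        avg_neighbors=avg_neighbors(net),
        in_fit=fit("in_degree"),
        out_fit=fit("out_degree"),
        total_fit=fit("degree"),
    )
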