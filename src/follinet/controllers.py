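"""Controller identification: hubs, bottlenecks, and their intersection.

A hub is a node whose total degree strictly exceeds the network mean plus
one standard deviation of total degree (population formula).  Bottlenecks
are the top-k nodes by bottleneck score, k defaulting to the hub count so
the two controller families are commensurate.  Nodes in both sets — the
hub-bottlenecks ("hub.BN") — are the network's putative controllers: they
concentrate connectivity and sit on the information-flow chokepoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .centrality import bottleneck_scores
from .interaction_db import SignalingNetwork
from .topology import degree_profile


@dataclass
class HubThreshold:
    mu: float
    sigma: float
    threshold: float  # mu + sigma; hubs strictly exceed this


@dataclass
class ControllerSet:
    hubs: dict[str, int]            # node -> total degree
    bottlenecks: dict[str, int]     # node -> bottleneck score
    hub_bn: set[str]
    threshold: HubThreshold
    k_bottlenecks: int
    n_nodes: int

    @property
    def union(self) -> set[str]:
        return set(self.hubs) | set(self.bottlenecks)

    @property
    def hub_percent(self) -> float:
        return controller_percentage(len(self.hubs), self.n_nodes)

    @property
    def union_percent(self) -> float:
        return controller_percentage(len(self.union), self.n_nodes)

    def to_dict(self) -> dict:
        return {
            "hubs": {n: int(d) for n, d in sorted(self.hubs.items())},
            "bottlenecks": {n: int(s) for n, s in sorted(self.bottlenecks.items())},
            "hub_bn": sorted(self.hub_bn),
            "threshold": {
                "mu": self.threshold.mu,
                "sigma": self.threshold.sigma,
                "threshold": self.threshold.threshold,
            },
            "k_bottlenecks": self.k_bottlenecks,
            "n_nodes": self.n_nodes,
            "hub_percent": self.hub_percent,
            "union_percent": self.union_percent,
        }


def controller_percentage(count: int, n_nodes: int) -> float:
    """Share of the network, as a percentage rounded to one decimal."""
    if n_nodes <= 0:
        raise ValueError("n_nodes must be positive")
    return round(100.0 * count / n_nodes, 1)


def identify_hubs(degrees: Mapping[str, int]) -> tuple[set[str], HubThreshold]:
    """Nodes with total degree strictly above mean + one population SD.

    With all degrees equal the threshold collapses to the mean and no node
    strictly exceeds it, so a regular graph has no hubs.
    """
    if len(degrees) < 2:
        raise ValueError("hub identification needs at least 2 nodes")
    vals = np.asarray(list(degrees.values()), dtype=float)
    mu = float(vals.mean())
    sigma = float(vals.std())  # population (divide-by-n) convention
    thr = HubThreshold(mu=mu, sigma=sigma, threshold=mu + sigma)
    hubs = {n for n, d in degrees.items() if d > thr.threshold}
    return hubs, thr


def identify_bottlenecks(
    bn_scores: Mapping[str, int],
    k: int,
    degrees: Mapping[str, int] | None = None,
) -> set[str]:
    """Top-k nodes by bottleneck score.

    Ties at the cutoff are broken by higher total degree (when degrees are
    supplied), then lexicographic node name, so the selection is
    deterministic.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if k > len(bn_scores):
        raise ValueError(f"k={k} exceeds node count {len(bn_scores)}")
    degrees = degrees or {}
    ranked = sorted(
        bn_scores,
        key=lambda n: (-bn_scores[n], -degrees.get(n, 0), n),
    )
    return set(ranked[:k])


def intersect_controllers(
    hubs: Mapping[str, int],
    bottlenecks: Mapping[str, int],
    n_nodes: int,
    threshold: HubThreshold,
    k_bottlenecks: int | None = None,
) -> ControllerSet:
    """Assemble the controller report: hubs, bottlenecks, and their overlap."""
    hub_bn = set(hubs) & set(bottlenecks)
    return ControllerSet(
        hubs=dict(hubs),
        bottlenecks=dict(bottlenecks),
        hub_bn=hub_bn,
        threshold=threshold,
        k_bottlenecks=len(bottlenecks) if k_bottlenecks is None else k_bottlenecks,
        n_nodes=n_nodes,
    )


def find_controllers(
    net: SignalingNetwork, k_bottlenecks: int | None = None, directed: bool = False
) -> ControllerSet:
    """End-to-end controller identification on a network.

    k_bottlenecks defaults to the hub count, reproducing the convention of
    asking the bottleneck ranking for as many nodes as the degree rule
    yielded.
    """
    prof = degree_profile(net)
    degrees = prof["degree"].to_dict()
    hub_set, thr = identify_hubs(degrees)
    scores = bottleneck_scores(net, directed=directed)
    k = len(hub_set) if k_bottlenecks is None else k_bottlenecks
    bn_set = identify_bottlenecks(scores, k, degrees=degrees)
    return intersect_controllers(
        {n: degrees[n] for n in hub_set},
        {n: scores[n] for n in bn_set},
        n_nodes=net.n_nodes,
        threshold=thr,
        k_bottlenecks=k,
    )
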