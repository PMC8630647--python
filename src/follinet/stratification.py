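"""Layering nodes into input, processing and output strata by degree ratio.

The in/out degree ratio DR_IO maps each node onto [0, 100] as the
percentage of its links that are incoming, 100 * in / (in + out): pure
sources (hormones entering the system) score 0, pure sinks (terminal
follicular events) score 100.  Nodes are then assigned to the input
(DR_IO < 36), processing (36 <= DR_IO < 68) or output (DR_IO >= 68) layer.
The integer band edges 0-35 / 36-67 / 68-100 are generalized to half-open
real intervals since the ratio is generally non-integer.
"""

from __future__ import annotations

import logging

import pandas as pd

from .controllers import ControllerSet
from .interaction_db import SignalingNetwork
from .topology import degree_profile

logger = logging.getLogger(__name__)

LAYERS = ("input", "processing", "output")
_PROCESSING_LOWER = 36.0
_OUTPUT_LOWER = 68.0


def dr_io(gamma_in: int, gamma_out: int) -> float:
    """Percentage of a node's links that are incoming, in [0, 100]."""
    if gamma_in < 0 or gamma_out < 0:
        raise ValueError("degrees must be non-negative")
    total = gamma_in + gamma_out
    if total == 0:
        raise ValueError("DR_IO undefined for an isolated node")
    return 100.0 * gamma_in / total


def assign_layer(dr: float) -> str:
    """Map a DR_IO value onto the input/processing/output stratum."""
    if not 0.0 <= dr <= 100.0:
        raise ValueError(f"DR_IO must lie in [0, 100], got {dr}")
    if dr < _PROCESSING_LOWER:
        return "input"
    if dr < _OUTPUT_LOWER:
        return "processing"
    return "output"


def _controller_class(node: str, controllers: ControllerSet | None) -> str:
    if controllers is None:
        return "other"
    if node in controllers.hub_bn:
        return "hub.BN"
    if node in controllers.hubs:
        return "hub"
    if node in controllers.bottlenecks:
        return "BN"
    return "other"


def stratify_network(
    net: SignalingNetwork, controllers: ControllerSet | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign every non-isolated node to a layer.

    Returns the per-node table (in/out degree, DR_IO, layer, controller
    class) and a layer x controller-class cross-tabulation.  Isolated nodes
    have no defined ratio; they are excluded and logged.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    prof = degree_profile(net)
    rows = []
    n_isolated = 0
    for node, r in prof.iterrows():
        if r["degree"] == 0:
            n_isolated += 1
            continue
        dr = dr_io(int(r["in_degree"]), int(r["out_degree"]))
        rows.append(
            {
                "node": node,
                "in_degree": int(r["in_degree"]),
                "out_degree": int(r["out_degree"]),
                "dr_io": dr,
                "layer": assign_layer(dr),
                "controller_class": _controller_class(node, controllers),
            }
        )
    if n_isolated:
        logger.info("excluded %d isolated nodes from stratification", n_isolated)
    table = pd.DataFrame(rows).set_index("node")
    summary = (
        pd.crosstab(table["layer"], table["controller_class"])
        .reindex(index=list(LAYERS), fill_value=0)
        .fillna(0)
        .astype(int)
    )
    return table, summary
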