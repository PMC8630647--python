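"""One-command orchestration of the full analysis.

Stages: load (or synthesize) the interaction database -> build the network
-> topology summary -> centrality table -> controller identification ->
stratification -> targeted + matched random attack -> KDE subpopulation
analysis of the controllers.  Every stage writes a machine-readable file
into the output directory and the manifest links them with content hashes,
the configuration, and the derived per-stage seeds, so a rerun with the
same configuration is byte-identical and verifiably so.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np

from . import __version__
from ._util import derive_seed, round_sig, write_json
from .attack import random_attack, targeted_attack
from .centrality import all_centralities
from .controllers import find_controllers
from .density import kde_analysis
from .interaction_db import build_network, read_interaction_table
from .stratification import stratify_network
from .synthetic_data import (
    SyntheticNetworkSpec,
    generate_interaction_table,
    generate_layered_scalefree,
)
from .topology import clustering_coefficient, topology_summary

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every knob of the pipeline; absent keys fall back to module defaults."""

    input_path: Optional[str] = None      # curated table; None -> synthetic
    synthetic_n_nodes: int = 641
    synthetic_edges: int = 2086
    directed_distances: bool = False
    k_bottlenecks: Optional[int] = None   # None -> |hubs|
    attack_fraction: float = 0.025
    attack_cycles: int = 2
    kde_bandwidth: Optional[float] = None
    kde_quantile: float = 0.05
    seed: int = 0
    outdir: str = "follinet_out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(frame, path: Path) -> None:
    frame = frame.copy()
    for col in frame.columns:
        if frame[col].dtype.kind == "f":
            frame[col] = frame[col].map(lambda x: round_sig(float(x)))
    frame.to_csv(path, sep="\t")


def _kde_payload(result) -> dict:
    return {
        "dims": result.dims,
        "bandwidth": [float(b) for b in result.bandwidth],
        "n_points": int(len(result.points)),
        "n_subpopulations": len(result.subpopulations or []),
        "subpopulations": [
            {
                "mode": [float(x) for x in s.mode],
                "members": s.members,
                "peak_density": s.peak_density,
            }
            for s in (result.subpopulations or [])
        ],
        "isolated": result.isolated or [],
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk).

    Any stage failure aborts with the stage name in the raised error;
    outputs of completed stages stay on disk next to a failure marker.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    stage = "setup"
    try:
        t0 = time.perf_counter()

        def done(name: str, path: Path) -> None:
            outputs[name] = path.name
            logger.info(
                "stage=%s out=%s elapsed=%.2fs", name, path.name, time.perf_counter() - t0
            )

        stage = "load"
        if config.input_path is not None:
            db = read_interaction_table(config.input_path)
            net, _ = build_network(db)
            truth = None
        else:
            spec = SyntheticNetworkSpec(
                n_nodes=config.synthetic_n_nodes,
                target_edges=config.synthetic_edges,
                seed=derive_seed(config.seed, "synthetic"),
            )
            net, truth = generate_layered_scalefree(spec)
            db = generate_interaction_table(net, spec)

        stage = "topology"
        summary = topology_summary(net, on_fit_error="none")
        path = outdir / "topology.json"
        write_json(path, summary.to_dict())
        done(stage, path)

        stage = "centrality"
        cent = all_centralities(net, directed=config.directed_distances)
        path = outdir / "centrality.tsv"
        _write_tsv(cent, path)
        done(stage, path)

        stage = "controllers"
        controllers = find_controllers(
            net, k_bottlenecks=config.k_bottlenecks, directed=config.directed_distances
        )
        path = outdir / "controllers.json"
        write_json(path, controllers.to_dict())
        done(stage, path)

        stage = "stratification"
        strata, cross = stratify_network(net, controllers)
        path = outdir / "strata.tsv"
        _write_tsv(strata, path)
        done(stage, path)
        path = outdir / "strata_summary.tsv"
        cross.to_csv(path, sep="\t")
        done("stratification_summary", path)

        stage = "attack_targeted"
        targeted = targeted_attack(
            net, fraction=config.attack_fraction, cycles=config.attack_cycles
        )
        path = outdir / "attack_targeted.json"
        write_json(path, targeted.to_dict())
        done(stage, path)

        stage = "attack_random"
        rand = random_attack(
            net,
            n_per_cycle=targeted.removed_per_cycle[0],
            cycles=config.attack_cycles,
            seed=derive_seed(config.seed, "attack_random"),
        )
        path = outdir / "attack_random.json"
        write_json(path, rand.to_dict())
        done(stage, path)

        stage = "kde"
        cc_values, _ = clustering_coefficient(net)
        kde_payload: dict[str, Any] = {}
        hubs = sorted(controllers.hubs)
        if hubs:
            kde1 = kde_analysis(
                np.array([cc_values[n] for n in hubs]),
                bandwidth=config.kde_bandwidth,
                density_quantile=config.kde_quantile,
            )
            kde_payload["hub_clustering_1d"] = {"nodes": hubs, **_kde_payload(kde1)}
        hub_bn = sorted(controllers.hub_bn)
        if len(hub_bn) >= 2:
            pts = np.array(
                [[cent.loc[n, "degree"], cent.loc[n, "bn_score"]] for n in hub_bn],
                dtype=float,
            )
            kde2 = kde_analysis(
                pts, bandwidth=config.kde_bandwidth, density_quantile=config.kde_quantile
            )
            kde_payload["hub_bn_degree_bn_2d"] = {"nodes": hub_bn, **_kde_payload(kde2)}
        path = outdir / "kde.json"
        write_json(path, kde_payload)
        done(stage, path)

        stage = "manifest"
        manifest = {
            "version": __version__,
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seeds": {
                "root": config.seed,
                "synthetic": derive_seed(config.seed, "synthetic"),
                "attack_random": derive_seed(config.seed, "attack_random"),
            },
            "n_records": len(db),
            "has_ground_truth_layers": truth is not None,
            "outputs": {
                name: {"file": fname, "sha256": _sha256(outdir / fname)}
                for name, fname in sorted(outputs.items())
            },
        }
        write_json(outdir / "manifest.json", manifest)
        return manifest
    except Exception as exc:
        marker = outdir / "FAILED"
        marker.write_text(f"stage={stage}\nerror={exc!r}\n")
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
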