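"""Curated molecular-interaction tables and the directed signaling network.

The analysis substrate is a literature-curated table of directed
interactions between molecules (hormones, kinases, second messengers) and
follicular events, one row per curated statement: source, interaction
label, target, mammal model, and the PubMed identifier of the supporting
article.  This module reads and validates such tables, summarizes their
species composition, and collapses them into a simple directed graph
(one edge per ordered node pair, no self-loops) on which all downstream
topology and centrality analysis runs.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from ._util import canonical

logger = logging.getLogger(__name__)

#: canonical field names and the header spellings accepted for each
_FIELD_ALIASES = {
    "source": {"source", "source molecule", "source_molecule"},
    "interaction": {"interaction", "interaction type", "interaction_type"},
    "target": {"target", "target molecule", "target_molecule"},
    "species": {"species", "mammal model", "mammal_model"},
    "pmid": {"pmid", "reference", "pubmed id", "pubmed_id"},
}

EXPORT_FORMATS = ("sif", "graphml", "edgelist")


@dataclass(frozen=True)
class InteractionRecord:
    """One curated edge: source --interaction--> target, with provenance."""

    source: str
    interaction: str = ""
    target: str = ""
    species: str = ""
    pmid: str = ""

    def key(self) -> tuple:
        return (self.source, self.interaction, self.target, self.species, self.pmid)


@dataclass
class InteractionDB:
    """An ordered, deduplicated collection of interaction records."""

    records: list[InteractionRecord]
    provenance: str = ""
    source_path: str | None = None
    n_duplicates_dropped: int = 0
    n_rows_skipped: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [r.key() for r in self.records],
            columns=["source", "interaction", "target", "species", "pmid"],
        )


@dataclass
class BuildCounts:
    """Bookkeeping from collapsing records into a simple digraph."""

    n_records: int
    n_edges: int
    n_self_loops_dropped: int


@dataclass
class SignalingNetwork:
    """Directed simple graph with per-edge annotation lists.

    Edges carry the merged ``interactions``, ``species`` and ``pmids`` of
    every record that contributed to them.  Parallel edges are collapsed and
    self-loops dropped at construction time: the betweenness definition used
    downstream is only valid on simple graphs, and a single link count is
    reported for the whole network.
    """

    graph: nx.DiGraph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_links(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edges(self) -> list[tuple[str, str]]:
        return sorted(self.graph.edges)

    def undirected(self) -> nx.Graph:
        """Undirected projection (reciprocal edge pairs collapse to one)."""
        return nx.Graph(self.graph)

    def subnetwork(self, nodes: Iterable[str]) -> "SignalingNetwork":
        return SignalingNetwork(self.graph.subgraph(nodes).copy())

    def without_nodes(self, nodes: Iterable[str]) -> "SignalingNetwork":
        g = self.graph.copy()
        g.remove_nodes_from(list(nodes))
        return SignalingNetwork(g)

    def reversed(self) -> "SignalingNetwork":
        return SignalingNetwork(self.graph.reverse(copy=True))


def _resolve_columns(header: Sequence[str]) -> dict[str, int]:
    """Map canonical field names to column indices, case-insensitively."""
    cols: dict[str, int] = {}
    for idx, name in enumerate(header):
        low = canonical(name).lower()
        for field_name, aliases in _FIELD_ALIASES.items():
            if low in aliases and field_name not in cols:
                cols[field_name] = idx
    return cols


def _sniff_delimiter(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_interaction_table(
    path: str | Path, delimiter: str | None = None
) -> InteractionDB:
    """Read a delimited interaction table into an :class:`InteractionDB`.

    The header row must name at least the source and target columns (any of
    the accepted spellings, case-insensitive).  Rows whose source or target
    is empty after canonicalization are skipped and counted; exact duplicate
    rows are collapsed and counted; a pmid that is not a digit string is
    cleared (the record is kept).

    Parameters
    ----------
    path
        Delimited text file, UTF-8, header required.
    delimiter
        Field separator; sniffed from the header (tab, else comma) when None.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if delimiter is None:
        delimiter = _sniff_delimiter(path)

    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, no header") from None
        cols = _resolve_columns(header)
        for required in ("source", "target"):
            if required not in cols:
                raise ValueError(
                    f"{path}: required column '{required}' not found in header "
                    f"{header!r}"
                )

        records: list[InteractionRecord] = []
        seen: set[tuple] = set()
        n_dup = 0
        n_skipped = 0
        n_bad_pmid = 0
        for row in reader:
            if not any(cell.strip() for cell in row):
                continue

            def cell(name: str) -> str:
                i = cols.get(name)
                return canonical(row[i]) if i is not None and i < len(row) else ""

            source, target = cell("source"), cell("target")
            if not source or not target:
                n_skipped += 1
                continue
            pmid = cell("pmid")
            if pmid and not pmid.isdigit():
                n_bad_pmid += 1
                pmid = ""
            rec = InteractionRecord(
                source=source,
                interaction=cell("interaction"),
                target=target,
                species=cell("species"),
                pmid=pmid,
            )
            if rec.key() in seen:
                n_dup += 1
                continue
            seen.add(rec.key())
            records.append(rec)

    if n_dup:
        logger.info("%s: collapsed %d duplicate rows", path, n_dup)
    if n_skipped:
        logger.warning("%s: skipped %d rows with empty source/target", path, n_skipped)
    if n_bad_pmid:
        logger.warning("%s: cleared %d non-numeric pmid values", path, n_bad_pmid)

    return InteractionDB(
        records=records,
        provenance=f"read from {path}",
        source_path=str(path),
        n_duplicates_dropped=n_dup,
        n_rows_skipped=n_skipped,
    )


def db_from_records(
    rows: Iterable[tuple | InteractionRecord], provenance: str = "in-memory"
) -> InteractionDB:
    """Build a deduplicated DB from in-memory tuples or records."""
    records: list[InteractionRecord] = []
    seen: set[tuple] = set()
    n_dup = 0
    for row in rows:
        rec = row if isinstance(row, InteractionRecord) else InteractionRecord(
            *[canonical(x) for x in row]
        )
        if rec.key() in seen:
            n_dup += 1
            continue
        seen.add(rec.key())
        records.append(rec)
    return InteractionDB(records, provenance=provenance, n_duplicates_dropped=n_dup)


def species_incidence(db: InteractionDB) -> pd.Series:
    """Percentage of records attributed to each mammal model, to 2 decimals.

    Mirrors the incidence table convention: the share of curated
    interactions, not of articles, per species label; percentages sum to
    100 within rounding.
    """
    if not db.records:
        raise ValueError("no records")
    counts = pd.Series([r.species or "(unspecified)" for r in db.records]).value_counts()
    pct = (100.0 * counts / counts.sum()).round(2)
    pct.name = "percent"
    pct.index.name = "species"
    return pct


def build_network(db: InteractionDB) -> tuple[SignalingNetwork, BuildCounts]:
    """Collapse a record table into a simple directed network.

    One edge per distinct ordered (source, target) pair; interaction labels,
    species and pmids of contributing records are merged into edge-attribute
    lists; self-loops are dropped and counted.
    """
    if not db.records:
        raise ValueError("cannot build a network from an empty database")
    g = nx.DiGraph()
    n_loops = 0
    for rec in db.records:
        if rec.source == rec.target:
            n_loops += 1
            continue
        if g.has_edge(rec.source, rec.target):
            data = g.edges[rec.source, rec.target]
            if rec.interaction and rec.interaction not in data["interactions"]:
                data["interactions"].append(rec.interaction)
            if rec.species and rec.species not in data["species"]:
                data["species"].append(rec.species)
            if rec.pmid and rec.pmid not in data["pmids"]:
                data["pmids"].append(rec.pmid)
        else:
            g.add_edge(
                rec.source,
                rec.target,
                interactions=[rec.interaction] if rec.interaction else [],
                species=[rec.species] if rec.species else [],
                pmids=[rec.pmid] if rec.pmid else [],
            )
    if n_loops:
        logger.info("dropped %d self-loop records", n_loops)
    counts = BuildCounts(
        n_records=len(db.records),
        n_edges=g.number_of_edges(),
        n_self_loops_dropped=n_loops,
    )
    return SignalingNetwork(g), counts


def export_network(net: SignalingNetwork, path: str | Path, format: str) -> Path:
    """Write the network as SIF, GraphML, or a 2-column TSV edge list.

    SIF lines are ``source<TAB>interaction<TAB>target`` using the first
    interaction label of each edge (``interacts`` when unlabeled).  GraphML
    carries the annotation lists as ``|``-joined edge attributes so a
    round-trip preserves them.
    """
    if net.n_nodes == 0:
        raise ValueError("cannot export an empty network")
    if format not in EXPORT_FORMATS:
        raise ValueError(
            f"unknown format {format!r}; supported: {', '.join(EXPORT_FORMATS)}"
        )
    path = Path(path)
    if format == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for u, v in net.edges():
                labels = net.graph.edges[u, v].get("interactions", [])
                label = labels[0] if labels else "interacts"
                fh.write(f"{u}\t{label}\t{v}\n")
    elif format == "edgelist":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("source\ttarget\n")
            for u, v in net.edges():
                fh.write(f"{u}\t{v}\n")
    else:  # graphml
        g = nx.DiGraph()
        g.add_nodes_from(net.graph.nodes)
        for u, v, data in net.graph.edges(data=True):
            g.add_edge(
                u,
                v,
                interactions="|".join(data.get("interactions", [])),
                species="|".join(data.get("species", [])),
                pmids="|".join(data.get("pmids", [])),
            )
        nx.write_graphml(g, path)
    return path


def load_network(path: str | Path, format: str) -> SignalingNetwork:
    """Read a network previously written by :func:`export_network`."""
    path = Path(path)
    if format not in EXPORT_FORMATS:
        raise ValueError(
            f"unknown format {format!r}; supported: {', '.join(EXPORT_FORMATS)}"
        )
    g = nx.DiGraph()
    if format == "sif":
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) == 3:
                    u, label, v = parts
                    g.add_edge(u, v, interactions=[label], species=[], pmids=[])
    elif format == "edgelist":
        with open(path, encoding="utf-8") as fh:
            next(fh)  # header
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) == 2:
                    g.add_edge(parts[0], parts[1], interactions=[], species=[], pmids=[])
    else:
        raw = nx.read_graphml(path)
        for node in raw.nodes:
            g.add_node(node)
        for u, v, data in raw.edges(data=True):
            g.add_edge(
                u,
                v,
                interactions=[x for x in str(data.get("interactions", "")).split("|") if x],
                species=[x for x in str(data.get("species", "")).split("|") if x],
                pmids=[x for x in str(data.get("pmids", "")).split("|") if x],
            )
    return SignalingNetwork(g)


def db_from_network(net: SignalingNetwork) -> InteractionDB:
    """Expand a network back into one record per (edge, provenance) tuple."""
    rows = []
    for u, v in net.edges():
        data = net.graph.edges[u, v]
        interactions = data.get("interactions") or [""]
        species = data.get("species") or [""]
        pmids = data.get("pmids") or [""]
        n = max(len(interactions), len(species), len(pmids))
        for i in range(n):
            rows.append(
                InteractionRecord(
                    source=u,
                    interaction=interactions[min(i, len(interactions) - 1)],
                    target=v,
                    species=species[min(i, len(species) - 1)],
                    pmid=pmids[min(i, len(pmids) - 1)],
                )
            )
    return db_from_records(rows, provenance="expanded from network")
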