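"""Pathway interaction parsing and subnetwork module construction.

A pathway is read as a list of gene–gene interactions; each connected
component of a pathway's interaction graph becomes one subnetwork module,
the unit of scoring for the rest of the pipeline. Modules that are near
duplicates of a larger module (two-way overlap of nodes+edges above a
threshold) or that carry too few interactions are filtered out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionRecord",
    "Subnetwork",
    "SubnetworkDB",
    "parse_interactions",
    "build_subnetworks",
    "overlap_fraction",
    "filter_redundant",
]

Edge = tuple[str, str]


def _edge(a: str, b: str) -> Edge:
    """Canonical unordered edge representation (endpoints sorted)."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class InteractionRecord:
    """One pathway interaction; ``gene_b`` is None for node-only membership
    records (GMT input), which contribute nodes but no edges."""

    pathway_id: str
    gene_a: str
    gene_b: str | None = None


@dataclass
class Subnetwork:
    """A connected interaction module derived from one pathway."""

    subnetwork_id: str
    pathway_id: str
    nodes: frozenset[str]
    edges: frozenset[Edge]

    @property
    def components(self) -> frozenset:
        """Nodes and edges pooled: the unit set for overlap comparison."""
        return self.nodes | self.edges

    @property
    def n_components(self) -> int:
        return len(self.nodes) + len(self.edges)

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(
                    f"{self.subnetwork_id}: edge ({a},{b}) endpoint missing "
                    "from node set"
                )


@dataclass
class SubnetworkDB:
    """Ordered collection of subnetworks plus filter provenance."""

    subnetworks: list[Subnetwork]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.subnetwork_id for s in self.subnetworks]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate subnetwork ids")

    def __len__(self) -> int:
        return len(self.subnetworks)

    def __iter__(self):
        return iter(self.subnetworks)

    def __getitem__(self, subnetwork_id: str) -> Subnetwork:
        for s in self.subnetworks:
            if s.subnetwork_id == subnetwork_id:
                return s
        raise KeyError(subnetwork_id)

    @property
    def ids(self) -> list[str]:
        return [s.subnetwork_id for s in self.subnetworks]

    def genes(self) -> set[str]:
        out: set[str] = set()
        for s in self.subnetworks:
            out |= s.nodes
        return out


def parse_interactions(
    path: str | Path, format: str = "edge-list"
) -> list[InteractionRecord]:
    """Read pathway interactions from an edge list or a GMT geneset file.

    Edge list: tab-delimited ``pathway_id  gene_a  gene_b`` (extra columns
    ignored, ``#`` comment lines skipped). Duplicate undirected pairs within
    a pathway are collapsed; self-loops are dropped and counted in the log.
    GMT rows (``name  description  member...``) yield node-only records.
    """
    path = Path(path)
    if format not in ("edge-list", "gmt"):
        raise ValueError(f"unknown format: {format!r}")
    records: list[InteractionRecord] = []
    seen: set[tuple[str, Edge]] = set()
    n_self_loops = 0
    n_duplicates = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if format == "gmt":
                if len(fields) < 3:
                    raise ValueError(
                        f"{path}:{lineno}: GMT line needs name, description "
                        "and at least one member"
                    )
                name = fields[0].strip()
                members = [g.strip() for g in fields[2:] if g.strip()]
                if not name or not members:
                    raise ValueError(f"{path}:{lineno}: empty geneset name or members")
                records.extend(InteractionRecord(name, g) for g in members)
                continue
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns, "
                    f"got {len(fields)}"
                )
            pid, a, b = (f.strip() for f in fields[:3])
            if not pid or not a or not b:
                raise ValueError(f"{path}:{lineno}: empty identifier")
            if a == b:
                n_self_loops += 1
                continue
            key = (pid, _edge(a, b))
            if key in seen:
                n_duplicates += 1
                continue
            seen.add(key)
            records.append(InteractionRecord(pid, a, b))
    if not records:
        raise ValueError(f"{path}: no interactions parsed")
    if n_self_loops:
        logger.info("%s: dropped %d self-loop(s)", path.name, n_self_loops)
    if n_duplicates:
        logger.info(
            "%s: collapsed %d duplicate undirected pair(s)", path.name, n_duplicates
        )
    return records


def build_subnetworks(records: Iterable[InteractionRecord]) -> list[Subnetwork]:
    """Split each pathway into connected components, one subnetwork each.

    Node-only records (GMT input) make the whole pathway membership a single
    edge-free subnetwork. Subnetwork ids are ``<pathway>.<ordinal>`` with
    ordinals assigned by descending node count (ties by smallest node id),
    so numbering is stable for any record order.
    """
    records = list(records)
    if not records:
        raise ValueError("empty record collection")
    by_pathway: dict[str, list[InteractionRecord]] = {}
    for r in records:
        by_pathway.setdefault(r.pathway_id, []).append(r)

    out: list[Subnetwork] = []
    for pid in sorted(by_pathway):
        recs = by_pathway[pid]
        g = nx.Graph()
        loose_nodes = [r.gene_a for r in recs if r.gene_b is None]
        g.add_edges_from((r.gene_a, r.gene_b) for r in recs if r.gene_b is not None)
        comps: list[tuple[frozenset[str], frozenset[Edge]]] = []
        for comp in nx.connected_components(g):
            edges = frozenset(_edge(a, b) for a, b in g.subgraph(comp).edges)
            comps.append((frozenset(comp), edges))
        if loose_nodes:
            # geneset membership without interactions: one edge-free module
            extra = frozenset(loose_nodes) - set(g.nodes)
            if extra:
                comps.append((extra, frozenset()))
        comps.sort(key=lambda c: (-len(c[0]), min(c[0])))
        for i, (nodes, edges) in enumerate(comps, start=1):
            out.append(Subnetwork(f"{pid}.{i}", pid, nodes, edges))
    return out


def overlap_fraction(a: Subnetwork, b: Subnetwork) -> tuple[float, float]:
    """Shared fraction of network components (nodes plus edges), both ways.

    Returns ``(|C(a) ∩ C(b)| / |C(a)|, |C(a) ∩ C(b)| / |C(b)|)`` where C(x)
    pools x's node ids and canonical undirected edges.
    """
    ca, cb = a.components, b.components
    if not ca or not cb:
        raise ValueError("overlap undefined for empty subnetworks")
    shared = len(ca & cb)
    return shared / len(ca), shared / len(cb)


def filter_redundant(
    subnetworks: Sequence[Subnetwork],
    overlap_threshold: float = 0.8,
    min_edges: int = 3,
) -> SubnetworkDB:
    """Drop small modules and near-duplicate modules.

    First removes every subnetwork with fewer than ``min_edges`` edges; then
    walks the survivors in deterministic order (descending component count,
    ties by id) and eliminates the smaller of any pair whose two directional
    overlap fractions are BOTH strictly above ``overlap_threshold``. One-way
    containment of a small module in a larger one does not trigger removal.
    Size ties eliminate the lexicographically larger id. The result is
    idempotent and independent of input ordering.
    """
    if not (0.0 < overlap_threshold <= 1.0):
        raise ValueError("overlap_threshold must be in (0, 1]")
    if min_edges < 0:
        raise ValueError("min_edges must be >= 0")

    sized = [s for s in subnetworks if len(s.edges) >= min_edges]
    n_small = len(list(subnetworks)) - len(sized)
    # larger modules (more components) take precedence; id breaks ties so the
    # lexicographically smaller id survives an exact-size conflict
    ordered = sorted(sized, key=lambda s: (-s.n_components, s.subnetwork_id))
    kept: list[Subnetwork] = []
    n_redundant = 0
    for cand in ordered:
        redundant = False
        for k in kept:
            fa, fb = overlap_fraction(k, cand)
            if fa > overlap_threshold and fb > overlap_threshold:
                redundant = True
                break
        if redundant:
            n_redundant += 1
        else:
            kept.append(cand)
    if n_small or n_redundant:
        logger.info(
            "filter_redundant: removed %d module(s) with < %d edges, "
            "%d redundant module(s); %d retained",
            n_small, min_edges, n_redundant, len(kept),
        )
    kept.sort(key=lambda s: s.subnetwork_id)
    return SubnetworkDB(
        kept,
        provenance={
            "overlap_threshold": overlap_threshold,
            "min_edges": min_edges,
            "n_input": len(list(subnetworks)),
            "n_removed_min_edges": n_small,
            "n_removed_redundant": n_redundant,
        },
    )
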