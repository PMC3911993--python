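"""Degradation-pathway prior graph from protein mass and sequence evidence.

A 2DE/MS experiment yields, per spot, a mass estimate and sequence evidence:
either the set of matched peptides or the residue intervals those peptides
cover on a named reference subunit.  A spot whose evidence is contained in
another spot's evidence, at lower mass, is taken to be a degradation product
of it.  Chains of containment (intact > primary > secondary product) are
reduced to their immediate steps, so an intact subunit links to its primary
products and each primary product to its own (secondary) products, rather
than every ancestor linking to every descendant.  Regulatory links (e.g.
small-subunit up-regulation of large-subunit synthesis) are literature
annotations supplied by the user, not inferred from sequence.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .errors import CyclicEvidenceError, IncomparableEvidenceError, PathsemError
from .model import ModelStructure, SemModel, build_sem_model

__all__ = [
    "ProteinRecord",
    "PriorEdge",
    "PathwayGraph",
    "sequence_contained",
    "build_prior_graph",
    "to_sem_skeleton",
    "read_protein_table",
    "read_regulation_table",
    "write_graphml",
    "write_dot",
]

Interval = tuple[int, int]


@dataclass(frozen=True)
class ProteinRecord:
    """One identified 2DE spot.

    ``evidence`` is either a frozenset of peptide strings or a frozenset of
    half-open residue intervals ``(start, end)`` in 0-based coordinates on
    ``reference_subunit``.  Intact records reference themselves.
    """

    id: str
    tier: str  # "intact" | "fragment"
    mass_kda: float
    reference_subunit: str | None = None
    evidence: frozenset = frozenset()

    def __post_init__(self):
        if self.tier not in ("intact", "fragment"):
            raise PathsemError(f"{self.id}: tier must be 'intact' or 'fragment'")
        if not self.mass_kda > 0:
            raise PathsemError(f"{self.id}: mass must be positive")
        if self.tier == "intact" and self.reference_subunit != self.id:
            raise PathsemError(
                f"{self.id}: an intact record must reference its own sequence"
            )
        kinds = {isinstance(e, str) for e in self.evidence}
        if len(kinds) > 1:
            raise PathsemError(f"{self.id}: mixed peptide and interval evidence")
        for e in self.evidence:
            if not isinstance(e, str):
                start, end = e
                if not start < end:
                    raise PathsemError(f"{self.id}: interval {e} has start >= end")

    @property
    def evidence_kind(self) -> str:
        for e in self.evidence:
            return "peptides" if isinstance(e, str) else "intervals"
        return "empty"


@dataclass(frozen=True)
class PriorEdge:
    source: str
    target: str
    kind: str  # "degradation" | "regulation"
    evidence: str = ""

    def __post_init__(self):
        if self.kind not in ("degradation", "regulation"):
            raise PathsemError(f"edge kind must be degradation or regulation, got {self.kind!r}")
        if self.source == self.target and self.kind != "regulation":
            raise PathsemError("self-loops are only allowed for regulation edges")


@dataclass
class PathwayGraph:
    """Directed pathway graph; the degradation subgraph is always a DAG."""

    nodes: list[str]
    edges: list[PriorEdge] = field(default_factory=list)

    def __post_init__(self):
        node_set = set(self.nodes)
        for e in self.edges:
            if e.source not in node_set or e.target not in node_set:
                raise PathsemError(f"edge {e.source}->{e.target} references unknown node")
        deg = self.subgraph("degradation")
        if not nx.is_directed_acyclic_graph(deg):
            cyc = nx.find_cycle(deg)
            raise CyclicEvidenceError(f"degradation subgraph has a cycle: {cyc}")

    def subgraph(self, kind: str) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            if e.kind == kind:
                g.add_edge(e.source, e.target)
        return g

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.source, e.target, kind=e.kind, evidence=e.evidence)
        return g

    def edge_set(self, kind: str | None = None) -> set[tuple[str, str]]:
        return {
            (e.source, e.target)
            for e in self.edges
            if kind is None or e.kind == kind
        }


# ---------------------------------------------------------------------------
# containment
# ---------------------------------------------------------------------------


def _merge_intervals(ivals) -> list[Interval]:
    out: list[Interval] = []
    for start, end in sorted(ivals):
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def _intervals_covered(inner, outer) -> bool:
    merged = _merge_intervals(outer)
    for start, end in inner:
        ok = any(ms <= start and end <= me for ms, me in merged)
        if not ok:
            return False
    return True


def sequence_contained(fragment: ProteinRecord, parent: ProteinRecord) -> bool:
    """True iff the fragment's (non-empty) evidence lies within the parent's.

    Peptide sets are compared by subset regardless of reference (shared
    peptides are themselves the evidence of shared sequence); interval sets
    require the same reference subunit and are compared by coverage.
    Comparing peptide evidence against interval evidence is meaningless and
    raises :class:`IncomparableEvidenceError` rather than returning False.
    """
    fk, pk = fragment.evidence_kind, parent.evidence_kind
    if fk == "empty" or pk == "empty":
        return False
    if fk != pk:
        raise IncomparableEvidenceError(
            f"cannot compare {fk} evidence of {fragment.id} with {pk} evidence of {parent.id}"
        )
    if fk == "peptides":
        return fragment.evidence <= parent.evidence
    if fragment.reference_subunit != parent.reference_subunit:
        return False
    return _intervals_covered(fragment.evidence, parent.evidence)


def _comparable(a: ProteinRecord, b: ProteinRecord) -> bool:
    ka, kb = a.evidence_kind, b.evidence_kind
    return ka != "empty" and kb != "empty" and ka == kb


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------


def build_prior_graph(
    records: list[ProteinRecord],
    regulation: list[PriorEdge] | None = None,
) -> PathwayGraph:
    """Build the degradation pathway graph by all-pairs containment.

    For every comparable pair, a containment of the lighter record's
    evidence within the heavier record's evidence yields a candidate
    degradation edge heavy -> light (the target must be a fragment).
    Transitively implied edges are then removed, so each product attaches
    to its immediate precursor(s) and the intact subunit links only to
    primary products; a fragment covered by several incomparable parents
    keeps one edge from each ("and/or" multi-parent semantics).  Mutual
    containment at equal mass has no consistent direction and raises
    :class:`CyclicEvidenceError`.  Regulation edges are appended verbatim.
    """
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise PathsemError("record ids must be unique")
    recs = sorted(records, key=lambda r: r.id)
    candidates: set[tuple[str, str]] = set()
    for a in recs:
        for b in recs:
            if a.id >= b.id or not _comparable(a, b):
                continue
            ab = sequence_contained(b, a)  # b inside a
            ba = sequence_contained(a, b)
            if ab and ba and a.mass_kda == b.mass_kda:
                raise CyclicEvidenceError(
                    f"mutual containment at equal mass: {a.id} <-> {b.id}"
                )
            if ab and a.mass_kda > b.mass_kda and b.tier == "fragment":
                candidates.add((a.id, b.id))
            if ba and b.mass_kda > a.mass_kda and a.tier == "fragment":
                candidates.add((b.id, a.id))

    g = nx.DiGraph()
    g.add_nodes_from(ids)
    g.add_edges_from(candidates)
    if not nx.is_directed_acyclic_graph(g):
        cyc = nx.find_cycle(g)
        raise CyclicEvidenceError(f"cyclic degradation evidence: {cyc}")
    reduced = nx.transitive_reduction(g)

    edges = [
        PriorEdge(source=u, target=v, kind="degradation", evidence="sequence containment")
        for u, v in sorted(reduced.edges())
    ]
    for e in regulation or []:
        if e.kind != "regulation":
            raise PathsemError("user-supplied edges must have kind='regulation'")
        edges.append(e)
    return PathwayGraph(nodes=ids, edges=edges)


def to_sem_skeleton(graph: PathwayGraph) -> SemModel:
    """One observed variable per node, one free structural coefficient per
    edge (degradation and regulation alike), free residual variance per
    endogenous variable and free variance per exogenous variable."""
    nodes = sorted(graph.nodes)
    regressions: dict[str, list[str]] = {}
    for e in sorted(graph.edges, key=lambda e: (e.target, e.source)):
        regressions.setdefault(e.target, [])
        if e.source not in regressions[e.target]:
            regressions[e.target].append(e.source)
    structure = ModelStructure(observed=nodes, regressions=regressions)
    return build_sem_model(structure)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _parse_evidence(text: str) -> frozenset:
    items = [t.strip() for t in text.split(";") if t.strip()]
    out = []
    for item in items:
        parts = item.split("-")
        if len(parts) == 2 and all(p.strip().isdigit() for p in parts):
            out.append((int(parts[0]), int(parts[1])))
        else:
            out.append(item)
    return frozenset(out)


def _format_evidence(ev: frozenset) -> str:
    items = []
    for e in sorted(ev, key=str):
        items.append(e if isinstance(e, str) else f"{e[0]}-{e[1]}")
    return ";".join(items)


def read_protein_table(path: str | Path) -> list[ProteinRecord]:
    """Read protein metadata CSV: id, tier, mass_kda, reference_subunit,
    evidence (semicolon-separated peptides or start-end intervals)."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"id", "tier", "mass_kda", "reference_subunit", "evidence"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise PathsemError(
                f"{path}: header must contain {sorted(required)}, got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(
                    ProteinRecord(
                        id=row["id"].strip(),
                        tier=row["tier"].strip(),
                        mass_kda=float(row["mass_kda"]),
                        reference_subunit=row["reference_subunit"].strip() or None,
                        evidence=_parse_evidence(row["evidence"]),
                    )
                )
            except (PathsemError, ValueError) as exc:
                raise PathsemError(f"{path}, line {lineno}: {exc}") from exc
    if not records:
        raise PathsemError(f"{path}: no protein records")
    return records


def write_protein_table(records: list[ProteinRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "tier", "mass_kda", "reference_subunit", "evidence"])
        for r in records:
            writer.writerow(
                [r.id, r.tier, f"{r.mass_kda:g}", r.reference_subunit or "", _format_evidence(r.evidence)]
            )


def read_regulation_table(path: str | Path) -> list[PriorEdge]:
    """Read regulation-edge CSV: source, target, evidence."""
    edges = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"source", "target"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise PathsemError(f"{path}: header must contain {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                edges.append(
                    PriorEdge(
                        source=row["source"].strip(),
                        target=row["target"].strip(),
                        kind="regulation",
                        evidence=(row.get("evidence") or "").strip(),
                    )
                )
            except PathsemError as exc:
                raise PathsemError(f"{path}, line {lineno}: {exc}") from exc
    return edges


def write_graphml(graph: PathwayGraph, path: str | Path) -> None:
    nx.write_graphml(graph.to_networkx(), str(path))


def write_dot(graph: PathwayGraph, path: str | Path) -> None:
    lines = ["digraph pathway {"]
    for node in graph.nodes:
        lines.append(f'  "{node}";')
    for e in graph.edges:
        style = "solid" if e.kind == "degradation" else "dashed"
        lines.append(f'  "{e.source}" -> "{e.target}" [kind={e.kind}, style={style}];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
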