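"""Directed, attributed pathway graphs with curation-aware editing.

A :class:`Pathway` is a collection of nodes (genes, compounds, complexes,
linked maps, abstract processes) joined by signed, weighted edges.  Every
mutating operation appends exactly one :class:`CurationLogEntry`, and the
log carries enough detail that replaying it on the original pathway
reproduces the edited one (see :func:`replay_log`).

Node and edge identity conventions:

* node ids are opaque strings; KEGG entry ids and user-assigned ids share
  one namespace,
* edges are identified by the triple ``(source, target, subtype)`` so the
  same node pair may carry e.g. both an activation and a phosphorylation.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from typing import Iterable, Iterator, Optional

import networkx as nx

from .errors import ValidationError

NODE_KINDS = ("gene", "compound", "group", "map", "process")
PROVENANCES = ("original", "auto_corrected", "curated")


@dataclass
class PathwayNode:
    """A pathway entity.

    ``gene_ids`` holds the identifiers from the source database (several
    for multi-gene KEGG entries; a compound id for compound nodes).
    ``members`` is non-empty exactly when ``kind == "group"`` and lists the
    node ids bundled into the complex.  ``fold_change`` is the positive,
    linear-scale FC_j consumed by propagation; ``signal`` is S_j once a
    propagation has run.
    """

    id: str
    label: str = ""
    kind: str = "gene"
    gene_ids: list[str] = field(default_factory=list)
    members: list[str] = field(default_factory=list)
    fold_change: float = 1.0
    signal: Optional[float] = None
    provenance: str = "original"
    fc_matched: Optional[int] = None  # genes matched at the last FC mapping

    def __post_init__(self) -> None:
        if self.kind not in NODE_KINDS:
            raise ValidationError(f"node {self.id!r}: unknown kind {self.kind!r}")
        if self.provenance not in PROVENANCES:
            raise ValidationError(f"node {self.id!r}: unknown provenance {self.provenance!r}")
        if not (self.fold_change > 0):
            raise ValidationError(f"node {self.id!r}: fold_change must be > 0")
        if self.signal is not None and not (self.signal > 0):
            raise ValidationError(f"node {self.id!r}: signal must be > 0")
        if (self.kind == "group") != bool(self.members):
            raise ValidationError(
                f"node {self.id!r}: members must be non-empty iff kind='group'"
            )


@dataclass
class PathwayEdge:
    """A directed interaction.

    ``impact`` is K_ij (+1 activation, -1 inhibition), ``weight`` is the
    positive interaction weight w_ij (default 1), ``subtype`` keeps the
    original relation label verbatim.  ``compound_ref`` records, for edges
    parsed from KGML compound relations, the id of the mediating compound
    entry (used by the automatic protein-compound-protein bridging).
    """

    source: str
    target: str
    impact: int = 1
    weight: float = 1.0
    subtype: str = "activation"
    provenance: str = "original"
    compound_ref: Optional[str] = None

    def __post_init__(self) -> None:
        if self.impact not in (1, -1):
            raise ValidationError(
                f"edge {self.source}->{self.target}: impact must be +1 or -1"
            )
        if not (self.weight > 0):
            raise ValidationError(
                f"edge {self.source}->{self.target}: weight must be > 0"
            )
        if self.provenance not in PROVENANCES:
            raise ValidationError(
                f"edge {self.source}->{self.target}: unknown provenance "
                f"{self.provenance!r}"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source, self.target, self.subtype)


@dataclass
class CurationLogEntry:
    """One mutation record.

    ``timestamp`` is a logical clock (monotone counter) rather than wall
    time so that identical edit sequences serialize identically.
    ``details`` stores the full payload needed to replay the operation.
    """

    timestamp: int
    operation: str
    targets: list[str]
    note: str = ""
    details: dict = field(default_factory=dict)


class Pathway:
    """A directed attributed pathway graph with an append-only edit log."""

    def __init__(self, id: str, name: str = "") -> None:
        self.id = id
        self.name = name
        self.nodes: dict[str, PathwayNode] = {}
        self.edges: list[PathwayEdge] = []
        self.curation_log: list[CurationLogEntry] = []

    # -- basic protocol ----------------------------------------------------

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Pathway):
            return NotImplemented
        return (
            self.id == other.id
            and self.name == other.name
            and self.nodes == other.nodes
            and self.edges == other.edges
            and self.curation_log == other.curation_log
        )

    def __repr__(self) -> str:
        return (
            f"<Pathway {self.id!r}: {len(self.nodes)} nodes, "
            f"{len(self.edges)} edges>"
        )

    def copy(self) -> "Pathway":
        return copy.deepcopy(self)

    # -- lookups -----------------------------------------------------------

    def node(self, node_id: str) -> PathwayNode:
        try:
            return self.nodes[node_id]
        except KeyError:
            raise ValidationError(f"unknown node id {node_id!r}") from None

    def find_edge(self, source: str, target: str, subtype: Optional[str] = None) -> PathwayEdge:
        matches = [
            e
            for e in self.edges
            if e.source == source
            and e.target == target
            and (subtype is None or e.subtype == subtype)
        ]
        if not matches:
            raise ValidationError(f"no edge {source!r} -> {target!r}")
        if len(matches) > 1:
            raise ValidationError(
                f"ambiguous edge {source!r} -> {target!r}: give a subtype"
            )
        return matches[0]

    def has_edge(self, source: str, target: str, subtype: Optional[str] = None) -> bool:
        return any(
            e.source == source
            and e.target == target
            and (subtype is None or e.subtype == subtype)
            for e in self.edges
        )

    def in_edges(self, node_id: str) -> list[PathwayEdge]:
        return [e for e in self.edges if e.target == node_id]

    def out_edges(self, node_id: str) -> list[PathwayEdge]:
        return [e for e in self.edges if e.source == node_id]

    def sinks(self) -> list[str]:
        """Node ids with out-degree 0, sorted."""
        with_out = {e.source for e in self.edges}
        return sorted(n for n in self.nodes if n not in with_out)

    def input_nodes(self) -> list[str]:
        """Node ids with in-degree 0, sorted."""
        with_in = {e.target for e in self.edges}
        return sorted(n for n in self.nodes if n not in with_in)

    def to_networkx(self) -> nx.DiGraph:
        """Plain DiGraph view (parallel subtypes collapse to one arc)."""
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.nodes))
        for e in self.edges:
            if not g.has_edge(e.source, e.target):
                g.add_edge(e.source, e.target, impact=e.impact, weight=e.weight)
        return g

    # -- log plumbing ------------------------------------------------------

    def _log(self, operation: str, targets: Iterable[str], note: str = "", **details) -> None:
        self.curation_log.append(
            CurationLogEntry(
                timestamp=len(self.curation_log),
                operation=operation,
                targets=list(targets),
                note=note,
                details=details,
            )
        )

    # -- mutating operations ----------------------------------------------

    def add_node(self, node: PathwayNode, provenance: str = "curated") -> "Pathway":
        if node.id in self.nodes:
            raise ValidationError(f"duplicate id {node.id!r}")
        for m in node.members:
            if m not in self.nodes:
                raise ValidationError(
                    f"group {node.id!r} references unknown member {m!r}"
                )
        node = copy.deepcopy(node)
        node.provenance = provenance
        self.nodes[node.id] = node
        self._log("add_node", [node.id], node=_node_dict(node))
        return self

    def remove_node(self, node_id: str) -> "Pathway":
        if node_id not in self.nodes:
            raise ValidationError(f"unknown node id {node_id!r}")
        removed_edges = [
            e for e in self.edges if node_id in (e.source, e.target)
        ]
        self.edges = [e for e in self.edges if node_id not in (e.source, e.target)]
        purged_from: list[str] = []
        for n in self.nodes.values():
            if node_id in n.members:
                n.members = [m for m in n.members if m != node_id]
                purged_from.append(n.id)
        node = self.nodes.pop(node_id)
        # a group emptied by the purge degenerates; demote it to a process node
        for gid in purged_from:
            g = self.nodes[gid]
            if g.kind == "group" and not g.members:
                g.kind = "process"
        self._log(
            "remove_node",
            [node_id],
            node=_node_dict(node),
            removed_edges=[_edge_dict(e) for e in removed_edges],
            purged_from=purged_from,
        )
        return self

    def add_edge(self, edge: PathwayEdge, provenance: str = "curated") -> "Pathway":
        if edge.source not in self.nodes:
            raise ValidationError(f"unknown source {edge.source!r}")
        if edge.target not in self.nodes:
            raise ValidationError(f"unknown target {edge.target!r}")
        if any(e.key == edge.key for e in self.edges):
            raise ValidationError(
                f"duplicate edge {edge.source!r} -> {edge.target!r} "
                f"({edge.subtype!r})"
            )
        edge = copy.deepcopy(edge)
        edge.provenance = provenance
        self.edges.append(edge)
        self._log("add_edge", [edge.source, edge.target], edge=_edge_dict(edge))
        return self

    def add_edges_from(self, source: str, targets: Iterable[str], **attrs) -> "Pathway":
        """One-to-many convenience: ``add_edge`` once per target."""
        for t in targets:
            self.add_edge(PathwayEdge(source=source, target=t, **attrs))
        return self

    def remove_edge(self, source: str, target: str, subtype: Optional[str] = None) -> "Pathway":
        edge = self.find_edge(source, target, subtype)
        self.edges.remove(edge)
        self._log("remove_edge", [source, target], edge=_edge_dict(edge))
        return self

    def set_edge_attributes(
        self,
        source: str,
        target: str,
        subtype: Optional[str] = None,
        *,
        impact: Optional[int] = None,
        weight: Optional[float] = None,
        new_subtype: Optional[str] = None,
    ) -> "Pathway":
        edge = self.find_edge(source, target, subtype)
        old = _edge_dict(edge)
        if impact is not None:
            if impact not in (1, -1):
                raise ValidationError("impact must be +1 or -1")
            edge.impact = impact
        if weight is not None:
            if not (weight > 0):
                raise ValidationError("weight must be > 0")
            edge.weight = weight
        if new_subtype is not None:
            candidate = (edge.source, edge.target, new_subtype)
            if any(e.key == candidate for e in self.edges if e is not edge):
                raise ValidationError(
                    f"duplicate edge {source!r} -> {target!r} ({new_subtype!r})"
                )
            edge.subtype = new_subtype
        edge.provenance = "curated"
        self._log(
            "set_edge_attributes",
            [source, target],
            old=old,
            new=_edge_dict(edge),
        )
        return self

    # -- integrity detectors (pure) ---------------------------------------

    def detect_disconnected_nodes(self) -> list[str]:
        """Node ids with neither incoming nor outgoing edges, sorted."""
        touched = {e.source for e in self.edges} | {e.target for e in self.edges}
        return sorted(n for n in self.nodes if n not in touched)

    def detect_duplicates(self) -> list[list[str]]:
        """Groups of nodes indistinguishable by (kind, gene_ids, members).

        Labels are deliberately ignored: display names vary across
        sources while the underlying biology does not.  Nodes carrying no
        gene ids and no members (bare process placeholders) are never
        reported.
        """
        buckets: dict[tuple, list[str]] = {}
        for n in self.nodes.values():
            if not n.gene_ids and not n.members:
                continue
            key = (n.kind, tuple(sorted(n.gene_ids)), tuple(sorted(n.members)))
            buckets.setdefault(key, []).append(n.id)
        return sorted(
            [sorted(ids) for ids in buckets.values() if len(ids) > 1]
        )

    def detect_cycles(self) -> list[list[str]]:
        """Strongly connected components of size > 1, plus self-loops.

        Self-loops are reported as singleton components: they obstruct a
        topological evaluation order exactly as larger loops do.
        """
        g = self.to_networkx()
        out = [sorted(c) for c in nx.strongly_connected_components(g) if len(c) > 1]
        self_loops = {e.source for e in self.edges if e.source == e.target}
        in_big = {n for c in out for n in c}
        out.extend([v] for v in sorted(self_loops - in_big))
        return sorted(out)

    def validate(self) -> None:
        """Re-check all structural invariants; raise on the first violation."""
        seen_keys: set[tuple[str, str, str]] = set()
        for nid, n in self.nodes.items():
            if nid != n.id:
                raise ValidationError(f"node keyed {nid!r} carries id {n.id!r}")
            n.__post_init__()
            for m in n.members:
                if m not in self.nodes:
                    raise ValidationError(f"group {nid!r}: unknown member {m!r}")
        for e in self.edges:
            e.__post_init__()
            if e.source not in self.nodes:
                raise ValidationError(f"dangling edge source {e.source!r}")
            if e.target not in self.nodes:
                raise ValidationError(f"dangling edge target {e.target!r}")
            if e.key in seen_keys:
                raise ValidationError(
                    f"duplicate edge {e.source!r} -> {e.target!r} ({e.subtype!r})"
                )
            seen_keys.add(e.key)


def _node_dict(node: PathwayNode) -> dict:
    return asdict(node)


def _edge_dict(edge: PathwayEdge) -> dict:
    return asdict(edge)


def replay_log(base: Pathway, log: Iterable[CurationLogEntry]) -> Pathway:
    """Re-apply an edit log to a copy of ``base``.

    ``replay_log(original, edited.curation_log[len(original.curation_log):])``
    reproduces ``edited`` node-for-node and edge-for-edge.
    """
    p = base.copy()
    for entry in log:
        d = entry.details
        if entry.operation == "add_node":
            nd = dict(d["node"])
            p.add_node(PathwayNode(**nd), provenance=nd["provenance"])
        elif entry.operation == "remove_node":
            p.remove_node(entry.targets[0])
        elif entry.operation == "add_edge":
            ed = dict(d["edge"])
            p.add_edge(PathwayEdge(**ed), provenance=ed["provenance"])
        elif entry.operation == "remove_edge":
            ed = d["edge"]
            p.remove_edge(ed["source"], ed["target"], ed["subtype"])
        elif entry.operation == "orient_edge":
            old, new = d["old"], d["new"]
            edge = p.find_edge(old["source"], old["target"], old["subtype"])
            edge.source, edge.target = new["source"], new["target"]
            edge.provenance = new["provenance"]
            p._log("orient_edge", entry.targets, old=old, new=new)
        elif entry.operation == "autocorrect":
            # summary entry: its structural effects are separately logged
            p.curation_log.append(copy.deepcopy(entry))
            p.curation_log[-1].timestamp = len(p.curation_log) - 1
        elif entry.operation == "set_edge_attributes":
            old, new = d["old"], d["new"]
            p.set_edge_attributes(
                old["source"],
                old["target"],
                old["subtype"],
                impact=new["impact"],
                weight=new["weight"],
                new_subtype=new["subtype"],
            )
        else:
            raise ValidationError(f"cannot replay operation {entry.operation!r}")
    return p
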