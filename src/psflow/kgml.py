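"""KGML import, automatic topology corrections, table import, JSON round-trip.

KGML (KEGG Markup Language) encodes each pathway map as ``entry`` elements
(genes, compounds, groups, linked maps) and ``relation`` elements between
them.  The encoding has well-known topological flaws for signal-flow
analysis: protein-compound-protein interactions appear only as an
annotation on a direct protein-protein relation, complexes are encoded as
group entries with no edges to their members, and binding/association
relations are semantically undirected.  :func:`autocorrect` repairs all
three, reporting every change it makes.

The pathway JSON written by :func:`to_json` is the canonical on-disk form:
stable key order, embedded curation log, explicit schema version.
"""

from __future__ import annotations

import io
import json
import logging
import warnings
from collections import deque
from dataclasses import dataclass, field

import pandas as pd
from lxml import etree

from .errors import ParseError, ValidationError
from .model import (
    CurationLogEntry,
    Pathway,
    PathwayEdge,
    PathwayNode,
    _edge_dict,
    _node_dict,
)

log = logging.getLogger(__name__)

JSON_SCHEMA_VERSION = "1.0"

#: KGML relation subtype -> edge sign.  The underlying model fixes only the
#: two-valued impact (+1 activation, -1 inhibition); the signs assigned to
#: the remaining KGML subtypes are this package's documented convention.
SUBTYPE_IMPACT: dict[str, int] = {
    "inhibition": -1,
    "repression": -1,
    "dissociation": -1,
    "activation": 1,
    "expression": 1,
    "binding/association": 1,
    "indirect effect": 1,
    "state change": 1,
    "phosphorylation": 1,
    "dephosphorylation": 1,
    "ubiquitination": 1,
    "methylation": 1,
    "glycosylation": 1,
    "compound": 1,
    "hidden compound": 1,
    "missing interaction": 1,
    "group-membership": 1,
    "unknown": 1,
}

_ENTRY_KIND = {
    "gene": "gene",
    "compound": "compound",
    "group": "group",
    "map": "map",
}


def impact_for_subtype(subtype: str) -> int:
    """Sign for a (possibly compound, ``+``-joined) relation subtype."""
    parts = subtype.split("+") if subtype else ["unknown"]
    signs = [SUBTYPE_IMPACT.get(p.strip(), 1) for p in parts]
    return -1 if -1 in signs else 1


# ---------------------------------------------------------------------------
# KGML parsing
# ---------------------------------------------------------------------------


def parse_kgml(document: str | bytes) -> Pathway:
    """Parse a KGML document into an uncorrected :class:`Pathway`.

    One node per ``entry`` (kind from the entry type; unknown types become
    ``process`` with a warning), ``gene_ids`` from the entry's space-
    separated ``name`` list, group members from ``component`` children, and
    one edge per ``relation`` with the subtype recorded verbatim.  No
    corrections are applied; see :func:`autocorrect`.
    """
    if isinstance(document, str):
        document = document.encode("utf-8")
    try:
        root = etree.parse(io.BytesIO(document)).getroot()
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed KGML: {exc}") from None
    if root.tag != "pathway":
        raise ParseError(f"not a KGML document (root element {root.tag!r})")

    pathway = Pathway(
        id=root.get("name", root.get("number", "pathway")),
        name=root.get("title", ""),
    )
    for entry in root.findall("entry"):
        eid = entry.get("id")
        if eid is None:
            raise ParseError("KGML entry without id attribute")
        etype = entry.get("type", "other")
        kind = _ENTRY_KIND.get(etype)
        if kind is None:
            warnings.warn(
                f"KGML entry {eid}: unknown type {etype!r}, keeping as 'process'",
                stacklevel=2,
            )
            kind = "process"
        graphics = entry.find("graphics")
        label = ""
        if graphics is not None and graphics.get("name"):
            label = graphics.get("name").split(",")[0].strip("...").strip()
        members = [c.get("id") for c in entry.findall("component")]
        gene_ids = (entry.get("name") or "").split()
        if kind == "group":
            gene_ids = []
        node = PathwayNode(
            id=eid,
            label=label,
            kind=kind,
            gene_ids=gene_ids,
            members=members if kind == "group" else [],
            provenance="original",
        )
        if eid in pathway.nodes:
            raise ParseError(f"duplicate KGML entry id {eid!r}")
        pathway.nodes[eid] = node

    for rel in root.findall("relation"):
        e1, e2 = rel.get("entry1"), rel.get("entry2")
        if e1 not in pathway.nodes or e2 not in pathway.nodes:
            raise ParseError(
                f"relation references unknown entries ({e1!r}, {e2!r})"
            )
        subtypes = [s.get("name", "unknown") for s in rel.findall("subtype")]
        compound_ref = None
        for s in rel.findall("subtype"):
            if s.get("name") in ("compound", "hidden compound"):
                compound_ref = s.get("value")
        subtype = "+".join(subtypes) if subtypes else "unknown"
        edge = PathwayEdge(
            source=e1,
            target=e2,
            impact=impact_for_subtype(subtype),
            weight=1.0,
            subtype=subtype,
            provenance="original",
            compound_ref=compound_ref,
        )
        if any(e.key == edge.key for e in pathway.edges):
            continue  # KGML occasionally repeats a relation verbatim
        pathway.edges.append(edge)

    # validate group member references
    for n in pathway.nodes.values():
        for m in n.members:
            if m not in pathway.nodes:
                raise ParseError(f"group {n.id!r}: unknown component {m!r}")
    return pathway


def parse_kgml_file(path) -> Pathway:
    with open(path, "rb") as fh:
        return parse_kgml(fh.read())


# ---------------------------------------------------------------------------
# automatic corrections
# ---------------------------------------------------------------------------


@dataclass
class CorrectionReport:
    """What :func:`autocorrect` changed, by correction class.

    Each list holds human-readable ``"src->tgt (why)"`` strings; the
    corresponding count properties equal the list lengths by construction.
    """

    compound_bridges: list[str] = field(default_factory=list)
    groups: list[str] = field(default_factory=list)
    binding_directions: list[str] = field(default_factory=list)
    missing_interactions: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def compound_bridges_added(self) -> int:
        return len(self.compound_bridges)

    @property
    def groups_resolved(self) -> int:
        return len(self.groups)

    @property
    def binding_directions_set(self) -> int:
        return len(self.binding_directions)

    @property
    def missing_interactions_added(self) -> int:
        return len(self.missing_interactions)

    @property
    def total(self) -> int:
        return (
            self.compound_bridges_added
            + self.groups_resolved
            + self.binding_directions_set
            + self.missing_interactions_added
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls, items in (
            ("compound_bridge", self.compound_bridges),
            ("group_resolved", self.groups),
            ("binding_direction", self.binding_directions),
            ("missing_interaction", self.missing_interactions),
        ):
            rows.extend({"class": cls, "detail": d} for d in items)
        return pd.DataFrame(rows, columns=["class", "detail"])


def _binding_depths(pathway: Pathway) -> dict[str, float]:
    """Multi-source BFS depth from input nodes, ignoring unresolved
    binding edges (their direction is exactly what is being decided)."""
    adjacency: dict[str, list[str]] = {n: [] for n in pathway.nodes}
    indeg = dict.fromkeys(pathway.nodes, 0)
    for e in pathway.edges:
        if e.provenance == "original" and "binding/association" in e.subtype:
            continue
        adjacency[e.source].append(e.target)
        indeg[e.target] += 1
    depths = {n: float("inf") for n in pathway.nodes}
    queue = deque(sorted(n for n in pathway.nodes if indeg[n] == 0))
    for n in queue:
        depths[n] = 0.0
    while queue:
        u = queue.popleft()
        for v in adjacency[u]:
            if depths[v] == float("inf"):
                depths[v] = depths[u] + 1
                queue.append(v)
    return depths


def autocorrect(pathway: Pathway) -> tuple[Pathway, CorrectionReport]:
    """Apply the automatic topology corrections; the input is not mutated.

    Three repairs, in order:

    1. *Compound bridging* — a relation annotated with a mediating
       compound ``c`` gets explicit ``source->c`` and ``c->target`` edges
       (impact +1) so signal can flow through the small molecule.
    2. *Group resolution* — edges touching a member of a complex are
       mirrored onto the group node, and every member receives a +1
       ``group-membership`` edge from its group (members remain nodes).
    3. *Binding direction* — each still-original ``binding/association``
       edge is oriented from the endpoint nearer the pathway inputs
       (smaller BFS depth from in-degree-0 nodes, computed without the
       unresolved binding edges); ties orient from the lexicographically
       smaller id.  Oriented edges are marked ``auto_corrected``, which
       makes the whole procedure idempotent.

    Every added or reoriented edge carries ``provenance="auto_corrected"``
    and appears in the report.  Original edges are never deleted.
    """
    p = pathway.copy()
    report = CorrectionReport()

    # 1. protein-compound-protein bridging
    for e in list(p.edges):
        if e.compound_ref is None:
            continue
        c = e.compound_ref
        if c not in p.nodes or p.nodes[c].kind != "compound":
            msg = (
                f"compound relation {e.source}->{e.target}: missing compound "
                f"entry {c!r}, correction skipped"
            )
            report.warnings.append(msg)
            log.warning(msg)
            continue
        added = False
        for s, t in ((e.source, c), (c, e.target)):
            if not p.has_edge(s, t, "compound"):
                p.add_edge(
                    PathwayEdge(source=s, target=t, impact=1, subtype="compound"),
                    provenance="auto_corrected",
                )
                added = True
        if added:
            report.compound_bridges.append(f"{e.source}->{c}->{e.target}")

    # 2. group resolution: mirror member edges onto the group ...
    member_of: dict[str, list[str]] = {}
    for n in sorted(p.nodes.values(), key=lambda n: n.id):
        if n.kind == "group":
            for m in n.members:
                member_of.setdefault(m, []).append(n.id)
    # iterate to a fixpoint: a mirrored edge may itself touch a member of
    # another (nested) group and need mirroring in turn
    grew = True
    while grew:
        grew = False
        for e in list(p.edges):
            if e.subtype == "group-membership":
                continue
            for gid in member_of.get(e.target, []):
                if e.source != gid and not p.has_edge(e.source, gid, e.subtype):
                    p.add_edge(
                        PathwayEdge(
                            source=e.source, target=gid, impact=e.impact,
                            weight=e.weight, subtype=e.subtype,
                        ),
                        provenance="auto_corrected",
                    )
                    report.missing_interactions.append(
                        f"{e.source}->{gid} (mirrored from member {e.target})"
                    )
                    grew = True
            for gid in member_of.get(e.source, []):
                if e.target != gid and not p.has_edge(gid, e.target, e.subtype):
                    p.add_edge(
                        PathwayEdge(
                            source=gid, target=e.target, impact=e.impact,
                            weight=e.weight, subtype=e.subtype,
                        ),
                        provenance="auto_corrected",
                    )
                    report.missing_interactions.append(
                        f"{gid}->{e.target} (mirrored from member {e.source})"
                    )
                    grew = True
    # ... and connect each group to its members
    for n in sorted(p.nodes.values(), key=lambda n: n.id):
        if n.kind != "group":
            continue
        added = False
        for m in n.members:
            if not p.has_edge(n.id, m, "group-membership"):
                p.add_edge(
                    PathwayEdge(
                        source=n.id, target=m, impact=1,
                        subtype="group-membership",
                    ),
                    provenance="auto_corrected",
                )
                added = True
        if added:
            report.groups.append(f"{n.id} (members {';'.join(n.members)})")

    # 3. binding direction
    depths = _binding_depths(p)
    for e in p.edges:
        if e.provenance != "original" or "binding/association" not in e.subtype:
            continue
        a, b = e.source, e.target
        da, db = depths[a], depths[b]
        if da < db:
            src, tgt = a, b
        elif db < da:
            src, tgt = b, a
        else:
            src, tgt = (a, b) if a < b else (b, a)
        flipped = (src, tgt) != (a, b)
        old = _edge_dict(e)
        e.source, e.target = src, tgt
        e.provenance = "auto_corrected"
        p._log("orient_edge", [src, tgt], old=old, new=_edge_dict(e))
        report.binding_directions.append(
            f"{src}->{tgt}" + (" (flipped)" if flipped else "")
        )

    p._log(
        "autocorrect",
        [],
        note=f"{report.total} automatic fixes",
        compound_bridges=report.compound_bridges,
        groups=report.groups,
        binding_directions=report.binding_directions,
        missing_interactions=report.missing_interactions,
    )
    p.validate()
    return p, report


# ---------------------------------------------------------------------------
# table import
# ---------------------------------------------------------------------------

_IMPACT_TOKENS = {
    "1": 1, "+1": 1, "activation": 1,
    "-1": -1, "−1": -1, "inhibition": -1,
}


def import_tables(nodes_tsv, edges_tsv) -> Pathway:
    """Build a pathway from node and edge TSV tables.

    Node columns: ``id, label, kind, gene_ids, members`` (the last two
    semicolon-separated, may be blank).  Edge columns: ``source, target,
    impact, weight, subtype`` with impact one of ``1, -1, activation,
    inhibition``.  Errors name the offending (1-based, header excluded)
    row.
    """
    nodes = pd.read_csv(nodes_tsv, sep="\t", dtype=str).fillna("")
    edges = pd.read_csv(edges_tsv, sep="\t", dtype=str).fillna("")
    for col in ("id", "label", "kind"):
        if col not in nodes.columns:
            raise ParseError(f"nodes table: missing column {col!r}")
    for col in ("source", "target", "impact"):
        if col not in edges.columns:
            raise ParseError(f"edges table: missing column {col!r}")

    p = Pathway(id="imported", name="imported")
    deferred_members: list[tuple[int, PathwayNode, list[str]]] = []
    for i, row in enumerate(nodes.itertuples(index=False), start=1):
        rid = row.id.strip()
        if not rid:
            raise ParseError(f"nodes table row {i}: empty id")
        if rid in p.nodes:
            raise ParseError(f"nodes table row {i}: duplicate node id {rid!r}")
        gene_ids = [g for g in getattr(row, "gene_ids", "").split(";") if g]
        members = [m for m in getattr(row, "members", "").split(";") if m]
        try:
            node = PathwayNode(
                id=rid, label=row.label, kind=row.kind.strip() or "gene",
                gene_ids=gene_ids, members=members, provenance="original",
            )
        except ValidationError as exc:
            raise ParseError(f"nodes table row {i}: {exc}") from None
        p.nodes[rid] = node
        if members:
            deferred_members.append((i, node, members))
    for i, node, members in deferred_members:
        for m in members:
            if m not in p.nodes:
                raise ParseError(
                    f"nodes table row {i}: group member {m!r} not a node"
                )

    for i, row in enumerate(edges.itertuples(index=False), start=1):
        token = row.impact.strip().lower()
        if token not in _IMPACT_TOKENS:
            raise ParseError(
                f"edges table row {i}: unparseable impact {row.impact!r}"
            )
        raw_weight = getattr(row, "weight", "") or "1"
        try:
            weight = float(raw_weight)
        except ValueError:
            raise ParseError(
                f"edges table row {i}: unparseable weight {raw_weight!r}"
            ) from None
        if row.source not in p.nodes:
            raise ParseError(f"edges table row {i}: unknown source {row.source!r}")
        if row.target not in p.nodes:
            raise ParseError(f"edges table row {i}: unknown target {row.target!r}")
        subtype = getattr(row, "subtype", "") or (
            "activation" if _IMPACT_TOKENS[token] == 1 else "inhibition"
        )
        try:
            edge = PathwayEdge(
                source=row.source, target=row.target,
                impact=_IMPACT_TOKENS[token], weight=weight,
                subtype=subtype, provenance="original",
            )
        except ValidationError as exc:
            raise ParseError(f"edges table row {i}: {exc}") from None
        if any(e.key == edge.key for e in p.edges):
            raise ParseError(
                f"edges table row {i}: duplicate edge "
                f"{row.source!r} -> {row.target!r}"
            )
        p.edges.append(edge)
    p.validate()
    return p


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------


def to_json(pathway: Pathway) -> str:
    """Serialize losslessly to diffable JSON (stable key order, UTF-8)."""
    doc = {
        "schema_version": JSON_SCHEMA_VERSION,
        "id": pathway.id,
        "name": pathway.name,
        "nodes": [_node_dict(pathway.nodes[k]) for k in sorted(pathway.nodes)],
        "edges": [_edge_dict(e) for e in pathway.edges],
        "curation_log": [
            {
                "timestamp": e.timestamp,
                "operation": e.operation,
                "targets": e.targets,
                "note": e.note,
                "details": e.details,
            }
            for e in pathway.curation_log
        ],
    }
    return json.dumps(doc, indent=1, ensure_ascii=False)


def from_json(text: str) -> Pathway:
    """Inverse of :func:`to_json`; ``from_json(to_json(p)) == p`` exactly."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid pathway JSON: {exc}") from None
    version = doc.get("schema_version")
    if version is None or version.split(".")[0] != JSON_SCHEMA_VERSION.split(".")[0]:
        raise ParseError(
            f"unsupported pathway JSON schema version {version!r} "
            f"(this build reads {JSON_SCHEMA_VERSION})"
        )
    p = Pathway(id=doc["id"], name=doc.get("name", ""))
    for nd in doc["nodes"]:
        node = PathwayNode(**nd)
        if node.id in p.nodes:
            raise ParseError(f"duplicate node id {node.id!r}")
        p.nodes[node.id] = node
    for ed in doc["edges"]:
        p.edges.append(PathwayEdge(**ed))
    for le in doc.get("curation_log", []):
        p.curation_log.append(CurationLogEntry(**le))
    p.validate()
    return p


def read_pathway(path) -> Pathway:
    with open(path, encoding="utf-8") as fh:
        return from_json(fh.read())


def write_pathway(pathway: Pathway, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(to_json(pathway))
        fh.write("\n")
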