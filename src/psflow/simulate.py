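"""Synthetic pathways, expression data and KGML documents.

Everything here is a pure function of a :class:`SimulationSpec` and its
seed, so fixtures regenerate identically anywhere.  The expression model
is a lognormal baseline (location 5, scale 0.5 on the natural-log scale —
positive, right-skewed values of realistic magnitude) with a designated
input-to-sink branch multiplied by a fold-change effect in the case group;
the ground truth of which nodes were perturbed is returned alongside, so
recovery and calibration experiments can score themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import Pathway, PathwayEdge, PathwayNode


@dataclass(frozen=True)
class SimulationSpec:
    """Knobs for the generators; defaults give a mid-sized signaling graph."""

    n_nodes: int = 20
    edge_probability: float = 0.25
    inhibition_fraction: float = 0.15
    cycle_injection: int = 0
    genes_per_node: int = 1
    group_fraction: float = 0.0
    effect_size: float = 4.0
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 0.5
    n_samples: int = 20  # per group
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValidationError("n_nodes must be >= 2")
        for name in ("edge_probability", "inhibition_fraction", "group_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.edge_probability == 0.0:
            raise ValidationError(
                "edge_probability 0 cannot produce a connected pathway"
            )
        if self.effect_size <= 0:
            raise ValidationError("effect_size must be > 0")


@dataclass
class GroundTruth:
    """Which branch was perturbed, and by how much."""

    branch_nodes: list[str]
    branch_genes: list[str]
    affected_sinks: list[str]
    null_sinks: list[str]
    effect_size: float

    def to_frame(self) -> pd.DataFrame:
        rows = [{"item": n, "role": "branch_node"} for n in self.branch_nodes]
        rows += [{"item": g, "role": "branch_gene"} for g in self.branch_genes]
        rows += [{"item": s, "role": "affected_sink"} for s in self.affected_sinks]
        rows += [{"item": s, "role": "null_sink"} for s in self.null_sinks]
        df = pd.DataFrame(rows, columns=["item", "role"])
        df["effect_size"] = self.effect_size
        return df


def random_pathway(spec: SimulationSpec) -> Pathway:
    """Sample a pathway: ranked-pair DAG, optional back-edge cycles.

    Nodes ``n00..`` are ranked by id; each forward pair (i < j) becomes an
    edge with probability ``edge_probability``, inhibiting with
    probability ``inhibition_fraction``.  ``cycle_injection`` back-edges
    are then added to create loops.  Every node carries
    ``genes_per_node`` distinct gene ids; a ``group_fraction`` share of
    late-ranked nodes become complexes over two earlier nodes.
    """
    rng = np.random.default_rng(spec.seed)
    width = max(2, len(str(spec.n_nodes - 1)))
    ids = [f"n{i:0{width}d}" for i in range(spec.n_nodes)]
    p = Pathway(id=f"sim{spec.seed}", name=f"simulated pathway (seed {spec.seed})")
    for i, nid in enumerate(ids):
        p.nodes[nid] = PathwayNode(
            id=nid,
            label=nid.upper(),
            kind="gene",
            gene_ids=[f"g{nid[1:]}_{k}" for k in range(spec.genes_per_node)],
            provenance="original",
        )
    edges: list[PathwayEdge] = []
    for i in range(spec.n_nodes):
        for j in range(i + 1, spec.n_nodes):
            if rng.random() < spec.edge_probability:
                inhib = rng.random() < spec.inhibition_fraction
                edges.append(
                    PathwayEdge(
                        source=ids[i], target=ids[j],
                        impact=-1 if inhib else 1,
                        subtype="inhibition" if inhib else "activation",
                        provenance="original",
                    )
                )
    p.edges = edges
    # back-edges to inject cycles
    injected = 0
    attempts = 0
    forward = {(e.source, e.target) for e in p.edges}
    while injected < spec.cycle_injection and attempts < 50 * max(1, spec.cycle_injection):
        attempts += 1
        j = int(rng.integers(1, spec.n_nodes))
        i = int(rng.integers(0, j))
        if (ids[i], ids[j]) in forward and not p.has_edge(ids[j], ids[i]):
            p.edges.append(
                PathwayEdge(
                    source=ids[j], target=ids[i], impact=1,
                    subtype="activation", provenance="original",
                )
            )
            injected += 1
    # convert a share of the last-ranked nodes into group nodes
    n_groups = int(round(spec.group_fraction * spec.n_nodes))
    candidates = [nid for nid in reversed(ids) if not any(
        nid in (e.source, e.target) for e in p.edges
    )] or list(reversed(ids))
    for nid in candidates[:n_groups]:
        pool = [x for x in ids if x != nid and p.nodes[x].kind == "gene"]
        members = sorted(
            str(m) for m in rng.choice(pool, size=min(2, len(pool)), replace=False)
        )
        n = p.nodes[nid]
        n.kind = "group"
        n.gene_ids = []
        n.members = members
    p.validate()
    return p


def _choose_branch(pathway: Pathway, rng: np.random.Generator) -> list[str]:
    """A random input->sink path (list of node ids), seeded."""
    inputs = pathway.input_nodes()
    if not inputs:
        raise ValidationError("pathway has no input node (in-degree 0)")
    out_adj: dict[str, list[str]] = {n: [] for n in pathway.nodes}
    for e in pathway.edges:
        out_adj[e.source].append(e.target)
    for n in out_adj:
        out_adj[n] = sorted(set(out_adj[n]))
    start = inputs[int(rng.integers(len(inputs)))]
    path = [start]
    seen = {start}
    cur = start
    while out_adj[cur]:
        nxt = [t for t in out_adj[cur] if t not in seen]
        if not nxt:
            break
        cur = nxt[int(rng.integers(len(nxt)))]
        path.append(cur)
        seen.add(cur)
    return path


def perturbed_expression(
    pathway: Pathway, spec: SimulationSpec
) -> tuple["pd.DataFrame", dict[str, str], GroundTruth]:
    """Two-group expression with one perturbed input->sink branch.

    Control samples are iid lognormal; case samples multiply the branch
    genes by ``spec.effect_size``.  Returns (genes x samples values,
    sample -> group labels, ground truth).  Sinks reachable from any
    branch node are ``affected_sinks``; the rest are ``null_sinks`` whose
    genes carry no group effect.
    """
    rng = np.random.default_rng(spec.seed + 1)
    branch = _choose_branch(pathway, rng)
    branch_genes = sorted(
        g for nid in branch for g in pathway.nodes[nid].gene_ids
    )
    genes = sorted(
        {g for n in pathway.nodes.values() for g in n.gene_ids}
    )
    n_per = spec.n_samples
    samples = [f"ctrl{j:02d}" for j in range(n_per)] + [
        f"case{j:02d}" for j in range(n_per)
    ]
    vals = np.exp(
        rng.normal(spec.baseline_log_mean, spec.baseline_log_sd,
                   size=(len(genes), 2 * n_per))
    )
    branch_rows = [genes.index(g) for g in branch_genes]
    vals[np.ix_(branch_rows, range(n_per, 2 * n_per))] *= spec.effect_size
    df = pd.DataFrame(vals, index=genes, columns=samples)
    labels = {s: ("case" if s.startswith("case") else "control") for s in samples}

    g = pathway.to_networkx()
    import networkx as nx

    reachable: set[str] = set(branch)
    for nid in branch:
        reachable |= nx.descendants(g, nid)
    sinks = pathway.sinks()
    truth = GroundTruth(
        branch_nodes=list(branch),
        branch_genes=branch_genes,
        affected_sinks=[s for s in sinks if s in reachable],
        null_sinks=[s for s in sinks if s not in reachable],
        effect_size=spec.effect_size,
    )
    return df, labels, truth


# ---------------------------------------------------------------------------
# KGML fixture writing
# ---------------------------------------------------------------------------

_KGML_EXPRESSIBLE_KINDS = {"gene", "compound", "group", "map"}


def write_kgml_fixture(pathway: Pathway) -> str:
    """Serialize a pathway as KGML so the parser can be round-trip tested.

    ``parse_kgml(write_kgml_fixture(p))`` equals ``p`` up to provenance
    fields.  Only KGML-expressible content is allowed: node kinds gene/
    compound/group/map, unit edge weights, subtypes whose sign matches the
    edge impact; anything else raises listing the offending feature.
    """
    from lxml import etree

    from .kgml import impact_for_subtype

    problems: list[str] = []
    for n in pathway.nodes.values():
        if n.kind not in _KGML_EXPRESSIBLE_KINDS:
            problems.append(f"node {n.id}: kind {n.kind!r} not expressible")
    for e in pathway.edges:
        if e.weight != 1.0:
            problems.append(
                f"edge {e.source}->{e.target}: non-unit weight {e.weight}"
            )
        if impact_for_subtype(e.subtype) != e.impact:
            problems.append(
                f"edge {e.source}->{e.target}: impact {e.impact} conflicts "
                f"with subtype {e.subtype!r}"
            )
    if problems:
        raise ValidationError(
            "pathway not expressible as KGML: " + "; ".join(problems)
        )

    root = etree.Element("pathway", name=pathway.id, title=pathway.name)
    for nid in sorted(pathway.nodes):
        n = pathway.nodes[nid]
        entry = etree.SubElement(
            root, "entry", id=n.id, name=" ".join(n.gene_ids), type=n.kind
        )
        if n.label:
            etree.SubElement(entry, "graphics", name=n.label)
        for m in n.members:
            etree.SubElement(entry, "component", id=m)
    for e in pathway.edges:
        rel = etree.SubElement(
            root, "relation", entry1=e.source, entry2=e.target, type="PPrel"
        )
        for part in e.subtype.split("+"):
            sub = etree.SubElement(rel, "subtype", name=part)
            if part in ("compound", "hidden compound") and e.compound_ref:
                sub.set("value", e.compound_ref)
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode("utf-8")
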