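"""Pathway signal flow: propagate fold changes from inputs to sinks.

The node signal recurrence, evaluated from the pathway inputs (in-degree-0
nodes, the ligand/receptor level) toward the terminal branch sinks:

    S_j = FC_j                                          (input nodes)
    S_j = FC_j * sum_{i in Inc(j)} p_i * w_ij * S_i^K_ij   (otherwise)

with the incoming-signal proportions p_i = S_i / sum_{k in Inc(j)} S_k.
FC_j is the node's positive linear fold change, w_ij the positive edge
weight (default 1) and K_ij the impact, +1 for activation and -1 for
inhibition — so an inhibiting parent enters as the *reciprocal* of its
signal.  With all fold changes at the neutral value 1 every signal is 1.

Cycles are handled by condensing the graph into strongly connected
components: the condensation is evaluated in topological order, and each
nontrivial SCC (or self-loop) is iterated with fixed-point sweeps over its
members in lexicographic order until the largest relative signal change
drops below ``tol`` (default 1e-6) or ``max_sweeps`` is reached.  No edge
is ever deleted to break a loop.

Internally signals are numpy arrays, so the same code path evaluates one
fold-change assignment or thousands of bootstrap replicates at once
(:func:`propagate_batch`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import Pathway

#: signals are clipped into this range to keep them finite and positive
_SIGNAL_FLOOR = 1e-300
_SIGNAL_CEIL = 1e300


@dataclass
class SCCDiagnostic:
    nodes: list[str]
    sweeps: int
    converged: bool


@dataclass
class PSFResult:
    """Signals for every node of one pathway under one FC assignment."""

    pathway_id: str
    signals: dict[str, float]
    order: list[str]
    sinks: list[str]
    sink_signals: dict[str, float]
    fold_changes: dict[str, float]
    labels: dict[str, str]
    scc_diagnostics: list[SCCDiagnostic] = field(default_factory=list)

    @property
    def converged(self) -> bool:
        return all(d.converged for d in self.scc_diagnostics)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "node": nid,
                "label": self.labels.get(nid, ""),
                "fold_change": self.fold_changes[nid],
                "signal": self.signals[nid],
            }
            for nid in sorted(self.signals)
        ]
        return pd.DataFrame(rows)


def evaluation_order(pathway: Pathway) -> tuple[list[str], list[list[str]]]:
    """Topological node order over the SCC condensation.

    Returns the flat node order (within-SCC ties broken lexicographically,
    SCC blocks ordered by a deterministic topological sort of the
    condensation) and the list of nontrivial SCCs (size > 1).
    """
    if not pathway.nodes:
        raise ValidationError("evaluation_order: empty pathway")
    blocks = _scc_blocks(pathway)
    order = [n for block in blocks for n in block]
    sccs = [block for block in blocks if len(block) > 1]
    return order, sccs


def _scc_blocks(pathway: Pathway) -> list[list[str]]:
    g = pathway.to_networkx()
    cond = nx.condensation(g)
    members = {c: sorted(cond.nodes[c]["members"]) for c in cond.nodes}
    # deterministic topological order: break ties by smallest member id
    topo = nx.lexicographical_topological_sort(cond, key=lambda c: members[c][0])
    return [members[c] for c in topo]


def propagate_batch(
    pathway: Pathway,
    node_fc: Mapping[str, np.ndarray],
    tol: float = 1e-6,
    max_sweeps: int = 100,
) -> tuple[dict[str, np.ndarray], list[SCCDiagnostic]]:
    """Evaluate the recurrence for many FC assignments at once.

    ``node_fc`` maps every node id to an array of fold changes (all the
    same length m); element k of each array forms the k-th assignment.
    Returns per-node signal arrays plus per-SCC iteration diagnostics.
    """
    for nid in pathway.nodes:
        if nid not in node_fc:
            raise ValidationError(f"no fold change provided for node {nid!r}")
        arr = np.asarray(node_fc[nid], dtype=float)
        if not np.all(arr > 0) or not np.all(np.isfinite(arr)):
            raise ValidationError(
                f"fold change for node {nid!r} must be positive and finite"
            )

    incoming: dict[str, list[tuple[str, float, int]]] = {n: [] for n in pathway.nodes}
    seen_pairs: set[tuple[str, str]] = set()
    for e in pathway.edges:
        if (e.source, e.target) in seen_pairs:
            continue  # parallel subtypes collapse to the first arc
        seen_pairs.add((e.source, e.target))
        incoming[e.target].append((e.source, e.weight, e.impact))

    signals: dict[str, np.ndarray] = {}
    diagnostics: list[SCCDiagnostic] = []

    def updated(j: str) -> np.ndarray:
        inc = incoming[j]
        denom = np.zeros_like(signals[inc[0][0]])
        for i, _, _ in inc:
            denom = denom + signals[i]
        total = np.zeros_like(denom)
        for i, w, k in inc:
            si = signals[i]
            term = si if k == 1 else 1.0 / si
            total = total + (si / denom) * w * term
        fc = np.asarray(node_fc[j], dtype=float)
        return np.clip(fc * total, _SIGNAL_FLOOR, _SIGNAL_CEIL)

    for block in _scc_blocks(pathway):
        has_self_loop = any(
            i == block[0] for (i, _, _) in incoming[block[0]]
        ) if len(block) == 1 else False
        if len(block) == 1 and not has_self_loop:
            j = block[0]
            if not incoming[j]:
                signals[j] = np.asarray(node_fc[j], dtype=float).copy()
            else:
                signals[j] = updated(j)
            continue
        # nontrivial SCC (or self-loop): fixed-point sweeps
        for j in block:
            signals[j] = np.asarray(node_fc[j], dtype=float).copy()
        converged = False
        sweeps = 0
        while sweeps < max_sweeps and not converged:
            sweeps += 1
            max_rel = 0.0
            for j in block:
                new = updated(j)
                rel = np.max(np.abs(new - signals[j]) / signals[j])
                max_rel = max(max_rel, float(rel))
                signals[j] = new
            converged = max_rel < tol
        diagnostics.append(
            SCCDiagnostic(nodes=list(block), sweeps=sweeps, converged=converged)
        )
    return signals, diagnostics


def propagate(pathway: Pathway, tol: float = 1e-6, max_sweeps: int = 100) -> PSFResult:
    """Propagate the pathway's node fold changes; returns per-node signals.

    Node fold changes must already be set (see
    :func:`psflow.expression.map_to_nodes`); all of them must be positive.
    """
    node_fc = {
        nid: np.array([n.fold_change]) for nid, n in pathway.nodes.items()
    }
    signals, diagnostics = propagate_batch(
        pathway, node_fc, tol=tol, max_sweeps=max_sweeps
    )
    order, _ = evaluation_order(pathway)
    sinks = pathway.sinks()
    flat = {nid: float(v[0]) for nid, v in signals.items()}
    return PSFResult(
        pathway_id=pathway.id,
        signals=flat,
        order=order,
        sinks=sinks,
        sink_signals={s: flat[s] for s in sinks},
        fold_changes={nid: n.fold_change for nid, n in pathway.nodes.items()},
        labels={nid: n.label for nid, n in pathway.nodes.items()},
        scc_diagnostics=diagnostics,
    )


def sink_summary(result: PSFResult) -> pd.DataFrame:
    """One row per terminal (sink) node: id, label, signal, log2 signal."""
    rows = [
        {
            "sink": s,
            "label": result.labels.get(s, ""),
            "signal": result.sink_signals[s],
            "log2_signal": float(np.log2(result.sink_signals[s])),
        }
        for s in sorted(result.sink_signals)
    ]
    return pd.DataFrame(rows)


def activity_matrix(
    pathways: list[Pathway],
    fc_maps: Mapping[str, Mapping[str, float]],
    missing_default: float = 1.0,
) -> pd.DataFrame:
    """Pathway-branch activity across many samples.

    For each pathway and each sample's fold-change map, maps genes to
    nodes and propagates; rows are ``pathway_id:sink``, columns samples,
    values log2 sink signals.  All samples of one pathway are evaluated in
    a single vectorized batch.
    """
    from .expression import map_to_nodes  # local import avoids a cycle

    sample_ids = list(fc_maps.keys())
    rows = {}
    for pw in pathways:
        mapped = [
            map_to_nodes(pw, dict(fc_maps[s]), missing_default=missing_default)
            for s in sample_ids
        ]
        node_fc = {
            nid: np.array([m.nodes[nid].fold_change for m in mapped])
            for nid in pw.nodes
        }
        signals, _ = propagate_batch(pw, node_fc)
        for s in pw.sinks():
            rows[f"{pw.id}:{s}"] = np.log2(signals[s])
    return pd.DataFrame(rows, index=sample_ids).T
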