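"""Bootstrap significance of pathway-branch (sink) signals.

Whether an observed sink signal could arise by chance is assessed by
re-running the propagation under a permutation null and counting how often
the null produces a signal at least as extreme as the observed one:

    p = (1 + #{iterations at least as extreme}) / (n_iterations + 1)

The plus-one correction makes these valid permutation p-values that are
never exactly 0.  "Extreme" is measured on the log-signal scale —
signals are multiplicative — as |log S*| >= |log S_obs|, i.e. at least as
far from the neutral signal 1 as the observation (two-sided default).

Two reshuffling modes:

* **gene shuffle** — permute the observed fold-change values among the
  pathway's own mapped genes (the value multiset is preserved exactly),
* **label shuffle** — permute the sample-group labels, preserving group
  sizes, and recompute fold changes from the expression matrix each time.

All iterations are evaluated in one vectorized propagation batch, and all
randomness flows from a single seeded ``numpy.random.default_rng`` (PCG64)
stream, so a fixed seed reproduces results bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .expression import (
    ExpressionMatrix,
    FoldChangeMap,
    fold_changes,
    map_to_nodes,
    validate_fold_changes,
)
from .engine import propagate, propagate_batch
from .model import Pathway

ALTERNATIVES = ("two_sided", "greater", "less")
NULL_CENTERS = ("observed", "neutral")

#: slack when comparing null to observed log signals, so that an exactly
#: reproduced observation (e.g. the identity permutation on tied values)
#: always counts as "at least as extreme"
_TIE_EPS = 1e-12


@dataclass(frozen=True)
class BootstrapConfig:
    mode: str = "gene_shuffle"
    n_iterations: int = 2000
    seed: int = 0
    alternative: str = "two_sided"
    null_center: str = "observed"
    missing_default: float = 1.0
    tol: float = 1e-6
    max_sweeps: int = 100

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValidationError("n_iterations must be >= 1")
        if self.alternative not in ALTERNATIVES:
            raise ValidationError(f"unknown alternative {self.alternative!r}")
        if self.null_center not in NULL_CENTERS:
            raise ValidationError(f"unknown null_center {self.null_center!r}")
        if self.mode not in ("gene_shuffle", "label_shuffle"):
            raise ValidationError(f"unknown mode {self.mode!r}")


@dataclass
class BootstrapResult:
    """Per-sink empirical significance for one pathway."""

    pathway_id: str
    table: pd.DataFrame  # sink, observed_signal, p_value, q_value, ...
    config: BootstrapConfig

    @property
    def p_values(self) -> pd.Series:
        return self.table.set_index("sink")["p_value"]

    @property
    def q_values(self) -> pd.Series:
        return self.table.set_index("sink")["q_value"]


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (empty in, empty out)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _pathway_gene_ids(pathway: Pathway) -> list[str]:
    genes: set[str] = set()
    for n in pathway.nodes.values():
        if n.kind == "gene":
            genes.update(n.gene_ids)
    return sorted(genes)


def _node_log_fc_arrays(
    pathway: Pathway,
    gene_row: dict[str, int],
    log_values: np.ndarray,
    default_log: float = 0.0,
) -> dict[str, np.ndarray]:
    """Per-node log-FC arrays from a (genes x iterations) log-value matrix,
    mirroring the geometric-mean aggregation of ``map_to_nodes``."""
    m = log_values.shape[1]
    out: dict[str, np.ndarray] = {}

    def resolve(nid: str, stack: tuple[str, ...] = ()) -> np.ndarray:
        if nid in out:
            return out[nid]
        if nid in stack:
            raise ValidationError(f"group membership cycle at {nid!r}")
        n = pathway.nodes[nid]
        if n.kind == "group":
            member_logs = [resolve(m_, stack + (nid,)) for m_ in n.members]
            arr = np.mean(member_logs, axis=0)
        elif n.kind == "gene":
            rows = [gene_row[g] for g in n.gene_ids if g in gene_row]
            arr = (
                log_values[rows].mean(axis=0)
                if rows
                else np.full(m, default_log)
            )
        else:
            arr = np.full(m, default_log)
        out[nid] = arr
        return arr

    for nid in sorted(pathway.nodes):
        resolve(nid)
    return out


def permuted_value_matrix(
    values: np.ndarray, n_iterations: int, rng: np.random.Generator
) -> np.ndarray:
    """(len(values) x n_iterations) matrix whose every column is an
    independent uniform permutation of ``values`` — the multiset is
    preserved exactly in each iteration."""
    n = int(n_iterations)
    return rng.permuted(
        np.broadcast_to(values, (n, values.size)).copy(), axis=1
    ).T


def _empirical_p(
    null_log: np.ndarray, obs_log: float, alternative: str, null_center: str
) -> float:
    n = null_log.size
    if null_center == "neutral":
        center = float(null_log.mean())
        null_log = null_log - center
        obs_log = obs_log - center
    if alternative == "two_sided":
        hits = np.abs(null_log) >= np.abs(obs_log) - _TIE_EPS
    elif alternative == "greater":
        hits = null_log >= obs_log - _TIE_EPS
    else:
        hits = null_log <= obs_log + _TIE_EPS
    return (1 + int(hits.sum())) / (n + 1)


def _assemble(
    pathway: Pathway,
    observed,
    sink_null: dict[str, np.ndarray],
    config: BootstrapConfig,
) -> BootstrapResult:
    rows = []
    for s in sorted(sink_null):
        null_log = np.log(sink_null[s])
        obs = observed.sink_signals[s]
        rows.append(
            {
                "sink": s,
                "label": observed.labels.get(s, ""),
                "observed_signal": obs,
                "log2_observed": float(np.log2(obs)),
                "p_value": _empirical_p(
                    null_log, float(np.log(obs)), config.alternative,
                    config.null_center,
                ),
                "boot_log_mean": float(null_log.mean()),
                "boot_log_sd": float(null_log.std(ddof=1)) if null_log.size > 1 else 0.0,
            }
        )
    table = pd.DataFrame(rows)
    table["q_value"] = adjust_bh(table["p_value"]) if len(table) else []
    return BootstrapResult(pathway_id=pathway.id, table=table, config=config)


def bootstrap_gene_shuffle(
    pathway: Pathway, fc: FoldChangeMap, config: Optional[BootstrapConfig] = None
) -> BootstrapResult:
    """Permutation null: reshuffle FC values among the pathway's genes.

    Each iteration reassigns the observed fold-change values (drawn
    without replacement from the pathway's own FC multiset) to the
    pathway's mapped genes, remaps nodes and re-propagates.  Needs at
    least two mapped genes, otherwise the permutation group is degenerate.
    """
    config = replace(config or BootstrapConfig(), mode="gene_shuffle")
    validate_fold_changes(fc)
    mapped = [g for g in _pathway_gene_ids(pathway) if g in fc]
    if len(mapped) < 2:
        raise ValidationError(
            f"gene shuffle needs >= 2 mapped genes, found {len(mapped)}"
        )
    observed = propagate(
        map_to_nodes(pathway, fc, missing_default=config.missing_default),
        tol=config.tol, max_sweeps=config.max_sweeps,
    )

    rng = np.random.default_rng(config.seed)
    values = np.array([fc[g] for g in mapped], dtype=float)
    perm = permuted_value_matrix(values, config.n_iterations, rng)
    gene_row = {g: i for i, g in enumerate(mapped)}
    node_log = _node_log_fc_arrays(
        pathway, gene_row, np.log(perm),
        default_log=float(np.log(config.missing_default)),
    )
    node_fc = {nid: np.exp(arr) for nid, arr in node_log.items()}
    signals, _ = propagate_batch(
        pathway, node_fc, tol=config.tol, max_sweeps=config.max_sweeps
    )
    sink_null = {s: signals[s] for s in pathway.sinks()}
    return _assemble(pathway, observed, sink_null, config)


def bootstrap_label_shuffle(
    pathway: Pathway,
    expr: ExpressionMatrix,
    case_group: str,
    control_group: str,
    config: Optional[BootstrapConfig] = None,
    pseudocount: float = 1.0,
) -> BootstrapResult:
    """Permutation null: reshuffle sample-group labels.

    Each iteration permutes the case/control assignment over the pooled
    samples (group sizes preserved), recomputes per-gene fold changes and
    re-propagates.  Both groups need at least two samples.
    """
    config = replace(config or BootstrapConfig(), mode="label_shuffle")
    case = expr.samples_in(case_group)
    ctrl = expr.samples_in(control_group)
    if len(case) < 2 or len(ctrl) < 2:
        raise ValidationError(
            f"label shuffle needs >= 2 samples per group "
            f"(case {len(case)}, control {len(ctrl)})"
        )
    obs_fc = fold_changes(expr, case_group, control_group, pseudocount)
    observed = propagate(
        map_to_nodes(pathway, obs_fc, missing_default=config.missing_default),
        tol=config.tol, max_sweeps=config.max_sweeps,
    )

    genes = [g for g in _pathway_gene_ids(pathway) if g in expr.values.index]
    samples = case + ctrl
    e = expr.values.loc[genes, samples].to_numpy(dtype=float) if genes else np.zeros((0, len(samples)))
    n_case, n_s = len(case), len(samples)
    n = config.n_iterations

    rng = np.random.default_rng(config.seed)
    # one label permutation per iteration, as a boolean case mask
    ranks = np.argsort(rng.random((n, n_s)), axis=1)
    case_mask = ranks < n_case  # iterations x samples
    mc = (e @ case_mask.T.astype(float)) / n_case + pseudocount
    mk = (e @ (~case_mask).T.astype(float)) / (n_s - n_case) + pseudocount
    if np.any(mk == 0) or np.any(mc == 0):
        raise ValidationError(
            "zero group mean with pseudocount 0; use a positive pseudocount"
        )
    log_fc = np.log(mc) - np.log(mk)  # genes x iterations
    gene_row = {g: i for i, g in enumerate(genes)}
    node_log = _node_log_fc_arrays(
        pathway, gene_row, log_fc,
        default_log=float(np.log(config.missing_default)),
    )
    node_fc = {nid: np.exp(arr) for nid, arr in node_log.items()}
    signals, _ = propagate_batch(
        pathway, node_fc, tol=config.tol, max_sweeps=config.max_sweeps
    )
    sink_null = {s: signals[s] for s in pathway.sinks()}
    return _assemble(pathway, observed, sink_null, config)


def combine_results(results: list[BootstrapResult]) -> pd.DataFrame:
    """Concatenate per-pathway tables and re-adjust BH across *all* sinks
    of the invocation (one multiple-testing family per run)."""
    frames = []
    for r in results:
        t = r.table.copy()
        t.insert(0, "pathway", r.pathway_id)
        frames.append(t)
    if not frames:
        return pd.DataFrame()
    combined = pd.concat(frames, ignore_index=True)
    combined["q_value"] = adjust_bh(combined["p_value"])
    return combined
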