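"""From expression matrices to the positive fold changes propagation needs.

The propagation engine consumes *linear-scale* fold changes: inhibition
enters the recurrence as a reciprocal on the parent signal, which is only
meaningful for strictly positive values.  Log-scale inputs must be
exponentiated by the caller (the CLI offers ``--log2-input``).

Multi-gene nodes and complexes aggregate by geometric mean — fold changes
are multiplicative, and an arithmetic mean would bias upward.  Genes with
no measurement default to the neutral FC 1 so they transmit signal without
distorting it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import Pathway

log = logging.getLogger(__name__)

#: gene id -> positive linear fold change
FoldChangeMap = dict


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of nonnegative values plus sample groups."""

    values: pd.DataFrame  # rows: gene ids, columns: sample ids
    groups: dict[str, str] = field(default_factory=dict)  # sample -> group

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise ValidationError("expression matrix: duplicate gene ids")
        if v.columns.has_duplicates:
            raise ValidationError("expression matrix: duplicate sample ids")
        if (v.values < 0).any():
            raise ValidationError("expression matrix: negative values")
        unknown = set(self.groups) - set(v.columns)
        if unknown:
            raise ValidationError(
                f"group labels for unknown samples: {sorted(unknown)}"
            )

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups.get(s) == group]


@dataclass
class IsoformTable:
    """Per-gene isoform fractions with coding flags.

    Fractions of all isoforms of one gene must sum to 1 (tolerance 1e-6).
    """

    table: pd.DataFrame  # columns: gene, isoform, fraction, coding

    def __post_init__(self) -> None:
        required = {"gene", "isoform", "fraction", "coding"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"isoform table: missing columns {sorted(missing)}")

    def coding_fraction(self) -> pd.Series:
        """Total coding-isoform fraction per gene; validates the sum-to-1
        invariant and raises naming the first offending gene."""
        sums = self.table.groupby("gene")["fraction"].sum()
        bad = sums[(sums - 1.0).abs() > 1e-6]
        if not bad.empty:
            g = bad.index[0]
            raise ValidationError(
                f"isoform fractions for gene {g!r} sum to {bad.iloc[0]:g}, not 1"
            )
        coding = self.table[self.table["coding"].astype(bool)]
        frac = coding.groupby("gene")["fraction"].sum()
        return frac.reindex(sums.index, fill_value=0.0)


def validate_fold_changes(fc: FoldChangeMap) -> None:
    for g, v in fc.items():
        if not (v > 0) or not np.isfinite(v):
            raise ValidationError(
                f"fold change for gene {g!r} must be positive and finite, got {v!r}"
            )


def fold_changes(
    expr: ExpressionMatrix,
    case_group: str,
    control_group: str,
    pseudocount: float = 1.0,
) -> FoldChangeMap:
    """Per-gene linear fold change between two sample groups.

    ``FC_g = (mean_case + pseudocount) / (mean_control + pseudocount)``.
    The default pseudocount of 1 keeps all-zero genes finite; with
    pseudocount 0 an all-zero gene is an error.
    """
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    case = expr.samples_in(case_group)
    ctrl = expr.samples_in(control_group)
    if not case or not ctrl:
        raise ValidationError(
            f"empty group (case {case_group!r}: {len(case)} samples, "
            f"control {control_group!r}: {len(ctrl)} samples)"
        )
    if set(case) & set(ctrl):
        raise ValidationError("case and control groups overlap")
    mc = expr.values[case].mean(axis=1) + pseudocount
    mk = expr.values[ctrl].mean(axis=1) + pseudocount
    if (mk == 0).any():
        g = mk.index[(mk == 0).values][0]
        raise ValidationError(
            f"gene {g!r} has zero control mean and pseudocount 0"
        )
    return dict(zip(mc.index, (mc / mk).astype(float)))


def coding_adjust(expr: ExpressionMatrix, isoforms: IsoformTable) -> ExpressionMatrix:
    """Scale each gene's expression by its total coding-isoform fraction.

    Overall gene expression need not reflect the part that is translated;
    multiplying by the coding fraction keeps only the protein-producing
    share.  Genes absent from the isoform table pass through unchanged
    (with a warning).
    """
    frac = isoforms.coding_fraction()
    missing = expr.values.index.difference(frac.index)
    if len(missing):
        log.warning(
            "coding_adjust: %d gene(s) absent from isoform table pass "
            "through unchanged (e.g. %s)", len(missing), list(missing[:3])
        )
    factors = frac.reindex(expr.values.index, fill_value=1.0)
    return ExpressionMatrix(
        values=expr.values.mul(factors, axis=0), groups=dict(expr.groups)
    )


def map_to_nodes(
    pathway: Pathway, fc: FoldChangeMap, missing_default: float = 1.0
) -> Pathway:
    """Assign node fold changes from a gene-level map; returns a copy.

    Gene nodes take the geometric mean of the mapped FCs of their
    ``gene_ids``; group nodes the geometric mean over their members'
    assigned FCs (nested groups resolve recursively); compound/map/process
    nodes and unmatched genes take ``missing_default``.  Each node records
    how many of its genes matched (``fc_matched``).
    """
    validate_fold_changes(fc)
    if not (missing_default > 0):
        raise ValidationError("missing_default must be > 0")
    p = pathway.copy()

    for n in p.nodes.values():
        if n.kind == "group":
            continue
        hits = [fc[g] for g in n.gene_ids if g in fc] if n.kind == "gene" else []
        n.fc_matched = len(hits)
        n.fold_change = (
            float(np.exp(np.mean(np.log(hits)))) if hits else missing_default
        )

    resolved: set[str] = set()

    def resolve_group(nid: str, stack: tuple[str, ...] = ()) -> None:
        n = p.nodes[nid]
        if n.kind != "group" or nid in resolved:
            return
        if nid in stack:
            raise ValidationError(f"group membership cycle at {nid!r}")
        for m in n.members:
            resolve_group(m, stack + (nid,))
        vals = [p.nodes[m].fold_change for m in n.members]
        n.fold_change = float(np.exp(np.mean(np.log(vals))))
        n.fc_matched = sum(p.nodes[m].fc_matched or 0 for m in n.members)
        resolved.add(nid)

    for nid in sorted(p.nodes):
        resolve_group(nid)
    return p


# ---------------------------------------------------------------------------
# TSV readers/writers
# ---------------------------------------------------------------------------


def read_fold_changes(path, log2_input: bool = False) -> FoldChangeMap:
    """Read a ``gene<TAB>fc`` table; ``log2_input`` exponentiates base 2."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected columns gene<TAB>fc")
    genes = df.iloc[:, 0].astype(str)
    vals = df.iloc[:, 1].astype(float)
    if log2_input:
        vals = np.power(2.0, vals)
    fc = dict(zip(genes, vals))
    validate_fold_changes(fc)
    return fc


def write_fold_changes(fc: FoldChangeMap, path) -> None:
    pd.DataFrame(
        {"gene": list(fc.keys()), "fc": list(fc.values())}
    ).to_csv(path, sep="\t", index=False)


def read_expression(values_path, groups_path=None) -> ExpressionMatrix:
    """Dense genes x samples TSV (first column gene id) plus an optional
    ``sample<TAB>group`` label table."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    groups: dict[str, str] = {}
    if groups_path is not None:
        gdf = pd.read_csv(groups_path, sep="\t")
        groups = dict(zip(gdf.iloc[:, 0].astype(str), gdf.iloc[:, 1].astype(str)))
    return ExpressionMatrix(values=values, groups=groups)


def read_isoforms(path) -> IsoformTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "isoform": str})
    return IsoformTable(table=df)
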