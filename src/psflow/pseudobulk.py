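"""Pseudo-bulk aggregation of single-cell expression.

Sparse single-cell profiles are too noisy to drive signal propagation
directly.  The remedy: from each cell group (tissue, cluster) draw up to
``max_cells_per_group`` cells (default 5000), partition them into
consecutive chunks of ``chunk_size`` (default 50) and sum gene-wise —
yielding dense pseudo-bulk samples.  Fold changes are then taken per
pseudo-sample against the global mean over all pseudo-samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .expression import FoldChangeMap


def make_pseudobulk(
    cells: pd.DataFrame,
    labels: dict[str, str],
    chunk_size: int = 50,
    max_cells_per_group: int = 5000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Sum chunks of cells into pseudo-bulk samples, per group.

    ``cells`` is genes x cells (nonnegative); ``labels`` maps every cell
    to its group.  Per group, ``min(max_cells_per_group,
    floor(n/chunk)*chunk)`` cells are drawn uniformly without replacement
    (seeded) and summed in consecutive chunks of ``chunk_size``; leftover
    cells (n mod chunk) are dropped.  Returns the pseudo-bulk matrix and
    the pseudo-sample -> group map.
    """
    if chunk_size < 1:
        raise ValidationError("chunk_size must be >= 1")
    if (cells.values < 0).any():
        raise ValidationError("cell matrix contains negative values")
    missing = [c for c in cells.columns if c not in labels]
    if missing:
        raise ValidationError(
            f"{len(missing)} cell(s) without group label (e.g. {missing[:3]})"
        )
    rng = np.random.default_rng(seed)
    groups = sorted({labels[c] for c in cells.columns})
    out_cols: dict[str, np.ndarray] = {}
    sample_groups: dict[str, str] = {}
    for grp in groups:
        members = [c for c in cells.columns if labels[c] == grp]
        if len(members) < chunk_size:
            raise ValidationError(
                f"group {grp!r} has {len(members)} cells, fewer than the "
                f"chunk size {chunk_size}"
            )
        n_take = min(max_cells_per_group, len(members))
        n_take = (n_take // chunk_size) * chunk_size
        chosen = rng.choice(len(members), size=n_take, replace=False)
        block = cells[[members[i] for i in chosen]].to_numpy(dtype=float)
        n_chunks = n_take // chunk_size
        sums = block.reshape(block.shape[0], n_chunks, chunk_size).sum(axis=2)
        for k in range(n_chunks):
            name = f"{grp}_pb{k:03d}"
            out_cols[name] = sums[:, k]
            sample_groups[name] = grp
    pb = pd.DataFrame(out_cols, index=cells.index)
    return pb, sample_groups


def global_mean_fold_change(
    pseudobulk: pd.DataFrame, pseudocount: float = 1.0
) -> dict[str, FoldChangeMap]:
    """Per-pseudo-sample fold changes against the global mean.

    ``FC_g,s = (x_g,s + pseudocount) / (mean_s'(x_g,s') + pseudocount)``.
    With pseudocount 0 and no all-zero rows, the per-gene mean of FCs
    across pseudo-samples is exactly 1.
    """
    if pseudobulk.shape[1] < 1:
        raise ValidationError("need at least one pseudo-sample")
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    gmean = pseudobulk.mean(axis=1).to_numpy() + pseudocount
    if (gmean <= 0).any():
        bad = pseudobulk.index[(gmean <= 0)][0]
        raise ValidationError(
            f"gene {bad!r}: zero global mean with pseudocount 0"
        )
    out: dict[str, FoldChangeMap] = {}
    for s in pseudobulk.columns:
        vals = (pseudobulk[s].to_numpy() + pseudocount) / gmean
        out[s] = dict(zip(pseudobulk.index, vals.astype(float)))
    return out


def read_cell_matrix(matrix_path, genes_path=None, cells_path=None) -> pd.DataFrame:
    """Read genes x cells expression, dense TSV or MatrixMarket + sidecars."""
    path = str(matrix_path)
    if path.endswith(".mtx"):
        from scipy.io import mmread

        if genes_path is None or cells_path is None:
            raise ValidationError(
                "MTX input needs --genes and --cells sidecar files"
            )
        m = mmread(path).toarray()
        genes = pd.read_csv(genes_path, sep="\t", header=None).iloc[:, 0].astype(str)
        cells = pd.read_csv(cells_path, sep="\t", header=None).iloc[:, 0].astype(str)
        if m.shape != (len(genes), len(cells)):
            raise ValidationError(
                f"matrix shape {m.shape} does not match sidecars "
                f"({len(genes)} genes, {len(cells)} cells)"
            )
        return pd.DataFrame(m, index=genes, columns=cells)
    return pd.read_csv(path, sep="\t", index_col=0)


def read_labels(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
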