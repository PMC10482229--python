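"""Single-cell to pathway-branch activity via pseudo-bulk aggregation.

Simulates two cell populations whose pathway-input genes differ, sums
cells into pseudo-bulk samples (chunks of 50), derives per-sample fold
changes against the global mean, and propagates each sample through a
pathway — yielding a branch x pseudo-sample activity matrix.
"""

import numpy as np
import pandas as pd

from psflow import (
    SimulationSpec,
    activity_matrix,
    global_mean_fold_change,
    make_pseudobulk,
    random_pathway,
)

pathway = random_pathway(SimulationSpec(n_nodes=15, edge_probability=0.25, seed=5))
genes = sorted(g for n in pathway.nodes.values() for g in n.gene_ids)
input_genes = {g for nid in pathway.input_nodes()
               for g in pathway.nodes[nid].gene_ids}

rng = np.random.default_rng(5)
n_cells = 400  # per population
base = rng.poisson(5.0, size=(len(genes), 2 * n_cells)).astype(float)
cells = pd.DataFrame(
    base,
    index=genes,
    columns=[f"tA_{i}" for i in range(n_cells)] + [f"tB_{i}" for i in range(n_cells)],
)
# population B has 3x the pathway-input expression
cells.loc[sorted(input_genes), cells.columns[n_cells:]] *= 3.0
labels = {c: c.split("_")[0] for c in cells.columns}

pb, sample_groups = make_pseudobulk(cells, labels, chunk_size=50, seed=1)
print(f"pseudo-bulk: {pb.shape[1]} samples from {cells.shape[1]} cells "
      f"({pb.shape[1] // 2} per population)")

fc_maps = global_mean_fold_change(pb)
activity = activity_matrix([pathway], fc_maps)
print("\nlog2 branch activity (rows: pathway sinks, columns: pseudo-samples):")
print(activity.round(2).to_string())
print("\npopulation tB drives the pathway inputs 3x harder, so its")
print("pseudo-samples show positive log2 activity at reachable sinks.")
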