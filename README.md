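# psflow

Topology-aware pathway activity analysis: curate directed signaling-pathway
graphs (KGML import with automatic corrections, editing with a full audit
log, network-quality metrics) and quantify the activity of every pathway
*branch* by propagating gene fold changes from the pathway inputs
(ligand/receptor level) to its terminal sink nodes, with bootstrap
branch-level significance.

Intended for computational biologists who work with KEGG-style signaling
pathways and want branch-resolved activity — one score per terminal
outcome of a pathway, not one score per pathway — from bulk, two-group or
single-cell expression data.

## The model

Each pathway is a directed graph of nodes (genes, compounds, complexes)
joined by signed, weighted interactions. Given a positive linear fold
change FC_j per node, the node signal S_j is evaluated from the in-degree-0
input nodes toward the sinks:

    S_j = FC_j                                              input nodes
    S_j = FC_j * Σ_{i ∈ Inc(j)}  p_i · w_ij · S_i^{K_ij}    otherwise

    p_i = S_i / Σ_{k ∈ Inc(j)} S_k

where Inc(j) is the set of upstream (parent) nodes, w_ij > 0 the
interaction weight (default 1) and K_ij the impact: +1 for activation and
−1 for inhibition. **The inhibition sign enters as a reciprocal on the
parent signal** — an inhibitor whose own signal is S contributes 1/S —
which is the load-bearing interpretation behind the whole package: it is
the only reading under which K ∈ {+1, −1} is meaningful together with
strictly positive multiplicative signals, and it makes FC ≡ 1 an exact
fixed point (neutral data ⇒ neutral signals, inhibition included).

Cycles are never broken by deleting edges: strongly connected components
are condensed, evaluated in topological order, and iterated with
fixed-point sweeps (tolerance 1e-6, at most 100 sweeps); convergence is
reported per component.

Significance of a sink's signal is assessed by permutation: reshuffling
either the fold-change values among the pathway's own genes, or the
sample-group labels, re-propagating each time, and counting
`p = (1 + #{null at least as extreme}) / (n + 1)` on the log-signal scale
(default n = 2000 iterations), with Benjamini–Hochberg adjustment across
all sinks of a run.

## Worked example

`examples/propagate_toy.py` builds a five-node cascade — a ligand
activates a receptor, the receptor feeds both a kinase arm and an
inhibitory arm, and a transcription factor integrates the two — with the
ligand gene doubled (FC 2) and the inhibitor halved (FC 0.5):

```
node signals along the evaluation order:
  LIG  FC=2.00  S=2.0000
  REC  FC=1.20  S=2.4000
  INH  FC=0.50  S=1.2000
  KIN  FC=1.00  S=2.4000
  TF   FC=1.00  S=1.8778

sink label   signal  log2_signal
  TF    TF 1.877778     0.909026
```

The receptor multiplies the incoming ligand signal by its own fold change
(2 × 1.2 = 2.4). The transcription factor mixes its two parents by their
signal proportions (p_KIN = 2.4/3.6, p_INH = 1.2/3.6); the inhibitory arm
enters reciprocally, so S_TF = (2/3)·2.4 + (1/3)·(1/1.2) ≈ 1.878: the
branch outcome is net activated, log2 signal ≈ 0.91.

The other examples show KGML parsing with automatic topology corrections
(`kgml_curation.py`), branch-level bootstrap significance on simulated
two-group data with known ground truth (`bootstrap_significance.py`), and
single-cell pseudo-bulk pathway activity (`pseudobulk_activity.py`).

## Command line

Every capability is also reachable through the thin `psf` CLI:

```sh
psf parse --kgml hsa04390.xml --out hippo.json --report fixes.tsv
psf metrics --pathway hippo.json --out topo.tsv
psf run --pathway hippo.json --fc fold_changes.tsv --out results/
psf bootstrap --pathway hippo.json --fc fold_changes.tsv --mode gene \
    --n 2000 --seed 42 --out boot.tsv
psf pseudobulk --matrix cells.mtx --genes genes.tsv --cells barcodes.tsv \
    --labels tissues.tsv --chunk 50 --max-cells 5000 --seed 7 --out pb.tsv
psf simulate --nodes 30 --seed 1 --out toy/
```

Exit codes: 0 success, 1 usage error, 2 data error. All randomness flows
from `--seed`; identical inputs and seed give byte-identical outputs.

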