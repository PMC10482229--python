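# Methods

## Signal propagation

The core quantity is the node signal

    S_j = FC_j · Σ_{i ∈ Inc(j)} p_i · w_ij · S_i^{K_ij},
    p_i = S_i / Σ_{k ∈ Inc(j)} S_k,

with S_j = FC_j at in-degree-0 input nodes. FC_j is a strictly positive
linear fold change, w_ij > 0 an interaction weight (default 1, arbitrary
positive values supported), and K_ij ∈ {+1, −1} the interaction impact.
An inhibiting parent therefore contributes the *reciprocal* of its signal.
Consequences that the tests rely on:

* FC ≡ 1 is an exact fixed point on any graph, inhibition included
  (1^(−1) = 1), so neutral data produce neutral signals.
* On a pure activation chain with unit weights the signal at depth d is
  the product of the fold changes of nodes 1..d.
* The proportions p_i are computed from raw parent signals — not
  weight- or sign-adjusted — and sum to 1 at every non-input node.
* Signals stay strictly positive; they are clipped to [1e-300, 1e300] so
  that runaway amplification saturates instead of overflowing to inf/0.

If several parallel interactions join the same ordered node pair (e.g. an
activation and a phosphorylation), propagation uses the first one; the
pair contributes a single term to the sum.

**Cycles.** Feedback loops are handled by condensing the graph into
strongly connected components, sorting the condensation topologically
(ties broken by smallest member id; within-component order is
lexicographic, so evaluation is fully deterministic), and iterating each
nontrivial component with Gauss–Seidel-style sweeps from the initial state
S = FC until the largest relative change drops below `tol` (default 1e-6)
or `max_sweeps` (default 100) is reached. No edge is ever deleted to
break a loop. The recurrence is multiplicative, so loops whose gain
differs from 1 genuinely have no positive fixed point (a two-node
amplifying loop grows every sweep; a reciprocal two-node loop oscillates);
such components are reported as non-converged in the result's
`scc_diagnostics` rather than silenced. Loops *fed by external input*
typically do converge (e.g. X→A⇄B with neutral loop fold changes
converges to the hand-solvable fixed point S_A = S_B = S_X).

**Vectorization.** Internally every node signal is a numpy array; one
code path evaluates a single fold-change assignment, all bootstrap
iterations of a permutation test, or all pseudo-bulk samples of an
activity matrix in a single sweep over the graph. This is purely an
implementation detail — column k of a batch equals a scalar run on
assignment k to machine precision (tested).

## Fold-change inputs

Fold changes are consumed on the linear scale; log2 inputs must be
exponentiated (the CLI's `--log2-input` does this). Aggregation onto
nodes uses the **geometric mean**: multi-gene nodes take the geometric
mean of their mapped genes' FCs, complexes (group nodes) the geometric
mean over their members, recursively. Fold changes are multiplicative, so
the arithmetic mean would bias upward; the geometric mean also makes an
all-ones map yield fold change 1 everywhere. Genes without a measurement,
and compound/map/process nodes, default to the neutral FC 1 so they
transmit signal without distorting it. Both conventions are this
package's choice and are stated here because the aggregation rule is not
fixed by the model itself.

Two-group fold changes are `(mean_case + c) / (mean_control + c)` with
pseudocount c (default 1, guarding all-zero genes). The coding-isoform
adjustment multiplies each gene's expression by its total coding-isoform
fraction (fractions must sum to 1 per gene, tolerance 1e-6); genes absent
from the isoform table pass through unchanged with a warning.

## Bootstrap significance

Branch-level p-values are permutation p-values with the plus-one
correction, p = (1 + r)/(n + 1), never exactly zero and valid by
construction. "At least as extreme" is measured on the log-signal scale:
two-sided means |log S*| ≥ |log S_obs| (distance from the neutral signal 1
at least that of the observation); `greater`/`less` compare log S*
against log S_obs one-sidedly. A comparison tolerance of 1e-12 on the log
scale makes exactly reproduced observations (tied permutations) count as
hits regardless of floating-point summation order.

Two nulls:

* **gene shuffle** — the observed FC values are permuted among the
  pathway's own mapped genes; the value multiset is preserved exactly in
  every iteration. Requires ≥ 2 mapped genes.
* **label shuffle** — sample-group labels are permuted with group sizes
  preserved; fold changes are recomputed from the expression matrix each
  iteration. Requires ≥ 2 samples per group.

Default n = 2000 iterations. BH adjustment is applied across all sinks of
one invocation (all pathways of a run form one family), delegated to
statsmodels. All permutations derive from a single
`numpy.random.default_rng(seed)` PCG64 stream, so results are bit-for-bit
reproducible across platforms for a fixed seed.

An alternative extremity definition, `null_center="neutral"`, recenters
the null log signals at their own mean before comparing — useful when the
permutation distribution of a sink is itself displaced from log S = 0.
The default compares against the observed value directly.

## Pseudo-bulk aggregation

From each cell group, `min(max_cells_per_group, ⌊n/chunk⌋·chunk)` cells
are drawn uniformly without replacement (seeded), partitioned into
consecutive chunks of `chunk_size` (defaults: 5000 cells, chunks of 50 →
100 pseudo-samples per group) and summed gene-wise; leftover cells
(n mod chunk) are dropped. Fold changes are taken per pseudo-sample
against the global mean over all pseudo-samples, on linear sums, with
pseudocount 1 by default; with pseudocount 0 and positive rows the
per-gene mean of the FCs is exactly 1. Each pseudo-sample's map can be
propagated through a pathway collection, giving a branch × pseudo-sample
log2-activity matrix (clustering of that matrix is out of scope).

## KGML import and automatic corrections

The parser maps each KGML entry to one node (entry types gene, compound,
group, map; anything else becomes `process` with a warning; multi-gene
entries stay single nodes carrying the full gene-id list) and each
relation to one edge with the subtype recorded verbatim. The impact
convention is: {inhibition, repression, dissociation} → −1, everything
else (activation, expression, binding/association, phosphorylation,
compound, unknown, …) → +1; for multi-subtype relations a single negative
subtype makes the edge inhibiting. Only the two-valued impact is fixed by
the model; the sign assigned to non-canonical subtypes is this package's
documented convention. KGML reaction elements (metabolic maps) are out of
scope.

`autocorrect` performs three repairs, each marked
`provenance="auto_corrected"` and reported:

1. **Compound bridging** — a relation annotated with a mediating compound
   c gains explicit source→c and c→target edges (impact +1), so signal
   flows through the small molecule.
2. **Group resolution** — edges touching a member of a complex are
   mirrored onto the group node (iterated to a fixpoint, since nested
   complexes can make a mirrored edge itself mirrorable), and every group
   gains +1 `group-membership` edges to its members. Mirrored edges are
   reported as missing interactions, membership edges as group
   resolutions.
3. **Binding direction** — undirected binding/association relations are
   oriented from the endpoint nearer the pathway inputs. Depths come
   from a multi-source BFS over in-degree-0 nodes computed *without* the
   unresolved binding edges (their file direction is an artifact and must
   not influence the decision); ties orient from the lexicographically
   smaller id. Orienting marks the edge auto-corrected even when the
   file's direction happened to be right — that marking is what makes the
   whole procedure idempotent (a second run reports zero fixes).

Original edges are never deleted. Corrections whose referenced compound
entry is missing are skipped with a warning.

## Topology metrics

`topology_report` works on the directed graph with unweighted (edge-count)
distances. `shortest_path_pairs` is the number of ordered node pairs
(u, v), u ≠ v, joined by a finite directed path — the scalar that grows
as curation restores connectivity. Betweenness is raw (unnormalized)
directed betweenness. Closeness and eccentricity use outgoing distances;
nodes that reach nothing are excluded from those medians, avoiding
infinities. Medians use the midpoint convention (fractional values
possible). The diameter of a graph with no finite path between distinct
nodes is 0. All metrics agree exactly with a brute-force Floyd–Warshall +
path-counting oracle on graphs ≤ 12 nodes (tested on 500 random digraphs).

## Editing and provenance

Every mutating operation on a pathway appends exactly one entry to an
append-only curation log, with enough payload that replaying the log on
the original reproduces the edited pathway. Log "timestamps" are a
logical monotone counter, not wall time: the log is embedded in the
canonical pathway JSON, and identical edit sequences must serialize
identically (the CLI guarantees byte-identical re-runs). Node duplicates
are detected by (kind, sorted gene ids, sorted members) — labels are
ignored because display names vary while the underlying biology does not;
nodes carrying neither gene ids nor members are never reported. The JSON
schema carries an explicit version string and refuses documents from a
different major version.

## Synthetic data

The generators exist so every capability is testable without downloads,
and they define the package's validation conditions:

* **Pathways** — ranked-pair DAGs (each forward pair independently an
  edge, default probability 0.25; default 20 nodes), inhibition fraction
  0.15, optional back-edges for cycles, one gene per node by default,
  optionally a fraction of nodes converted to two-member complexes. Pure
  function of spec + seed.
* **Expression** — per-gene, per-sample values `exp(N(5, 0.5))` (natural-
  log scale): positive, right-skewed, realistic magnitude for normalized
  expression. Case samples multiply the genes of one randomly chosen
  input→sink branch by the effect size (default 4); default 20 samples
  per group. Ground truth (branch nodes/genes, affected vs null sinks) is
  returned for recovery scoring.
* **KGML fixtures** — pathways expressible in KGML (unit weights, subtype
  consistent with impact) serialize to KGML text that parses back
  structurally identical up to provenance.

What these simulations do *not* emulate: realistic KEGG topology (hub
degree distributions, pathway crosstalk), count noise and library-size
variation of real RNA-seq, correlated genes, or batch effects. Passing
calibration and power checks on them demonstrates the statistical
machinery is correct under its own assumptions, not performance on any
particular real dataset.

## Validation sizes and numerical choices

The acceptance script and test suite validate at these problem sizes,
chosen to make every check complete in seconds to a couple of minutes on
a single core while keeping the estimates sharp:

* propagation vs independent recursive evaluator: 500 random DAGs ≤ 15
  nodes, agreement to 1e-9 relative (measured: exact to machine
  precision);
* neutral identity: 200 random graphs including cycles;
* proportion conservation: tolerance 1e-12;
* bootstrap calibration: a 200-node null pathway, 500 replicate datasets
  × 2000 iterations; pooled type-I error at α = 0.05 asserted within
  [0.03, 0.07]; per-sink uniformity by Kolmogorov–Smirnov at family
  α = 0.01 with Bonferroni over the pathway's sinks (testing every sink
  at raw α = 0.01 would fail spuriously for a few dozen sinks);
* power: 100 replicates of a 30-node pathway, 4-fold branch effect, 20
  samples/group; branch sink recovered at q < 0.05 in ≥ 90% of
  replicates; null-sink type-I error asserted within [0.02, 0.09]
  (≈ 400–600 null trials, a ±3σ band around 0.05);
* parser round-trip and autocorrect idempotence: 100 generated fixtures;
  metrics oracle: 500 digraphs ≤ 12 nodes; pseudo-bulk: 5000 cells in
  chunks of 50 → exactly 100 pseudo-samples, conservation exact.

## Known limitations

* Cyclic propagation is defined operationally (fixed-point sweeps), and
  loops with multiplicative gain ≠ 1 do not converge; they are flagged,
  and their saturated signals should not be interpreted quantitatively.
* The binding-direction heuristic needs reachable inputs; in a component
  with no in-degree-0 node it falls back to the lexicographic rule.
* `shortest_path_pairs` summarizes connectivity as a pair count; it is
  not comparable across pathways of very different size without
  normalization.
* Gene-shuffle permutes within the pathway's own gene set, so a pathway
  whose genes share one FC value cannot reach significance by
  construction (p = 1), which is the intended degenerate behavior.
* Differential-expression modeling (dispersion estimation, normalization
  of raw counts), isoform quantification and coding-potential prediction
  are upstream of this package: it consumes their outputs.
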