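# Methods

## Model

`bipnull` analyzes binary bipartite incidence matrices **A** (rows: plant
nodes; columns: fungal nodes; `a_ij ∈ {0,1}`). The null model is the
bipartite binary configuration model (BiCM): the canonical
maximum-entropy ensemble over `n_rows × n_cols` binary matrices whose
expected degree sequence equals the observed one. Entropy maximization
under per-node degree constraints gives an entrywise-independent
Bernoulli distribution with

    p_ij = x_i y_j / (1 + x_i y_j),

one positive multiplier per node (`theta_i = −log x_i` on the exponential
scale). The multipliers that solve the expected-degree equations

    Σ_j p_ij = k_i  (every row)      Σ_i p_ij = d_j  (every column)

also maximize the Bernoulli log-likelihood of **A**, so the fitted `p` is
a maximum-likelihood estimate. The constraint is *soft*: individual
ensemble draws have fluctuating degrees; only the ensemble average
reproduces the observed sequence. This is deliberate — observed degrees
in molecular association data carry sampling noise, and a null model that
freezes them exactly (hard-constraint rewiring) conditions on that noise.

### Solver

* **Degree-class reduction.** Nodes with equal degree provably share a
  multiplier, so the system is solved with one unknown per distinct row
  degree and per distinct column degree. At the largest realistic scale
  (hundreds × hundreds) this makes the fit effectively instant.
* **Forced-structure peeling.** A row whose degree equals the number of
  (remaining) columns can only satisfy its constraint with `p = 1` across
  them, which no finite multiplier represents. Such rows/columns are
  peeled iteratively before solving: their probabilities are fixed at 1,
  the opposite layer's remaining degrees are decremented, and nodes whose
  remaining degree hits 0 are fixed at `p = 0` symmetrically. Multipliers
  of peeled nodes are flagged at the limits (`inf` / `0`). If peeling
  consumes the whole matrix the fit is exact and flagged *degenerate*:
  the ensemble contains a single matrix. Perfectly nested (Ferrers)
  matrices always end up here — they are the unique realizations of their
  degree sequences — so a fully nested matrix can never deviate from its
  own null (z = 0 by the zero-variance convention).
* **Iteration.** The interior system is solved by the fixed-point map
  `x_i ← k_i / Σ_j y_j/(1 + x_i y_j)` alternating layers, initialized at
  `x_i = k_i/√E`. If the residual stalls (progress < 1e-13 over a
  50-iteration window) the solver falls back to a Levenberg–Marquardt
  least-squares refinement in log-parameter space. Convergence is
  declared at a maximum absolute degree residual of 1e-8 (degrees are
  O(1)–O(10²) integers, so an absolute tolerance is interpretable);
  failure raises an error carrying the residual trace.
* **Sampling.** Null matrix `s` is drawn entrywise Bernoulli(`p_ij`) from
  an RNG substream derived from `(seed, s)`, so ensembles are
  reproducible and prefix-stable (the first k of n samples do not depend
  on n).

## Metrics

**NODF** (0–100). For every unordered pair of rows with strictly
different fills, the pair contributes `100 · overlap / smaller fill`
(overlap counted in the lower-fill row); equal fills or a zero lower fill
contribute 0. Same for column pairs; NODF is the mean over all row and
column pairs. The paired term depends only on fills and overlaps, so no
matrix sorting is needed. The implementation is vectorized
(`A Aᵀ` overlap matrices) and is tested for exact agreement with a
literal pairwise-loop oracle.

**Barber modularity** `Q = (1/E) Σ (a_ij − k_i d_j/E)` over same-module
plant–fungus pairs, computed by exact integer accumulation divided once
by `E²` (the stored Q is reproducible to 1e-12 from the labels). The
optimizer alternates best-label sweeps — every row node adopts the module
with the largest Q gain given the column labels, then vice versa; within
a layer moves do not interact, so a synchronous sweep equals a sequence
of single-node moves and never decreases Q — until a fixed point, then
greedily merges module pairs while Q increases, and repeats. The search
runs `n_restarts` times (restart 0: one module per plant node; later
restarts: random assignments from a `(seed, restart)` stream) and keeps
the best partition, never below the single-module baseline Q = 0.
Argmax tie-breaks take the lowest module id and the sweep order is fixed,
so results are deterministic for a given seed. Zero-degree nodes carry no
Q weight and are assigned singleton modules. This is a local-search
heuristic in the label-propagation family: it is exact on the
block-structured instances used for validation (verified against
exhaustive partition enumeration on ≤ 10-node instances, and against the
closed form `Q = 1 − 1/k` for k equal disjoint complete blocks), but like
all modularity maximizers it guarantees only local optimality in general.

## Inference

For each metric the pipeline reports the observed value, the null
distribution over `n_null` ensemble draws (default 999), the z-score
`(observed − null mean)/null SD` (sample SD, denominator n−1), and
add-one empirical tail probabilities `(count + 1)/(n_null + 1)` with ties
counted as extreme — never zero, standard for Monte-Carlo tests. Both
tails are always reported. Verdicts at significance α (default 0.05)
follow the sign convention: nested iff `z(NODF) > 0` and `p_upper ≤ α`,
anti-nested iff `z(NODF) < 0` and `p_lower ≤ α`; modular/non-modular
analogously for Q. If every null value is identical the ensemble is
flagged degenerate, z is 0 (or a signed-infinity sentinel when the
observed value differs), and the verdict is "indistinguishable".

Null matrices are scored exactly as drawn: empty rows/columns arising in
a sample are not pruned (their NODF pairs contribute 0; isolates get
singleton modules), so observed and null metrics always refer to the same
layer sizes. Modularity on null matrices uses fewer restarts (default 5)
than on the observed matrix (default 20); both are parameters.

## Synthetic data

The generators stand in for published plant–AMF association tables
(roughly 1–245 plant nodes × 8–277 fungal nodes, heterogeneous degrees,
variable connectance):

* `gen_random(n_rows, n_cols, connectance, seed)` — i.i.d. Bernoulli fill.
* `gen_perfectly_nested(n_rows, n_cols, fill_profile)` — left-packed
  Ferrers matrix from a strictly decreasing fill profile (fills ≥ 1).
  NODF is 100 when both layers' fills are strictly decreasing, e.g. the
  square staircase profile `(n, n−1, …, 1)`.
* `gen_modular(module_sizes, p_in, p_out, seed)` — planted partition;
  each module needs at least one row and one column; the planted
  partition is returned for recovery tests. Defaults used throughout the
  validation suite: 4 modules of 10 × 15, `p_in = 0.6`, `p_out = 0.05` —
  a contrast strong enough to be unambiguous yet far from block-diagonal.
* `gen_heterogeneous(row_weights, col_weights, target_links, seed)` —
  Chung-Lu-style edge probabilities
  `min(1, w_i v_j T/(Σw Σv))`; expected links equal `target_links` when
  nothing clips.

One master seed; each generator uses a private stream keyed by a
generator tag, and entries are drawn row-major, so fixtures are
bit-reproducible. The generators emulate degree heterogeneity and planted
mesoscale structure; they do not emulate read-depth noise, spatial
autocorrelation, or phylogenetic signal, so passing tests demonstrate
correctness of the machinery, not ecological realism of any particular
dataset.

## Validation design and problem sizes

The automated checks run at sizes chosen to finish in minutes on one
core while still covering the realistic range: 100 BiCM fits on random
matrices from 5×8 to 120×250 (connectance 0.05–0.6); ensemble consistency
with 999 samples of a 20×30 fit (≥ 99 % of nodes within 4 CLT standard
errors); NODF against the pairwise oracle on 200 matrices up to 12×12;
modularity optima against exhaustive partition search on 8-node
instances; type-I calibration with 200 replicates of a 20×40 null
(n_null = 199); planted-structure recovery over 20 seeds (n_null = 199).

**Type-I error calibration** draws matrices from a fitted BiCM and scores
each against *that same model* — the null hypothesis that generated them —
so observed and null metric values are exchangeable and the lower-tail
NODF rejection rate at α = 0.05 is nominal (measured ≈ 0.04–0.08 across
master seeds). A related but different procedure — refitting the BiCM to
each analyzed matrix, which is what the pipeline necessarily does on real
data whose generating model is unknown — is *not* exactly calibrated for
NODF: the refitted canonical ensemble carries extra degree fluctuation
relative to the single conditioned realization, which systematically
raises null NODF (degree ties break more often under fluctuation) and
biases z(NODF) negative (roughly −1.5 on 20×40 matrices at connectance
0.3). Users comparing small matrices near the band |z| ≲ 2 should keep
this conservative-against-nestedness bias in mind; strongly significant
deviations (the planted-structure recovery shows median z(Q) ≈ +26 and
z(NODF) ≈ −3.5 under truth) are far outside its reach.

## Data handling defaults

* CSV dialect: UTF-8, comma-separated; first column = plant labels,
  header row = fungal labels.
* Binarization: any strictly positive count → 1; no abundance threshold.
* Dataset filter: at least 5 fungal nodes and at least 1 plant node
  (single-plant matrices are legitimate — their rows may be populations,
  treatments or time points).
* Empty rows/columns are removed (and reported) before fitting: a
  zero-degree node forces `p = 0` identically and contributes nothing to
  either metric, but would inflate pair counts.
* Plant-layer aggregation (sample → population → species → meta-network)
  merges rows by Boolean OR: the aggregated node carries the union of its
  members' associations.

## Known limitations

* Binary matrices only; no weighted (strength-sequence) configuration
  model, no degree-corrected block models.
* The modularity search is heuristic; on large weakly modular matrices
  the returned Q is a lower bound on the optimum. Restart counts are the
  main lever.
* The refit-bias described above means z(NODF) values of small magnitude
  are conservative evidence for anti-nestedness on real data.
* p-values are Monte-Carlo estimates with resolution `1/(n_null + 1)`.
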