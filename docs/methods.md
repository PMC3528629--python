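# Methods

## Problem and model

`simfuse` addresses similarity fusion for a compound set described by
L ≥ 2 independent views.  View l contributes a symmetric similarity
matrix `S_l ∈ [0,1]^{n×n}` with unit diagonal; the goal is a single
fused matrix `S = Σ_l α_l S_l` with learned convex weights α.  The
premise connecting this to pharmacology is that compounds similar in
either chemical structure or bioactivity tend to share protein
targets, so a similarity that integrates both should group
co-targeting compounds better than either view alone.

### Per-view similarities

* **Bioactivity**: the sample Pearson correlation of two activity
  profiles, clipped at zero.  Weak negative correlations between
  activity profiles are noise for the purpose of molecular similarity,
  and clipping keeps the matrix in [0,1].  Correlation is computed on
  pairwise-complete features; a pair sharing fewer than 3 complete
  features, or with a constant profile on the shared subset, gets
  similarity 0 with a warning.  A compound whose whole observed profile
  is constant is rejected (its correlation is undefined everywhere).
* **Structure**: the Tanimoto index `|A∩B| / |A∪B|` over set bits of
  binary fingerprints.  All-zero fingerprints are rejected (undefined
  self-similarity).
* **Distance-based profile similarity** `1/(1+d_euclidean)` is provided
  only to reproduce side-by-side validity-curve comparisons against a
  distance-based clustering; the mapping of a distance into [0,1] is
  this package's own convention and that curve is illustrative.

### Normalization

The fusion objective treats each view as a probability distribution
over compound pairs.  `standardize_normalize` z-scores S over all n²
entries (diagonal included — the transform is defined on the whole
matrix), shifts by the global minimum so entries are nonnegative, and
divides by the total.  The shift, rather than clipping, preserves the
ordering and relative spacing of similarities; the result is invariant
to any positive affine rescaling of S.  The diagonal is retained: the
shift rule keeps each row's self-entry maximal, which the low-rank
factorization tolerates, and removing it has no textual basis in the
transform.  A constant matrix has no z-form and is an error; the
stochastic form is computed lazily so that a degenerate S (e.g. two
identical compounds, all entries 1) only fails if fusion actually
needs it.

### Objective and algorithm

```
min_{α,V,H}  Σ_l α_l C(P_l ‖ V Hᵗ) − η H(α),   Σα = 1, α ≥ 0, V,H ≥ 0
```

with `C(P‖Q) = −Σ p log q` (natural log, q floored at 1e−12) and
`H(α)` the Shannon entropy of the weights.  Starting from uniform α,
two steps alternate:

1. **Factorization.**  Cross-entropy is linear in its first argument,
   so `Σ_l α_l C(P_l‖Q) = C(P̄‖Q)` with `P̄ = Σ_l α_l P_l`; the inner
   problem is a single rank-k nonnegative factorization of P̄.  It is
   solved by the standard multiplicative updates for the KL/divergence
   objective (the EM algorithm for this model), followed by rescaling
   `V·Hᵗ` onto the probability simplex — the exact minimizer along the
   scaling direction, under which minimizing generalized KL coincides
   with minimizing cross-entropy.  Each sweep is monotone, so the
   recorded cross-entropy trace never increases (slack 1e−9 for
   floating point).
2. **Weight update.**  With `ce_l = C(P_l‖Q)` fixed, minimizing
   `α·ce − ηH(α)` on the simplex is solved in closed form by
   `α_l ∝ exp(−ce_l/η)` (the stationarity condition of the Lagrangian;
   a numerically shifted softmax).  This replaces a general NLP solver;
   a brute-force simplex grid search is kept in the test suite as the
   independent oracle.

Both steps are exact or monotone partial minimizations, and the
factorization warm-starts across outer iterations, so the outer
objective trace is non-increasing.  Convergence is declared when
`max|Δα| < tol_alpha` (default 1e−6) or the relative objective change
drops below `tol_objective` (default 1e−8); caps default to 100 outer
and 1000 inner iterations.  Because the factorization is non-convex,
`fuse` runs `n_restarts` (default 5) independent seeded initializations
(V, H ~ Uniform(0.1, 1), scaled onto the simplex) and keeps the best
final objective.  Restart r of a run with seed s draws from
`SeedSequence([s, r])`, so results are bit-reproducible and restarts
are decorrelated.

The fused matrix returned is the convex combination of the *original*
S matrices (the normalized P̄ is also exposed for sensitivity checks);
downstream clustering operates on fused S.

### Choosing η

η is tuned by leave-one-out stability.  For each η on a grid (default
0.001–1000, 25 points), each of the n leave-one-out subsets is fused
(subset r with seed `base + r`) and clustered on `d = 1 − fused_S`.
Stability and quality are summarized by:

* **AMD** — for each class count k in `k_range` (default [2, 15]) every
  subset tree is cut into k classes; each unordered pair of subset
  clusterings is compared on the compounds both contain, after
  restricting to that intersection, by the minimum over label
  relabelings of the number of disagreeing compounds (solved as an
  assignment problem on the k×k agreement matrix — raw label
  comparison would measure label-encoding noise, not instability).
  AMD is the mean over pairs, then the unweighted mean over k.
* **ADI** — Dunn's index (minimum between-cluster distance over
  maximum cluster diameter) of each subset partition, averaged over
  subsets per k; the mean and the variance over k are reported.
  Singleton clusters have diameter 0; an all-singleton partition makes
  the index unbounded and is excluded from the averages with a warning.

The recommendation is the AMD-minimizing η, tie-broken by the larger
ADI mean; the full per-η table is returned so a user can apply their
own judgment, which matters in practice because the AMD curve can be
flat or favor degenerate extremes on easy data.

### Clustering, validation, screening

Clustering is agglomerative on `d = 1 − s` (SciPy's implementation;
average linkage by default, complete/single exposed — the field's
common default for similarity-derived distances, with monotone merge
heights).  Tie handling follows SciPy's deterministic
nearest-neighbor-chain order.  Trees are cut into exactly k classes
with labels canonicalized by first leaf appearance, and exported as
Newick with branch lengths equal to merge-height differences.

The compound–target bipartite graph is projected onto compounds
(edge iff ≥1 shared target, shared-target count stored as edge
metadata but unused by the statistic).  A cluster is scored by the
mean *induced-subgraph* degree of its members — edges leaving the
cluster do not count, since the statistic measures target sharing
within a class — and a clustering by the unweighted mean over classes.
Over the full compound set the statistic reduces to `2|E|/|V|`.

Screening ranks all non-query compounds by descending fused
similarity, ties broken lexicographically by id, 1-based ranks.  The
fused score uses weights learned once on the full compound set, so
α = (1, 0) reproduces view 1's ranking exactly.  The comparison table
flags (not filters) hits with fused similarity above 0.5 and, given an
edge list, marks hits sharing a target with the query.

## Synthetic benchmark

The generator plants `k_true` clusters in all three inputs at once:

* profiles: cluster centers ~ N(0, 1) per feature; compound = center +
  N(0, noise²) per feature, optionally plus a per-compound scalar
  offset (emulating a dose-scale shift that inflates Euclidean
  distance while leaving the correlation at 1);
* fingerprints: cluster templates ~ Bernoulli(0.3) per bit; each bit
  flipped with probability noise/2, so noise 1 gives uniform bits and
  exactly zero signal; at least one set bit is enforced per compound;
* targets: `targets_per_cluster` dedicated targets hit by every
  member, plus one foreign target per compound with probability
  `annotation_noise`, so at zero noise the projection is a disjoint
  union of cluster cliques with within-cluster degree (size − 1).

Defaults (n = 37, k = 6, 60 features, 1024 bits, noise 0.2 per view,
3 targets per cluster, annotation noise 0.05) mirror the scale of a
curated growth-inhibition panel study.  What the benchmark does *not*
emulate: correlated features (real cell-line panels are strongly
correlated), chemical-series structure in fingerprints, hub targets,
or class imbalance.  Passing tests therefore demonstrate correctness
of the machinery and the qualitative behavior of the method (weight
concentration, stability, validity dominance), not performance on real
pharmacological data.

## Numerical choices and limitations

* log floor 1e−12 inside cross-entropy; EM denominators floored the
  same way; NaN in the objective raises with the iteration index.
* Simulation and test problem sizes (e.g. the 20-seed recovery sweep
  at n = 37, the 3-point η grid in the pipeline determinism check) are
  chosen to exercise the full pipeline at the default benchmark scale
  while keeping a complete run cheap on a single CPU.
* At small η the objective is nearly winner-take-all and the learned α
  can saturate exactly to (1, 0) in double precision; this is the
  intended limit, not an error state.
* AMD's averaging order (pairs, then k) and ADI's variance-over-k are
  this package's documented readings of conventions that admit
  alternatives (variance over subsets is easily recovered from the
  per-subset Dunn values if needed).
* The η recommendation on easy synthetic data is often the smallest
  grid value (perfectly separable structure is stable under any
  weighting); on real, noisier data AMD/ADI trade off non-trivially
  and intermediate η values win.
* More than two views are supported throughout the fusion core; the
  two-view case is simply the default wiring of the CLI.
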