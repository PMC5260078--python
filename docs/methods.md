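# Methods

## Model and assumptions

The regressor assumes chronological age is, after preprocessing, an
approximately linear function of a sparse set of methylation probes plus a
low-dimensional expression signal that is *complementary* to methylation:
the expression stage is fit to the methylation-stage residuals, never to age
directly.  This ordering encodes the empirical prior that methylation
carries the stronger age signal and expression refines it.  Ages are used in
raw years; both modalities are assumed standardized per feature within each
tissue before fitting, and training/test ages are centred at the *training*
mean only (the mean is stored in the model and re-added at prediction time).

### Stage 1 — Lasso on methylation

Objective `(1/2n)‖y − X_m β‖² + λ‖β‖₁` (scikit-learn's `Lasso`
parameterization).  λ is selected by minimum pooled cross-validated squared
error over a log-spaced grid (default 25 points, 1e-3…10); no 1-SE rule.
Residuals carried to stage 2 are in-sample by default; a `cv_residuals`
flag switches to CV residuals.  The intercept is fitted for numerical
hygiene but is ≈ 0 because ages are pre-centred.

### Stage 2 — correlation-ranked forward stepwise with PLS compression

Candidate gene sets are prefixes of the |Pearson r|-vs-residual ranking.
Each candidate count g is scored by CV squared error of a PLS1 fit (NIPALS,
`scale=False`; components capped at `min(max_pls_components, g, n_train−1)`).
**The ranking is recomputed inside every training fold.**  Ranking once on
the full data leaks the held-out samples into the selection: measured on
pure-noise residuals, full-data ranking made the stepwise stage "beat" the
intercept in 10/10 replicates, while fold-internal ranking correctly fell
back to the intercept in 8/10.  The final selection applied to all training
data still uses the full-data ranking, which is the deployed selector.
Gene count g* is chosen first (at maximal admissible components), then the
component count c* at fixed g*; ties prefer the smaller value.  An
intercept-only baseline (g = 0) competes, so the stage can return an empty
selection and the model degrades gracefully to methylation-only.

Flattening the PLS composition (`x_rotations_` × component coefficients)
yields one linear weight per selected gene; staged and flattened predictions
agree to 1e-8 by test.  Markers = nonzero Lasso probes + selected genes,
ranked by |weight|.

### Cross-validation schemes

Multi-tissue models use leave-one-tissue-out folds (one fold per training
tissue — "6-fold" when six tissues train); tissue-specific models use a
seeded 5-fold partition with fold sizes differing by ≤ 1.

## Preprocessing

Per tissue and per modality: columns are centred, the projection onto the
top 3 left singular vectors is removed (rank-3 confounder regression), and
features are scaled to unit sample sd (ddof = 1).  Test tissues are
processed on their own samples; a frozen-from-training mode is not the
default because tissue blocks are assumed to carry tissue-specific batch
structure.  Removing k PCs twice equals removing 2k at once — the operation
is *not* idempotent for full-rank data, and the test suite asserts the
sequential-equals-one-shot identity instead.  Constant features are dropped
with a logged warning rather than raising; features dropped in any tissue
block are dropped globally to keep matrices aligned.

## Enrichment

Upper-tail hypergeometric p via `scipy.stats.hypergeom.sf` (log-gamma
internally); exact-rational enumeration agrees to < 1e-12 for all N ≤ 20.
The universe N defaults to all genes in the profiled expression matrix
(configurable).  FDR control is Benjamini–Hochberg step-up; the default
significance call is q < 0.25, the rigorous pathway mode uses q < 0.1.
Methylation probes are mapped to gene symbols through a user-supplied
two-column table; unmapped probes are dropped with a logged count.

## PPI shortest-path subnetwork

Edges with STRING-style combined score strictly above 700 are kept
(duplicates collapse to the maximum score; self-loops dropped).  Path length
is unweighted hop count by default — the score cutoff already enforces
confidence, and the hop metric lets BFS serve as the engine with
Floyd–Warshall as an independent oracle.  When several shortest paths tie,
the default keeps exactly one per marker pair: the lexicographically
smallest node sequence, reconstructed greedily from per-marker BFS distance
maps.  This makes counts deterministic but *label-dependent*; the
`tie_mode="all"` option counts every tied path and is the mode under which
betweenness is invariant to node relabeling.  Betweenness is the count of
marker-pair paths with the node strictly interior (endpoints excluded).

The permutation test redraws uniform node sets of the marker count and
recomputes the whole construction.  The reported p is the plain proportion
`#(perm ≥ obs)/n_perm` (weak inequality — the conservative reading), with
p = 0 reported as "< 1/n_perm" and significance called at p < 0.05.  This
estimator is discrete and conservative under ties (observed betweenness 0
forces p = 1), so its null distribution is *not* uniform; the
`tie_break="randomized"` mode returns the exchangeable randomized-rank
p-value, exactly U(0,1) under the null, and is what the calibration tests
exercise.  The default estimator remains the reported one.

## Cross-tissue co-profiling network

Strata: young = age ≤ 50, old = age ≥ 60, 50–60 excluded.  Tissues qualify
with **more than** `min_per_group` (default 3, i.e. ≥ 4) samples in both
strata; a flag relaxes to ≥.  Discretization thresholds mean ± sd are
computed per (tissue, marker) over *all* of that tissue's samples, so the
thresholds are stratum-independent and K-S differences reflect
distributional change, not threshold change; boundary values fall in the
middle band.  The K-S statistic is the sup over the joint support of the
absolute ECDF difference, computed on the discretized values by default
(`discretized=False` gives a raw-value debugging mode).  All marker × marker
pairs across a tissue pair are scored — cross-gene pairs are the interesting
case.  Edges keep `|K-S_old − K-S_young| > 0.95` (strict).

## Pathway interaction networks

Inputs are the **unthresholded** cross-tissue deltas (feeding the
0.95-filtered edges would make the type-1 cut of 0.6 vacuous).  A marker
pair contributes to every pathway pair whose memberships it satisfies
(inclusive counting — the only order-independent choice given overlapping
pathways); same-pathway cross-tissue edges are allowed.  Type 1 sums deltas
above 0.6 (edges with zero qualifying deltas are absent); type 2 sums all
deltas and flags `display` when the sum exceeds 3, retaining every edge in
the output (the > 3 cut is treated as a rendering convention, not part of
the method); type 3 sums all deltas over pathways at q < 0.1.

## Synthetic cohorts

The generator emulates a multi-tissue paired cohort: a latent uniform age
(default 30–85 y, midpoint = the mean-age constant), standard-Gaussian
feature background, causal features loaded with an age-proportional
component, and the realized age *re-derived* as
`age = mean + Σ β_f x_f + N(0, noise_sd)`.  This guarantees the linear model
family is exactly well-specified (a recoverable truth for the recovery
tests) at the cost of ages being only approximately uniform.  Defaults —
6 tissues × 50 samples, 200 + 200 features, 5 methylation-causal at
2.0 years/unit, 3 expression-causal at 1.0 years/unit, noise 1.0 y — define
the reference condition used by the recovery and ordering experiments.  The
rank-3 confounder (shared sample scores, modality-specific loadings,
`batch_strength` default 1.0) is added *after* the age is derived, so it
genuinely confounds and is matched in rank by the 3-PC preprocessing; 1.0
puts its per-feature variance on the scale of the background noise, a
moderate batch effect.

`old_shift_pairs` plant cross-tissue co-profiling signal: feature_a gains
+magnitude in tissue_a's old samples, feature_b gains −magnitude in
tissue_b's old samples (anti-correlated old-age change).  Geometry of the
planted edge: with a large magnitude and an old fraction p < ~0.46, the
tissue-wide mean ± sd band contains the entire unshifted young stratum
(K-S_young = 0) while both old strata land in opposite extreme bands
(K-S_old = 1), giving delta = 1.  The planted-edge experiment therefore uses
ages 20–80 (old fraction ≈ 1/3) with 100 samples/tissue and magnitude 200;
above p ≈ 1/2 the shifted stratum dominates the tissue mean and the band
flips onto the young samples, which is why the fraction must stay bounded
away from one half.  Background gene sets in that experiment exclude the
planted marker genes so a random set cannot coincide with the planted
pathway construct.

What the generator does **not** emulate: beta-value distributions bounded in
[0,1], probe-level array structure, count-based RNA-seq noise, non-linear
age trends, or realistic correlation between tissues.  Passing tests
therefore demonstrate correctness of the machinery and recoverability of a
well-specified signal — not performance on real cohorts.

## Problem sizes and numerical choices

Experiments run at: recovery — 5 cohorts of 300 samples; ordering — 10
cohorts, 4 training / 2 held-out tissues; permutation calibration — 200
replicates at 100 permutations on a 40-node graph; FDR null — 1000
replicates over 20 sets; oracle sweeps — all hypergeometric configurations
to N = 20, 1000 K-S pairs, 50 random 20-node graphs.  Each suite finishes
in seconds to about a minute on one CPU.  Ties in λ, gene count and
component selection prefer the smaller value; correlation ties keep input
column order; all randomness flows from explicitly passed seeds, and
reruns are bit-identical.

## Known limitations

- The single-path betweenness depends on the documented lexicographic tie
  policy; use `tie_mode="all"` for label-free counts.
- The reported permutation p is conservative under ties by construction.
- In-sample stage-1 residuals slightly favour genes correlated with
  methylation-overfit noise; the `cv_residuals` flag trades this for noisier
  residuals.
- The confidence-weighted path mode (length = 1000 − score) uses Dijkstra
  without a lexicographic tie guarantee.
- Residual error is reported as a sum of squared errors in years² and
  labelled as such; comparisons across groups of different size should use
  the per-sample mean.
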