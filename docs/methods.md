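# Methods

This note records the model assumptions, the defaults and why they were
chosen, the numerical decisions, and what the synthetic benchmark does
and does not demonstrate.

## Data model and preprocessing

A dataset is a features × samples abundance matrix; missing entries are
allowed on input.  Cleaning runs in a fixed order:

1. **Missingness filter** — a feature is dropped when missing in strictly
   more than `max_missing_frac` of samples (default 0.10; a feature at
   exactly 10% is kept).
2. **Variance filter** — per-feature sample SD (ddof = 1) is computed on
   observed values; features strictly below the `sd_percentile`-th
   percentile of those SDs are dropped (default 25, linear-interpolation
   percentile, so ties at the threshold survive).  Both filters act on
   features regardless of the orientation the file was read in; filtering
   samples by SD would not be meaningful for abundance data.
3. **Optional feature cap** — when `max_features` is set, only the
   top-SD features are kept.  The library default is `None`; the CLI
   enables 5000, a practical ceiling for the dense matrix algebra
   downstream.
4. **kNN imputation** — a missing cell (f, s) is replaced by the mean of
   the `knn_k` (default 10) nearest features' values at sample s, with
   nearness the Euclidean distance over samples observed in both
   features; a cell with no eligible neighbour falls back to the feature
   mean.  Feature-space kNN (impute a feature from similar features) is
   the convention of the classical expression-matrix imputers.  SDs for
   the variance filter are computed *before* imputation so imputed values
   cannot rescue a low-variance feature.
5. **Standardization** — each feature to mean 0 / sample SD 1.

The order matters and is observable through the `PreprocessReport`
counts, which satisfy the conservation identity
`in − missing − low_sd − cap = out`.

## Graphical lasso

The precision matrix solves
max log det Θ − tr(SΘ) − λ‖Θ‖₁,off with the diagonal unpenalized and
S the empirical correlation of the standardized data (standardization
makes covariance and correlation coincide, removing an ambiguity).
λ defaults to 0.25.  Estimation delegates to scikit-learn's
coordinate-descent solver; convergence is then *certified* in-house by a
duality gap: Θ⁻¹ is projected onto the dual-feasible box
{|W_ij − S_ij| ≤ λ off-diagonal, W_ii = S_ii} and the gap
f(Θ) − log det Ŵ − p bounds the suboptimality.  `tol` is a per-entry gap
tolerance (total gap ≤ tol·p², default 1e-4): the gap grows with the
number of features, so an absolute tolerance would be unreachably strict
for wide matrices (p ≫ n leaves long flat valleys where coordinate
descent plateaus) and needlessly loose for small ones.  When coordinate
descent stalls short of the certified threshold, proximal-gradient
polishing steps on the primal finish the job; if even that fails the
estimator raises rather than returning a silently unconverged fit.

Partial correlations are ρ_ij = −θ_ij/√(θ_ii θ_jj) with the diagonal
stored as 0, because the matrix feeds an adjacency whose self-edges must
vanish.  Users may supply precomputed partial correlations and skip
estimation entirely.

## Topological overlap and module detection

The adjacency is the *unsigned* partial correlation a_ij = |ρ_ij|: sign
information is deliberately discarded so that strongly negatively
coupled features cluster together, and the whole chain becomes invariant
to per-feature sign flips.  No soft-thresholding power is applied to the
partial correlations — sparsity is already enforced by λ.

TOM is computed exactly (matrix products internally; the test suite pins
it to a triple-loop oracle at 1e-12).  1 − TOM is clustered with average
linkage (scipy); ties are resolved by scipy's deterministic merge order.

The dynamic hybrid cut takes candidate branches from a static cut at
`cut_height` (default 0.99) and keeps a branch when

* it has at least `min_module_size` members (default 10 — partial
  correlation networks produce smaller, more uniform modules than
  marginal-correlation networks, so the classical floor of 30 would be
  too coarse),
* its **core scatter** (mean pairwise dissimilarity among the
  `min_module_size` most-connected members) is below a ceiling, and
* its **gap** (attachment height minus core scatter) is above a floor.

Ceiling and floor derive from `deep_split` ∈ 0..4 via maxCoreScatter ∈
{0.64, 0.73, 0.82, 0.91, 0.95} and minGap = (1 − maxCoreScatter)·3/4,
mapped onto the height interval [h_base, cut_height].  **h_base is the
median merge height below the cut**, not a low quantile: glasso-sparse
networks place most merge heights just under the cut height, and a
single unusually tight branch would otherwise drag a minimum- or
5%-quantile anchor so low that every genuine module fails the scatter
ceiling.  The median anchors the criteria to the typical merge scale and
is insensitive to such outliers.  Where these internal constants differ
from other implementations of the hybrid cut, planted-structure recovery
(ARI), not bit-compatibility, is the correctness standard.

With `pam_stage` (default on), each unassigned feature joins the module
with the smallest average dissimilarity, provided that module is the
unique nearest one and no farther than the cut height.  Modules are
relabelled 1..M by decreasing size; 0 marks unassigned features.

## Eigenfeatures

The module summary is the first right-singular vector of the module's
standardized submatrix, rescaled to mean 0 / SD 1 so cross-dataset
correlations are scale-free.  PC sign is arbitrary, so it is fixed by
requiring non-negative correlation with the module's mean sample profile
(first-loading sign breaks exact ties); without the convention,
downstream Spearman signs would be run-dependent.  `var_explained` is
σ₁²/Σσ_k².  Both raw loadings and kME (feature ↔ eigenfeature Pearson
correlation) are exported, since either may be wanted as a "loading".

## Integration and phenotype tests

All cross-dataset eigenfeature pairs get a Spearman rho (average ranks
on ties, two-sided t-approximation p) and Benjamini–Hochberg q-values
computed over the complete pair list — an all-pairs scan inflates false
positives, so an explicit multiplicity correction is reported even
though ranking by |rho| is the primary interface.  Edge ranking breaks
|rho| ties lexicographically for determinism.  Both a top-K and a max-q
filter are exposed; neither is applied by default in the library.

Phenotype association uses Welch's t (two groups; no equal-variance
assumption) or Kruskal–Wallis (more groups; no normality assumption on
eigenfeature scores), with BH across modules within one grouping — each
grouping is its own hypothesis family.  Significance is flagged on q by
default with a raw-p escape hatch.  Degenerate zero-variance inputs
report p = 1 with a flag rather than NaN.

## Synthetic benchmark

The generator draws, per module m, a latent factor z_m ~ N(0,1) over
samples and members x_f = √w·z_m + √(1−w)·σ·ε, so with σ = 1 the
expected within-module correlation is exactly w and the module has a
well-defined first PC — the rank-1 block model simultaneously exercises
module recovery and eigenfeature recovery.  Cross-layer couplings
correlate two modules' latents at a chosen strength; background features
are independent noise; missingness is completely at random.  The
standard benchmark configuration is 2 layers × (6 modules of 30 features
+ 40 background features), w = 0.6, two couplings at 0.9, 100 samples —
sizes a desktop run completes in seconds while keeping p > n, the regime
the sparse estimator exists for.

What passing these benchmarks does **not** show: real abundance data
have heavy-tailed intensity distributions, batch effects, informative
missingness, and correlated (not block-diagonal) module structure; the
generator models none of these.  Results on the fixture demonstrate
algorithmic correctness, not field performance.

Two properties of the fixture are worth knowing:

* Because module members share a latent, their empirical SDs are
  strongly correlated; a latent that happens to draw a low sample
  variance can push an entire module below the SD-filter percentile.
  On clean simulated data (no missingness, unit population variance) the
  cleaning filters have nothing to clean, so the benchmark chain runs
  standardization only; the filters' semantics are tested separately on
  inputs built for them.
* The plain-correlation baseline (`correlation_adjacency`, soft power 1)
  merges the entire fixture dendrogram below the cut height — indirect
  associations give every feature pair a nonzero TOM — producing a
  single catch-all module.  This is the extreme form of the
  few-large-modules behaviour the baseline is included to demonstrate,
  and it makes its module-size SD undefined (one observation).

## Determinism

Every stage is deterministic given its inputs; the only randomness is
the generator seed, which the CLI threads from one global seed.  Two
runs with the same config produce byte-identical outputs, and the run
manifest (config echo, versions, seed, stage timings) suffices to
reproduce a run.

## Known limitations

* No missing-data-aware GGM: imputation precedes estimation.
* One PC per module; a module driven by two latents is summarized by the
  stronger one.
* The hybrid cut does not recursively split branches; a branch that
  merges two modules below the cut height is returned whole (lower
  `cut_height` or raise λ to separate).
* λ selection is manual (`scan-lambda` reports the trade-off table; no
  cross-validation).
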