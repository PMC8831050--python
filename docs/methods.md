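# Methods

`updrs` implements a hybrid pipeline for predicting Parkinson's disease
progression — Motor-UPDRS (0–108) and Total-UPDRS (0–176) — from
per-recording voice features collected by telemonitoring. The pipeline
has four stages: (1) missing-value prediction by iterated low-rank SVD,
(2) unsupervised patient grouping by ensembles of base clusterers fused
through a consensus function, (3) per-group PCA decorrelation, and
(4) per-group bagged ensembles of RBF-kernel support vector regressors,
one ensemble per target.

The premise is heterogeneity: different patient groups can follow
different feature-to-UPDRS maps. A single regressor has to average over
those maps; a clustered model only has to learn one smooth map per
group. The pipeline's value is exactly the size of that gap, which is
why the test suite includes both the heterogeneous regime (where the
clustered model must win) and a null regime (where it must not).

## Missing-value prediction (iterative truncated SVD)

The feature block is treated as a dense matrix; masked cells are
initialised with observed column means. Each sweep z-scores the
columns, replaces the matrix by its best rank-d approximation (truncated
SVD), copies the approximation's values into the masked cells only, and
undoes the normalisation. Sweeps stop when the largest absolute change
in any imputed cell falls below `tol` (default 1e-6) or after
`max_iter` (default 100) sweeps; `single_pass=True` performs the
literal one-sweep variant. Observed cells are never altered.

Numerical choices:

* **Rank.** `rank_d=None` selects the smallest rank capturing ≥ 90% of
  the squared singular-value mass at the first sweep; any fixed rank
  can be forced.
* **Normalisation inside the iteration** uses the *current filled
  matrix's* column moments, not the observed cells' moments. At the
  fixed point these are the completed matrix's own statistics, so
  centering does not add a rank: an exactly rank-2 block is recovered
  exactly at `rank_d=2`. Centering on observed cells only (the
  alternative convention) subtracts a row vector outside the completed
  matrix's row space and needs one extra rank for the same recovery.
  The standalone `normalize()` helper, used for scoring and
  preprocessing, works on observed entries only.
* **Scale** is the sample standard deviation (ddof = 1); constant
  columns raise an error naming the column.

## Base clusterers

**Gaussian-mixture EM.** Diagonal covariance by default — the
per-dimension variance update is the closest multivariate reading of a
scalar-σ mixture — with full covariance behind a flag. Initialisation
is k-means++ seeding; 5 restarts, best final log-likelihood kept. A
variance floor of 1e-6 × the per-feature variance prevents component
collapse. The log-likelihood trace is recorded per fit; tests assert it
is nondecreasing (within 1e-9) on every fit, which is the EM guarantee
and the first thing to break if the E- or M-step is wrong. Rows are
assigned to the argmax-responsibility component, ties toward the lowest
index.

**Self-organizing map.** A small rectangular lattice trained online:
per sample, the best-matching node and its lattice neighbours move
toward the sample. The neighbourhood radius starts at
max(rows, cols)/2 and the learning rate at 0.5; both decay
exponentially to 0.01 over the epochs (default 200 for standalone use;
the experiment harness uses 50). Empty nodes are kept as empty
clusters so the map geometry stays addressable; consensus functions
drop them when building hyperedges.

## Consensus functions

All three consume an ensemble of partitions of the same rows and emit
one consensus partition. Input partitions are first *canonicalised*
(labels renamed in order of first appearance), which makes every
consensus function exactly invariant to how the base clusterers happened
to name their clusters.

* **Majority voting.** Every partition is aligned to the first by
  optimal one-to-one label matching (Hungarian method on the
  contingency table; surplus clusters keep fresh labels). Each row then
  takes its modal aligned label; ties go to the earliest partition in
  ensemble order.
* **CSPA.** The co-association matrix S (fraction of partitions
  co-clustering each pair) is re-clustered by average-linkage
  agglomeration on 1 − S, cut at the target cluster count.
  Agglomeration is deterministic and dependency-free; the contract is
  similarity-based re-clustering, not any particular graph library.
* **HGPA.** Every cluster of every partition becomes a hyperedge; the
  consensus is a balanced k-way vertex split minimising the number of
  cut hyperedges. The search is multi-restart greedy single-vertex-move
  refinement with per-hyperedge part-count bookkeeping
  (Fiduccia–Mattheyses-style constant-time gain updates), 20 restarts
  by default: 19 random balanced starts plus one informed start from
  agglomerating the shared-hyperedge-count similarity. Part sizes must
  stay within (1 ± `imbalance_tolerance`) × n/k, default tolerance 0.2.
  On small instances (n ≤ 12) the returned cut is audited in tests
  against exhaustive enumeration of balanced bipartitions.

The consensus cluster count defaults to the median k of the ensemble's
members. Which consensus to trust is an empirical question the
experiment harness answers per dataset; on the synthetic heterogeneous
regime HGPA is the strongest, consistent with its global cut objective.

## PCA decorrelation

Per consensus cluster, a PCA basis is fit on the cluster's training
rows and applied to any row routed there. The retention rule keeps the
fewest components whose cumulative explained variance reaches the
threshold (default 0.95). Covariance uses the n−1 denominator;
eigenvector signs are fixed by making each component's
largest-magnitude loading positive, so bases are reproducible across
linear-algebra backends. PCA is always fit on training rows only.

## SVR ensembles

The regressor is ε-insensitive support vector regression with the
radial kernel written as K(x, y) = exp(−‖x−y‖²/γ²): γ is a *length
scale* in input units. The dual is solved by libsvm's SMO (through
scikit-learn) with the reciprocal-scale mapping g = 1/γ² applied
internally; dual feasibility (0 ≤ β, β* ≤ C, Σ(β−β*) = 0) is asserted
in tests on trained models, and a point strictly inside the ε-tube must
carry zero dual weight.

Hyperparameters are tuned by exhaustive grid search under 5-fold
cross-validation with seeded fold assignment. The full grids are
γ ∈ [0.01, 0.1] step 0.005 (19 values), ε ∈ [0.0001, 0.002] step
0.0001 (20 values) and C ∈ [3, 4.1] step 0.005 (221 values) — 83,980
cells. Because 5-fold search over the full product is an
hours-per-model proposition, two reduced grids are provided: `fast`
(5 × 5 × 5 evenly spaced values including endpoints, every value a
member of the full grid) and `tiny` (the single mid cell, for smoke
runs). Ties are broken toward smaller C, then larger ε, then smaller γ.

**Input and target scaling.** The grid's γ values are length scales of
order 0.01–0.1 and its ε values tube widths of order 10⁻³–10⁻⁴, i.e.
they presuppose inputs and targets of matching magnitude. The pipeline
therefore standardises each cluster's PCA scores and shrinks them so
the root-mean-square pairwise distance equals the grid midpoint
γ = 0.055 (for standardised p-dimensional rows, E‖x−y‖² = 2p, so the
factor is 0.055/√(2p)), and min-max maps each target to [0, 1].
Across the grid the squared distance-to-bandwidth ratio then spans
roughly 0.3–30 — from smooth to narrow kernels — and the ε grid spans
tube widths from 0.01% to 0.2% of the target range. Predictions are
mapped back to UPDRS units before being returned or scored; all
reported errors are in raw UPDRS points. The low-level operations
(`svr_train`, `grid_search`, `train_ensemble`) apply no scaling of
their own, so oracle tests can address the solver directly.

**Bagging.** Each ensemble holds 8 members by default, each trained on
a with-replacement resample of full training size (member i seeded with
seed + i; a degenerate resample with fewer than two distinct rows is
redrawn from a fresh sub-seed and logged). The ensemble prediction is
the unweighted mean of member predictions.

**Cluster-wise model.** Per consensus cluster with at least
`min_cluster_size` rows (default 25 — five folds of five): PCA → input
scaling → grid search per target → 8-member bagged ensemble per
target, plus the cluster centroid in imputed feature space. Tuning is
per cluster and per target, since nothing forces two targets or two
clusters to share hyperparameters. Rows from clusters below the
minimum are pooled into a fallback model (trained on the pool, or on
all rows if the pool is itself too small); if no cluster reaches the
minimum a single global model is fit with a warning. At prediction
time each row is routed to the nearest cluster centroid (Euclidean, in
imputed feature space) — the simplest auditable rule, returned
alongside the predictions. Grid search optionally tunes on a seeded
subsample of at most `max_tune_rows` rows (default 350) before the
final ensembles are trained on all rows; tuning cost grows superlinearly
with rows while the selected cell stabilises early, so this is where
the pipeline buys its speed.

## Evaluation

Metrics per prediction/observation pairing: RMSE; MAE; Willmott's
Index of Agreement IA = 1 − Σ(P−O)² / Σ(|P−Ō|+|O−Ō|)²; prediction
accuracy PA = Pearson correlation of P and O; and adjusted
R² = 1 − (1−R²)(n−1)/(n−m−1) with R = PA and m the predictor count
(the retained PCs of the routing cluster, averaged over clusters, in
pipeline reports). These are the standard definitions throughout — in
particular MAE is the mean absolute error, not a squared quantity, so
RMSE ≥ MAE always holds in this package's reports.

The experiment harness evaluates on held-out *subjects*: either a
single grouped holdout split (default, 25% of subjects) or a grouped
k-fold rotation. No subject's recordings ever span the train/test
boundary — recordings of one subject are strongly dependent, and
row-wise splitting would leak identity into the score. Base clusterers
are fit on training rows only (standardised with training statistics);
test rows reach a cluster only through centroid routing.

## Synthetic data generator

The generator emulates the telemonitoring schema: ~40 subjects with
100–200 recordings each, 16 correlated voice features, age/sex/test_time
covariates, and the two bounded targets. Structure:

* features follow a per-cluster Gaussian factor model — 3 shared latent
  factors with unit-norm loadings give marginal variance 1 for any
  correlation strength ρ ∈ [0,1); pairwise correlations grow
  monotonically with ρ (the multicollinearity PCA is asked to remove);
* cluster means are placed with minimum pairwise distance equal to
  `cluster_separation`, in units of the within-cluster SD;
* subjects carry cluster membership (assigned in rotation, so cluster
  sizes are balanced) and a small per-subject feature offset
  (SD 0.25);
* Motor-UPDRS is a cluster-specific smooth map (linear + quadratic +
  sinusoidal + interaction terms in the first features) plus Gaussian
  noise (default SD 2.0 UPDRS points); Total-UPDRS is an affine
  function of the motor signal plus its own cluster-specific feature
  term and noise. Coefficients differ in magnitude and sign across
  clusters, so cluster-then-regress genuinely beats one global
  regressor; `shared_target_function=True` with zero separation gives
  the null regime in which they tie. Targets are clipped to their
  scale bounds and the clip count is reported so tests can avoid
  saturated configurations.

What the generator does *not* emulate: the marginal shapes of real
acoustic measures (jitter and shimmer are heavy-tailed and bounded
below), longitudinal drift of UPDRS within subject over test_time, and
missingness that correlates with disease severity (masking here is
uniform at random). Passing tests therefore demonstrate that the
machinery is correct and that the method wins *when its structural
premise holds* — not that the premise holds in any particular clinical
dataset.

## Problem sizes and determinism

Test and acceptance runs use scaled study conditions chosen to keep a
full suite run comfortably on one CPU: the heterogeneous-regime
check uses 1,500 rows (30 subjects × 50 recordings), 5 replicate
seeds, the `fast` grid and grouped holdout evaluation; cluster-recovery
checks use 600 rows; consensus oracles use exhaustive enumeration at
n ≤ 12. Every stochastic component (generator, masking, EM and SOM
initialisation, fold shuffling, bootstrap resampling, HGPA restarts)
is driven by an explicit seed, and the pipeline is a pure function of
(config, seeds): rerunning a configuration reproduces its report
byte-for-byte.

## Known limitations

* HGPA's greedy refinement carries no optimality guarantee beyond the
  small-instance audit; on large instances the informed start does most
  of the work.
* The SVR solver's KKT conditions hold to libsvm's working tolerance
  (1e-3 by default); the exact-KKT audit in tests tightens the solver
  tolerance instead of loosening the assertion.
* Centroid routing can misroute rows that sit between clusters; the
  routing labels are returned so such rows can be audited.
* `min_cluster_size` interacts with the consensus k: a consensus that
  fragments the data produces fallback-served rows rather than failing.
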