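# Methods

This note documents the models, estimators, numerical choices and known
limitations of `risis`. Everything stated here is computed by the test suite
or the analysis drivers; nothing is asserted beyond what the code measures.

## Discovery model

The discovery target is a *binary partition with clear separation*: a
labeling of samples into a larger class g0 and a smaller class g1 such that
a compact gene module separates the classes far beyond chance.

**Separation score.** For labels with class sizes (n0, n1) the per-gene
moderated t-statistic is

    t_g = (mean_g1 - mean_g0) / sqrt((sp2_g + s0) * (1/n1 + 1/n0))

with `sp2_g` the pooled within-class variance and `s0` the median of
overall gene variances, a floor that keeps near-constant genes from
dominating. The split score is the mean of the m = 100 largest t_g^2. The
score is symmetric under label swap and invariant to gene/sample order.

**Search.** Candidates are seeded deterministically from (a) exact 1-D
2-means threshold splits of the sample scores on each of the top 10
principal components and (b) largest-gap threshold splits on each of the
200 most variable genes, all restricted to leave at least
`min_group_size = max(5, 10% of n)` samples on each side. After exact
deduplication, the 25 best seeds by initial score are refined by
first-improvement sweeps of single-sample reassignment (cap 50 sweeps).
Refining only the best seeds keeps one search under a second at 1,000 genes
x 129 samples while leaving multi-start coverage broad enough that, on
8-sample toy matrices, the refined optimum matches exhaustive enumeration
of all bipartitions (a property the suite asserts). The refinement kernel
is JIT-compiled with numba.

**Significance.** The null distribution of the *best achievable* score is
estimated by re-running the identical search on matrices whose genes have
each been independently permuted across samples (destroying all
gene-module/sample-class covariance while preserving each gene's marginal
distribution). With `n_perm` such draws the p-value of a refined candidate
is `(1 + #{null max >= score}) / (n_perm + 1)`; candidates with p >= alpha
(default 0.05) are discarded. Because the null re-runs the full search, the
optimism of hill-climbing is present on both sides of the comparison; on
pure-noise cohorts the search returns an empty list in >= 90% of runs,
which the acceptance suite checks. `n_perm` must satisfy
`1/(n_perm + 1) < alpha` (the code rejects configurations that cannot reach
significance); the default is 99.

**Redundancy.** Surviving partitions are pruned greedily from the top
score: a partition is dropped if its label agreement (after optimal class
matching) with an already-kept one exceeds 0.8.

## Stability gating

For each bootstrap replicate (default 100), `floor(0.63 n)` training
samples are drawn without replacement and the search is re-run on them with
the permutation filter off — at this stage false positives are controlled
by the requirement that a replicate split match the candidate (label
agreement >= 0.75 on the shared samples), and by the final stability bar.
A matched replicate split trains a diagonal linear discriminant
(`w_g = (mean_g1 - mean_g0)/(s_g^2 + s0)`, centers at class-mean midpoints,
threshold at the training equal-error point) whose predictions on the
replicate's held-out samples are compared with the candidate labels.
Stability is the mean held-out agreement over matched replicates (defined
as 0 when nothing matches), and a candidate is retained when stability
strictly exceeds 0.95.

Hold-out confirmation repeats the same construction against the disjoint
model-selection samples: the full-training discriminant fixes reference
labels there, each replicate's matched classifier re-predicts them, and the
split is confirmed when the mean prediction consistency exceeds the same
bar. An earlier design that asked only "is the predicted partition stable
within the model-selection matrix?" was discarded: in a matrix containing a
real strong partition, even a noise-trained classifier's projection
collapses onto that partition, so the check could not reject noise
candidates. The replicate-matching construction rejects them structurally
(a noise candidate is never rediscovered, so its consistency is 0).

Small minorities are a known limitation: a class with fewer than ~6
expected members in a 63% subsample sits at the `min_group_size` floor and
may fail rediscovery, deflating stability for real but small subgroups.

## MicroRNA cross-validation

Nearest shrunken centroids: standardized class-vs-overall differences
`d_kg = (xbar_kg - xbar_g)/(m_k (s_g + s0))`, `m_k = sqrt(1/n_k - 1/n)`,
soft-thresholded by Delta; prediction minimizes the standardized distance
to the shrunken centroid minus `2 log(prior_k)` with empirical priors, ties
to the lexicographically first class. Nested CV uses stratified outer
k = 10 and inner k = 5 folds; the Delta grid is 30 even points from 0 to
the largest |d_kg| of the fold's training part; inner ties resolve toward
the larger Delta (more parsimony). Outer-fold test predictions pool into
one confusion matrix; consensus features are the strict intersection of
surviving features across outer-fold models. Per-class error is
off-diagonal row mass over row sum, reported at 2-3 decimals.

## Subtype score

Signature genes are robustly rescaled per gene by clipping at the 2.5% and
97.5% quantiles and mapping those to -1/+1 (constant genes map to 0); this
makes the score invariant to per-gene positive affine transforms and hence
portable across platforms. The score is `sum w_g x_gs / sum |w_g|`, in
[-1, 1], with discriminant weights signed so that positive means higher in
the angiogenic class. Per-cohort score standardization is available as an
option but off by default; cross-platform behavior beyond per-gene scaling
is untested.

Bimodality: univariate Gaussian mixtures for k = 1..5 fitted by EM
(k-means initialization, 3 seeded restarts, tolerance 1e-6 on the
log-likelihood increment, variance floor 1e-6 x total variance), selected
by BIC = -2 loglik + (3k - 1) ln n. The per-iteration log-likelihood trace
is retained and its monotonicity asserted in tests; fits are cross-checked
against scikit-learn's GaussianMixture. With k >= 2 the highest-mean
component is the angiogenic one and a sample is called angiogenic when its
posterior mass on that component exceeds 0.5; the decision boundary is the
posterior-0.5 crossing located on a 2001-point grid. k = 1 yields an
explicit no-subtype flag rather than calls.

## Survival and clinical association

Kaplan-Meier, logrank and Cox regression are delegated to lifelines; Cox
uses Efron tie handling (lifelines' default, preferred over Breslow for
small samples) and the Wald 95% CI `exp(beta +/- 1.96 se)`. Implausible
coefficients (|beta| > 20 or non-finite SE) are reported as suspected
monotone likelihood rather than returned. Fisher 2x2 tests use the exact
two-sided probability-mass ordering (scipy); r x c tables use a
fixed-margin Monte-Carlo estimate (random pairing of row/column
memberships, add-one-corrected `(k+1)/(n_mc+1)`, default n_mc = 20,000,
agreeing with the exact 2x2 answer to < 0.005 at n_mc = 1e5). Zero-margin
rows/columns are dropped with a warning. Subtype proportions are reported
as integer-rounded percentages per category.

Functional characterization of a module is hypergeometric
over-representation against user-supplied GMT gene sets within the filtered
gene universe, with Benjamini-Hochberg control and a 10% FDR flag. This is
a deliberate simplification of rank-based gene-set enrichment: the module
is a fixed 100-gene list, so set overlap is the natural statistic, and it
needs no gene ranking or annotation-specific permutation scheme.

## Synthetic cohorts

The generator emulates the study design, not the platform: gene baselines
mu_g ~ Normal(8, 1.5^2) on a log2-like intensity scale, additive class
shifts of `effect x noise_sd` on disjoint planted modules, i.i.d. Gaussian
noise (noise_sd = 1). Defaults: 129 tumors, 12,000 genes, four planted
partitions with minority fractions 33/129, 46/129, 0.30 and 0.42 (the first
two mirror the class sizes the confusion tables imply) and a common effect
of 2.5 sigma on 100-gene modules; 12 technical duplicates appended as extra
columns (re-noised copies of the clean profile, so the duplicate-variance
filter has something to measure); 743 microRNAs of which 40 are shifted by
2 sigma between split-1 classes; exponential survival with baseline rate
0.1 per time unit and hazard ratio 1.3 for the split-1 minority, censored
by an independent Uniform(0, T) with T solved by root-finding to hit the
target censoring fraction (0.3); clinical covariates drawn from fixed
category frequencies, optionally tilted by a log-odds parameter (0 by
default, i.e. independent of subtype).

What this does *not* emulate: probe-level effects, batch structure,
correlated background expression, heavy-tailed noise, or gene-gene
correlation outside the planted modules. Passing tests therefore
demonstrate correctness of the machinery and its statistical calibration
under the design assumptions, not performance on real arrays.

Problem sizes used in the validation suite are chosen to keep the full run
in a few minutes of one CPU: the planted-recovery check runs at the full
design size (12,000 x 129, 99 permutations, 40 bootstrap replicates), the
20-replicate false-positive check uses 2,000-gene x 60-sample noise
cohorts filtered to 400 genes (the false-positive behavior of the
permutation test does not depend on matrix size), and survival calibration
uses 100 replicates at n = 500-1,090.

## Reproducibility

Every stochastic stage takes an explicit seed; the pipeline derives
per-stage seeds from one config seed by fixed offsets, and a rerun with the
same config reproduces artifacts byte for byte (asserted in tests). The
search itself is deterministic given its inputs; randomness enters only
through permutation draws, bootstrap subsets, folds and the generator.
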