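# Methods

This note documents the models, the synthetic data generators, the
measurement protocol and the numerical choices behind `plsdabench`, in
enough detail to judge what the test suite does and does not establish.

## Projection methods

All methods operate on the column-centered matrix `Xc = X - mean(X)`
and expose unit-norm direction columns `weights_`, training
`scores_`, a per-component importance, and nearest-centroid class
prediction in score space.

**PCA.** A thin SVD of `Xc` yields the eigenpairs of the sample
covariance `C = X'CnX/(n-1)` exactly; `component_importance_` holds the
eigenvalues in non-increasing order and `loadings_` the scaled
eigenvectors `sqrt(lambda_i) e_i`. Requesting more than `min(n-1, m)`
components is an error; a zero-variance matrix is rejected as
degenerate.

**PLS-DA.** The label block is the single centered 0/1 vector
`yc`, so the covariance-maximising weight of each component is the
closed form `w_h ∝ X_h' yc` (the rank-one eigenproblem needs no
iteration). After each component the data matrix is deflated by the
rank-one score/loading update `X_{h+1} = X_h - t_h p_h'` with
`p_h = X_h' t_h / (t_h' t_h)`; `y` is **not** deflated. This is the
standard single-response construction and makes score columns mutually
orthogonal. New samples are projected with the rotation matrix
`W (P'W)^{-1}`, which reproduces the training scores exactly.
`y_loadings_` stores the per-component regression of `yc` on the score;
the importance is the achieved covariance `|t_h' yc|/(n-1)`. Requesting
more components than the rank supports truncates with a warning rather
than failing, since grid sweeps routinely hit that edge.

**sPLS-DA.** Before normalisation the weight is soft-thresholded with
the penalty set to the largest excluded magnitude, so each component's
support has an exact, user-chosen size (`keep`). This is the hard-
selection limit of the lasso-penalised sparse PLS construction; the
benchmark always asks for exactly `s` features, so no continuous
penalty tuning is exposed. With `keep = m` the method reproduces dense
PLS-DA to machine precision. An exact tie at the threshold would shrink
a kept entry to zero; such entries are clamped to the smallest positive
float so the support-size contract survives ties (measure-zero on
continuous data).

**ICA.** PCA whitening to `d` dimensions, then the symmetric fixed-point
iteration for the log-cosh negentropy contrast. Components are ordered
by the squared deviation of `E[log cosh s]` from its standard-normal
value. The unmixing matrix depends on the `random_state` only through
its initialisation; the same seed gives bit-identical results. On
Gaussian-only data no direction is preferred and the ordering is
effectively arbitrary — an identifiability limit of ICA itself, not of
the implementation. With one component the whitened space is
one-dimensional, so ICA coincides with PCA. For feature selection ICA
ranks features by the maximum |unmixing weight| across components,
because independent sources have no canonical "first" component.

**SPCA.** Per component, alternating rank-one SVD steps
(`u <- Xv/|Xv|`, `v <- threshold(X'u)`) with the same exact-support
threshold operator, then projection deflation. With no threshold the
iteration converges to the leading singular vector, i.e. plain PCA.

**RLDA.** Single discriminant `(S_W + ridge I)^{-1}(mu_1 - mu_0)` with
`S_W` the pooled within-class covariance. The default ridge is
`1e-3 * mean(diag(S_W))` — scale-free, large enough to invert `m > n`
scatters, small enough to leave well-conditioned problems unchanged.
`ridge = 0` demands a positive-definite scatter and otherwise raises an
error directing the user to a positive ridge.

**Prediction rule.** All methods classify new samples by the nearest
class centroid in score space (centroids from training scores). This is
the simplest member of the distance-rule family commonly used with
PLS-DA; no claim is made that it matches any particular existing
implementation's default distance.

**Sign convention.** Every weight column is oriented so its largest-
magnitude entry is positive. Predictions, selections and all metrics are
invariant to these sign flips; the convention only pins down serialized
output across platforms.

## Synthetic data models

All generators draw from `numpy.random.default_rng(seed)` and are
bit-exactly reproducible from their `GeneratorSpec`. Signal features
are generated in the leading columns and scattered by a recorded random
column permutation; the manifest stores the permuted signal indices and
a true loading vector (indicator of the signal set). Degenerate
labelings (a class with fewer than two members) are regenerated with an
incremented seed, at most 100 times.

**random_labels.** All m features i.i.d. U[0,1]; labels are fair coin
flips; the signal set is empty, so every selected feature counts as a
false positive.

**linear.** All features i.i.d. U[0,1]; a sample is class 0 when the
*mean* of its s signal features is at least C = 0.5, class 1 otherwise.
The sum-threshold rule is read on the mean scale because a fixed
threshold of 0.5 on the raw sum of s uniforms leaves class 1 empty for
any s > 2; the mean reading keeps the rule linear and the classes near
balance for every s. `C <= 0` or `C >= 1` makes the rule one-sided by
construction; such specs return the single-class labeling instead of
retrying. Note a structural property of this model: the labels are a
deterministic function of an i.i.d. uniform matrix, so the *marginal*
distribution of X carries no trace of the rule. An unsupervised method
therefore has nothing to detect — its expected selection precision is
s/m — while the per-feature label covariance that PLS-DA estimates is
positive on every signal feature. Results on this model should be read
with that asymmetry in mind (see "Known limitations").

**cluster.** The signal features of a sample are drawn from one of two
spherical Gaussian clusters (class = cluster membership, fair-coin
assignment) whose centers sit a distance
`delta = 2 z_0.95 (1 + sep)/(1 - sep) * cluster_sd` apart along a random
direction of the signal subspace, centered on 0.5; noise features are
i.i.d. U[0,1]. `sep` in [-0.9, 0.9] is the two-cluster quantile
separation index (alpha = 0.05) solved in closed form: -0.9 gives
near-coincident clusters, 0 clusters that just touch at their 95%
quantiles, 0.9 a ~62-sd gulf. `cluster_sd` defaults to `sqrt(1/12)`,
the standard deviation of the uniform noise, so signal features have
the same marginal spread as noise and only the separation — not raw
variance — carries class information; with a much larger cluster sd the
signal subspace dominates total variance and variance-seeking methods
find it at any separation, which defeats the purpose of the sweep. The
empirical separation recovered from the generated scores matches `sep`
within ±0.1 at n = 2000 (round-trip test).

**interval.** The unit interval is split into p subintervals of width
1/p. For each (class, feature) pair an assignment decides whether
values are drawn from one fixed random subinterval (chosen once per
class/feature, shared by all samples) or from the full [0,1]. Presets:
`signal_constrained` confines the class-1 signal features only;
`noise_constrained` additionally confines every noise feature for *all*
samples (same subinterval for both classes, hence class-uninformative
but low-variance). The second preset is what makes variance-based
selection shine: the informative features are the only high-variance
ones. With p = 1 the "subinterval" is [0,1] itself and the model is
uninformative. Custom assignments are accepted as a
`(class | 'all', 'signal' | 'noise') -> 'subinterval' | 'full'` map.

## Measurement protocol

**Feature selection.** A fitted model ranks features by |weight| on its
first component (ICA: max across components), ties broken toward the
lower index; the top s features are scored against the manifest.
Because exactly s features are selected and exactly s are true,
fp = fn and precision = recall on every record — precision is therefore
the only tabulated selection metric.

**Loading recovery.** Cosine distance `1 - |cos angle|` between the
first weight vector and the unit-normalised true loading. The absolute
value makes the metric invariant to the arbitrary sign of fitted
directions.

**Apparent separability.** The best training accuracy of a threshold on
the first-component score, scanning every cut between distinct sorted
values in both orientations (0.5 for constant scores on balanced
labels; 1.0 for perfectly separated scores). This is the optimistic
"apparent error" counterpart of the CV error.

**Repeated CV.** Stratified k-fold (default 5 folds, 10 repetitions)
with a fresh fold assignment per repetition. All fitting statistics —
centering means, weights, centroids — come from the training folds
only; the random-label studies hovering at 0.5 are the leak check. With
coin-flip labels the realised class split is not exactly 50/50, so
held-out error can sit slightly below 0.5 without leakage (the
classifier partially captures the majority class); dataset-level spread
at n = 100 is about ±0.05.

**Grids.** Each (cell, repeat) derives its seed from
`SeedSequence([base_seed, i, j, r])`, so any cell is reproducible in
isolation and tables are bit-identical across runs. The surface tables
are long-format DataFrames/TSVs of (axis values, method, metric, mean,
sd, repeats).

## Problem sizes used

The shipped studies run at the benchmark's stated settings — n = 200,
s = 10, m in the tens-to-hundreds for the model comparisons; n = 100
with m up to 20 000 for the ratio study — with 20 repeats per grid cell
and 100 CV repetitions (10 datasets x 10 repetitions) per ratio, which
keeps the full suite and the acceptance script to tens of seconds while
leaving per-cell standard errors well below the effect sizes asserted.
Repeat counts are parameters (`GridSpec.repeats`,
`CVConfig.repetitions`) and can be raised freely.

## Known limitations

* On the **linear** model as implemented (labels post hoc from i.i.d.
  features), PCA is blind by construction, so this package's linear
  study shows PLS-DA ahead of PCA — the opposite of the ordering
  sometimes reported for "linearly separable" benchmarks whose
  generators couple the signal features (e.g. compositionally). Any
  generator that shifts class means along the rule direction is
  detected at least as well by the label-covariance weight of PLS-DA,
  so the reversed ordering is not reachable from this rule family; a
  coupled generator would need to put class information into the
  covariance structure while keeping per-feature label covariance near
  zero.
* The cluster model reproduces a separation *index*, not any particular
  cluster-generation package's covariance rotations; clusters are
  spherical by design.
* Apparent separability is measured on the first component only. With
  m >= 2n a perfectly separating hyperplane always exists in full
  feature space, but the first-component statistic saturates at 1.0
  only from m/n around 20 upward (it is ~0.94 at m = 2n, n = 100).
* The one-vs-all curve analysis takes abundance values as provided (no
  compositional transform) and scores against whatever importance table
  is supplied; the shipped tests use a planted fixture, so they
  demonstrate harness correctness, not conclusions about any external
  dataset.
* Passing tests on these generators show method behavior under clean,
  known-truth conditions — uniform noise, independent features,
  exactly s informative features. Real omics data add compositionality,
  correlation among noise features, heavy tails and batch structure,
  none of which the generators emulate.
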