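# plsdabench

Partial Least-Squares Discriminant Analysis (PLS-DA) is widely used in
omics and chemometrics both to select discriminative features and to
classify samples, yet on data with many more features than samples it
happily finds "perfect" separations of randomly labeled points.
`plsdabench` is a benchmarking package for studying exactly when PLS-DA
helps and when it misleads: it implements PLS-DA, PCA and sparse PLS-DA
from first principles (plus ICA, sparse PCA and regularized LDA for
comparison), four ground-truthed synthetic data models, and an
evaluation harness that scores each method as a feature selector
(precision against the known signal set) and as a classifier (repeated
stratified cross-validation).

It is aimed at methodologists and applied analysts who want a controlled
test bed: every synthetic dataset carries a manifest naming its signal
features and generating rule, so "did the method find the right
features?" has an exact answer.

## Methods

With `X` the n x m data matrix and `Cn` the centering matrix:

* **PCA** — components are eigenvectors `e_i` of
  `C = X'CnX/(n-1)`; loading vectors are `L_i = sqrt(lambda_i) e_i`.
* **PLS-DA** — component `h` maximises `cov(X_h a_h, y b_h)` for the
  0/1 label vector `y`; since the label block is a single column, each
  weight has the closed form `a_h ∝ X_h'(y - mean(y))`, and `X` is
  deflated between components so score columns are orthogonal.
* **sPLS-DA** — the same iteration with each weight soft-thresholded to
  an exact number of nonzero entries (embedded feature selection).
* **ICA / SPCA / RLDA** — fixed-point negentropy maximisation after PCA
  whitening; alternating regularized SVD with soft-thresholding;
  `(S_W + ridge I)^{-1}(mu_1 - mu_0)` with pooled within-class scatter.

Classification uses the nearest class centroid in score space.

Synthetic models: `random_labels` (uniform noise, coin-flip labels),
`linear` (label = linear rule over s signal features), `cluster` (two
Gaussian clusters in the signal subspace, separation set by a quantile
separation index in [-0.9, 0.9]), and `interval` (features constrained
to width-1/p subintervals of [0, 1]).

## Worked example

```python
import numpy as np
from plsdabench import GeneratorSpec, generate, PCA, PLSDA
from plsdabench.evaluation import select_top_features, selection_confusion

spec = GeneratorSpec(model="cluster", n=200, m=100, s=10, sep=0.0, seed=1)
data = generate(spec)
for est in (PCA(n_components=1), PLSDA(n_components=1)):
    est.fit(data.X, data.y)
    picked = select_top_features(est, 10)
    conf = selection_confusion(picked, data.truth, 100)
    print(est.method, "precision", conf.precision)
```

prints

```
pca precision 0.7
plsda precision 0.8
```

i.e. on two-cluster data whose clusters just touch (separation index 0),
label-aware PLS-DA recovers 8 of the 10 true signal features while PCA,
which only sees variance, recovers 7.  The experiment grids
(`plsdabench.experiments`) repeat such cells over parameter sweeps and
tabulate mean precision, cosine distance to the true loading vector,
apparent separability and CV error as long-format tables; the same
studies are exposed on the command line:

```sh
plsdabench grid --model cluster --axes "sep=-0.5,0,0.5;n=50,200" --out table.tsv
plsdabench separability --ratios 2:1,1:2,1:20,1:200 --out sep.tsv
```

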