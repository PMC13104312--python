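# Methods

This note documents the statistical model behind `fairspace`, the choices
made where the design was genuinely open, what the synthetic cohorts do and
do not emulate, and the known limits of the approach.

## Model and assumptions

The central assumption is linearity: demographic effects are taken to
manifest as a low-dimensional *linear* subspace of feature space, separable
from disease effects because the two kinds of variation tend to occupy
different axes. Healthy controls from all demographic groups are assumed to
be a sufficient sample of the demographic structure; cases are excluded
from the PCA so that the candidate directions are not contaminated by
disease variation. Confounders must be *observed* (the group label is
given); latent-confounder estimation is out of scope.

The dual flagging criterion — bias effect size above `es_bias`, disease
effect size below `es_disease` — is deliberately asymmetric: the defaults
(0.1 and 0.5) exclude even small demographic effects while protecting
medium-to-large disease effects. With more than two demographic groups or
disease conditions the two-group Cohen's *d* is replaced by Cohen's *f*
(between-group SD over pooled within-group SD, population-weighted
numerator) with unchanged thresholds; *f* reduces to |d|/2 for two
equal-size groups, so the scales are commensurate.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `es_bias` | 0.1 | minimum \|d\| (or f) of control-group separation for a PCA direction to be flagged |
| `es_disease` | 0.5 | maximum case/control \|d\| (or f) a flagged direction may carry |
| `es_bias_prime` | 0.1 | minimum \|d\| for an LDA-refined direction to enter `V_bias` |
| `n_permutations` | 19,999 | label permutations per feature-level test (p-value floor 5e-5) |
| `alpha_features` | 0.05 | BH-FDR threshold for calling a feature biased |
| `max_components` | none | optional cap on retained PCA directions |
| `disease_subspace_dims` | 50 | dimensions of the greedy disease subspace used in signal-loss reporting |
| `top_k_markers` | 5,000 | regions kept per disease type when ranking tumor-normal differences |
| `impact_quantile` | 0.25 | fraction of features reported as most impacted by adjustment |
| `svm_C` | 1.0 | L2 regularization of the linear-SVM detection stage |

Effect-size thresholds always compare magnitudes; the orientation of a
subspace direction is arbitrary (a deterministic sign convention — largest
loading positive — is applied only so that serialized models are
reproducible; the contract is the *span* of `V_bias`, not individual
vectors).

## Numerical choices

- **Centering.** All projections and the removal operate on
  `X − 1cᵀ` with `c` the training-control mean, and the center is added
  back: `X_adj = X − (X − 1cᵀ) V_bias V_biasᵀ`. This keeps the adjusted
  matrix on the original scale and makes the empty model an exact
  identity. A `centered=False` flag applies the raw projector instead.
  PCA centers but does not scale features to unit variance.
- **Rank handling.** PCA directions with singular value ≤ 1e-10 × the
  largest are treated as numerically null and dropped; the disease-subspace
  LDA works in the top-(samples − 2) PCA coordinates of the training
  matrix, because discriminant analysis in an ambient dimension of
  thousands of features is ill-posed.
- **LDA regularization.** The within-class covariance in the (small)
  working coordinate system is Ledoit–Wolf shrunk (`shrinkage='auto'`), so
  a discriminant is always defined even with tiny minority strata. With
  >2 groups the leading discriminant of the eigendecomposition is used.
- **Deflation.** After each discriminant the remaining working basis is
  recomputed as an orthonormal basis (SVD) of the orthogonal complement of
  the found direction within the current span — numerically stabler than
  sequential Gram–Schmidt. All m refined directions are computed and then
  thresholded; there is no early stopping, because LDA order does not
  guarantee monotone effect sizes.
- **Permutation tests.** Welch's t is the permutation statistic (robust to
  the unequal group sizes inherent to the setting; the permutation null is
  valid for any statistic). Random permutations use the add-one convention
  p = (1+b)/(1+B); when the number of distinct label assignments is ≤ B the
  null is enumerated exhaustively and p is exact. Feature-level tests are
  two-sided by default; one-sided tests are reserved for directional
  score-distribution comparisons. Constant-and-equal groups give p = 1;
  constant-but-unequal give t = ±∞.
- **RDA.** Signal loss is the Ezekiel-adjusted redundancy-analysis R²:
  multivariate OLS of the first n disease-subspace coordinates on the
  `V_bias` coordinates, `adjR² = 1 − (1−R²)(s−1)/(s−k−1)`; undefined
  (reported missing) when samples ≤ predictors + 1. The implementation is
  cross-checked against the `vegan` R package in the test suite.
- **AUROC inference.** DeLong midrank variance for CIs (Wald, clipped to
  [0,1]) and for the paired one-sided comparison of two score vectors.
  Whether bracketed AUROC intervals in comparable analyses are DeLong or
  bootstrap is rarely stated; DeLong was chosen and is validated against a
  bootstrap oracle in the tests.
- **Detection stage.** Markers are ranked by mean tumor-minus-normal
  difference (descending, ties broken by feature ID); multi-disease runs
  union the per-type top lists. Values are clipped at 0 before the
  `log(1+1000·X)` transform, since the adjustment can push counts slightly
  negative while the transform's domain and the physics of counts require
  nonnegativity. The SVM score is the signed decision margin
  (rank-equivalent to a probability; no extra calibration fit), with a
  Platt-calibrated probability available behind `probability=True`.
- **Cross-validation.** Stratified k-fold preserving class × group
  proportions, seedable or supplied via a metadata `fold` column; the
  bias model is fitted per training fold only and applied to both folds;
  pooled AUROC is computed on concatenated test scores, not the mean of
  fold AUROCs; one model per arm per fold, no ensembling.

## The synthetic cohorts

`SyntheticSpec` defaults define the reference study conditions used
throughout the acceptance tests: 2,000 features; majority 300 controls +
300 cases; minority 150 controls + 15 cases; a 3-D planted bias span at
Cohen's d = 0.8 per direction applied to *all* minority samples (bias is a
property of the person, not the disease — the fit only ever sees the
control contrast); a 5-D disease span at d = 1.0 applied to all cases;
spans orthogonal by default (`overlap_angle=90`); i.i.d. Gaussian noise of
unit SD. Gaussian noise matches the linear-subspace premise of the method;
a lognormal-count mode exists for realism but defaults off. Planted
directions are random orthonormal vectors unless explicit (e.g. sparse)
bases are supplied.

Two structural properties of this generator matter when interpreting test
results:

- The planted group shift is *constant* within the minority group, so the
  group-mean structure is rank-1 regardless of the nominal span dimension:
  a two-group discriminant can identify at most one direction of the
  planted span, and within-group score rankings (hence per-group AUROC)
  are unaffected by the shift itself. Consequently the generator
  reproduces the feature-level and score-distribution symptoms of
  demographic bias, but only weakly the per-group AUROC degradation seen
  in real cohorts, where bias interacts with disease signal in richer
  ways.
- With dense random planted directions, per-feature effects are diluted by
  √p (per-feature d ≈ 0.03 at the reference scale), below feature-level
  detectability; sparse bases (as in the README example) are the right
  tool when feature-level behavior is the object of study.

Passing tests on these cohorts therefore demonstrate the algebra, the
estimator behavior, leakage safety, and the direction of the corrections —
not clinical performance on real methylation data.

## Problem sizes used in the tests

The acceptance tests run the reference cohort at 50 seeds for subspace
recovery and the paired fairness comparison, 10 seeds for feature-level
debiasing (1,999 permutations), and 3 seeds for signal-loss estimation
with a 50-dimensional disease subspace; statistical-primitive calibration
uses 500 null datasets at 199 permutations. `scripts/acceptance.py` runs
one full cross-validated experiment plus a 10-replicate paired summary.

## Known limitations

- Linear subspaces only; nonlinear (kernel or learned-representation)
  bias structure is out of scope by design.
- Observed group labels are required; latent or continuous confounders are
  not modeled.
- At the reference noise level the planted bias direction itself is not
  recoverable to tight angular precision (the best linear estimator of a
  d = 0.8 shift in 2,000 dimensions from 450 controls is ≈70° off);
  the method removes the *estimated* span, which suffices to zero the
  measured bias but should not be read as recovering the generative
  directions.
- The effect-size threshold `es_bias = 0.1` equals the null sampling SD of
  d at the reference control-group sizes, so roughly 30% of pure-noise PCA
  directions are flagged in Step 2; the LDA refinement then concentrates
  them into ~3 selected directions even under a no-bias null. Users
  wanting a conservative selected dimension on null-like data should raise
  `es_bias`/`es_bias_prime` relative to `√(1/n₁ + 1/n₂)` of their control
  strata.
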