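"""The four-step bias-subspace removal algorithm.

The method assumes demographic effects manifest as linear components of the
feature space.  It (1) decomposes the control samples by PCA, (2) flags
principal directions that separate demographic groups among controls while
carrying little case/control signal, (3) refines the flagged span by
iterative linear discriminant analysis with deflation to concentrate the
bias into as few directions as possible, and (4) removes the projection of
any matrix onto the selected directions.

Fitting uses training data only; the fitted model can then be applied
uniformly to training and testing matrices, which keeps the procedure
leakage-safe under cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .io import FeatureMatrix, RunConfig, SampleMetadata
from .stats import group_effect_size

__all__ = [
    "PCABasis",
    "SubspaceFlag",
    "DebiasModel",
    "fit_pca_on_controls",
    "project",
    "flag_subspaces",
    "iterative_lda_refine",
    "select_bias_directions",
    "debias_fit",
    "debias_transform",
]

_SV_RTOL = 1e-10  # singular values below this fraction of the largest are noise


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Deterministic orientation: the largest-|loading| entry of each column
    is made positive (ties resolved to the lowest row index by argmax)."""
    if V.size == 0:
        return V
    idx = np.abs(V).argmax(axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


@dataclass
class PCABasis:
    """Orthonormal principal directions of the training controls."""

    center: np.ndarray
    directions: np.ndarray        # (n_features, n_dirs), orthonormal columns
    singular_values: np.ndarray   # descending

    @property
    def n_directions(self) -> int:
        return self.directions.shape[1]


@dataclass(frozen=True)
class SubspaceFlag:
    """Per-PCA-direction diagnostics from the dual effect-size criterion."""

    index: int
    bias_es: float
    disease_es: float
    flagged_biased: bool


@dataclass
class DebiasModel:
    """Fitted model: centering vector plus selected orthonormal bias
    directions, applicable to any matrix with matching features."""

    feature_ids: list[str]
    center: np.ndarray
    bias_directions: np.ndarray            # (n_features, k), orthonormal
    per_direction_bias_es: np.ndarray      # length k
    pca_flags: list[SubspaceFlag]
    config_used: RunConfig
    refined_directions: Optional[np.ndarray] = None   # all m refined, ordered
    refined_bias_es: Optional[np.ndarray] = None

    @property
    def n_selected(self) -> int:
        return self.bias_directions.shape[1]


def _control_groups(meta: SampleMetadata) -> tuple[np.ndarray, np.ndarray]:
    """Control mask and group labels; validates stratum sizes."""
    ctrl = meta.is_control
    groups = meta.group[ctrl]
    levels, counts = np.unique(groups, return_counts=True)
    if levels.size < 2:
        raise ValueError(
            "controls must span at least two demographic groups "
            f"(found {list(levels)})"
        )
    small = levels[counts < 2]
    if small.size:
        raise ValueError(f"control stratum with < 2 samples: {small[0]!r}")
    return ctrl, groups


def fit_pca_on_controls(
    X: FeatureMatrix,
    meta: SampleMetadata,
    max_components: Optional[int] = None,
) -> PCABasis:
    """PCA (SVD of the centered control submatrix) fit on controls only.

    Excluding cases keeps the decomposition focused on demographic and other
    non-disease variation.  Directions whose singular value is below
    1e-10 x the largest are treated as numerically null and dropped.
    """
    meta = meta.aligned_to(X)
    ctrl = meta.is_control
    if int(ctrl.sum()) < 3:
        raise ValueError("need at least 3 control samples to fit PCA")
    Xc = X.values[ctrl]
    center = Xc.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc - center, full_matrices=False)
    if s.size and s[0] > 0:
        keep = s > _SV_RTOL * s[0]
    else:
        keep = np.zeros(s.shape, dtype=bool)
    V = _fix_signs(Vt[keep].T)
    s = s[keep]
    if max_components is not None and V.shape[1] > max_components:
        V = V[:, :max_components]
        s = s[:max_components]
    return PCABasis(center=center, directions=V, singular_values=s)


def project(X: FeatureMatrix | np.ndarray, center: np.ndarray,
            v: np.ndarray) -> np.ndarray:
    """Scores of each sample on direction(s) ``v`` after centering."""
    vals = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    v = np.asarray(v, dtype=float)
    if vals.shape[1] != v.shape[0]:
        raise ValueError(
            f"dimension mismatch: matrix has {vals.shape[1]} features, "
            f"direction has {v.shape[0]}"
        )
    return (vals - center) @ v


def _bias_and_disease_es(scores: np.ndarray, meta: SampleMetadata,
                         ctrl: np.ndarray) -> tuple[float, float]:
    bias = group_effect_size(scores[ctrl], meta.group[ctrl]).magnitude
    if np.unique(meta.disease[~ctrl]).size > 1:
        # several disease conditions: Cohen's f across all disease levels
        disease = group_effect_size(scores, meta.disease).magnitude
    else:
        disease = group_effect_size(scores, ctrl.astype(int)).magnitude
    return bias, disease


def flag_subspaces(
    basis: PCABasis,
    X_train: FeatureMatrix,
    meta: SampleMetadata,
    es_bias: float,
    es_disease: float,
) -> list[SubspaceFlag]:
    """Dual effect-size criterion per principal direction.

    bias_es is |Cohen's d| (f for >2 groups) between minority and majority
    *control* projections; disease_es is the case/control effect over all
    training samples.  A direction is biased when it shows substantial
    demographic separation (> es_bias) but minimal disease signal
    (< es_disease).
    """
    meta = meta.aligned_to(X_train)
    ctrl, _ = _control_groups(meta)
    if (~ctrl).sum() < 2:
        raise ValueError("need at least 2 case samples to assess disease signal")
    scores = project(X_train, basis.center, basis.directions)
    flags = []
    for j in range(basis.n_directions):
        bias_es_j, disease_es_j = _bias_and_disease_es(scores[:, j], meta, ctrl)
        flags.append(SubspaceFlag(
            index=j, bias_es=bias_es_j, disease_es=disease_es_j,
            flagged_biased=bool(bias_es_j > es_bias and disease_es_j < es_disease),
        ))
    return flags


def _leading_discriminant(S: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """First LDA discriminant direction in the coordinates of ``S``.

    Ledoit-Wolf shrinkage of the within-class covariance keeps the problem
    well-posed even when the working dimension approaches the group sizes.
    """
    levels = np.unique(labels)
    if S.shape[1] == 1:
        return np.array([1.0])
    if levels.size == 2:
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        lda.fit(S, labels)
        w = lda.coef_[0]
    else:
        lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage="auto")
        lda.fit(S, labels)
        w = lda.scalings_[:, 0]
    nrm = np.linalg.norm(w)
    if nrm == 0:  # identical class means; any direction is as good
        w = np.zeros(S.shape[1])
        w[0] = 1.0
        return w
    return w / nrm


def iterative_lda_refine(
    X_train: FeatureMatrix,
    meta: SampleMetadata,
    biased_dirs: np.ndarray,
    center: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Concentrate demographic bias by iterative LDA with deflation.

    Working in the coordinates of control-sample projections onto the
    flagged directions, repeatedly: fit LDA majority-vs-minority (leading
    discriminant for >2 groups), map the discriminant back to feature space,
    record its bias effect size, then deflate — restrict the working basis to
    the orthogonal complement of the found direction — and iterate until the
    span is exhausted.

    Returns ``(directions, effect_sizes)``: an ordered orthonormal set
    spanning exactly span(biased_dirs), with the control-group |d| (or f)
    of each direction's projections.
    """
    meta = meta.aligned_to(X_train)
    ctrl, groups = _control_groups(meta)
    B = np.asarray(biased_dirs, dtype=float)
    if B.ndim != 2 or B.shape[1] == 0:
        raise ValueError("need at least one biased direction")
    m = B.shape[1]
    S_full = project(X_train, center, B)[ctrl]      # controls in span coords
    R = np.eye(m)                                   # remaining-subspace basis
    dirs, es = [], []
    while R.shape[1] > 0:
        S = S_full @ R
        w = _leading_discriminant(S, groups)
        d_span = R @ w                              # unit in span coords
        d_span /= np.linalg.norm(d_span)
        dirs.append(B @ d_span)                     # unit in feature space
        es.append(group_effect_size(S_full @ d_span, groups).magnitude)
        if R.shape[1] == 1:
            break
        # deflation: orthonormal basis of the complement of d_span within R
        P = R - np.outer(d_span, d_span @ R)
        Uc, sc, _ = np.linalg.svd(P, full_matrices=False)
        R = Uc[:, sc > 1e-10 * max(sc[0], 1e-300)][:, : R.shape[1] - 1]
    out_dirs = _fix_signs(np.column_stack(dirs))
    return out_dirs, np.asarray(es)


def select_bias_directions(
    refined_dirs: np.ndarray,
    refined_es: np.ndarray,
    es_bias_prime: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Keep refined directions whose bias effect size exceeds the threshold,
    preserving LDA order.  All m refined directions are computed first and
    thresholded afterwards (LDA order does not guarantee monotone effect
    sizes)."""
    refined_es = np.asarray(refined_es, dtype=float)
    keep = refined_es > es_bias_prime
    return refined_dirs[:, keep], refined_es[keep]


def debias_fit(
    X_train: FeatureMatrix,
    meta: SampleMetadata,
    config: RunConfig | None = None,
) -> DebiasModel:
    """Fit the full model on training data: PCA on controls, dual-criterion
    flagging, iterative LDA refinement, effect-size selection."""
    config = config or RunConfig()
    meta = meta.aligned_to(X_train)
    basis = fit_pca_on_controls(X_train, meta, config.max_components)
    flags = flag_subspaces(basis, X_train, meta, config.es_bias, config.es_disease)
    flagged_idx = [f.index for f in flags if f.flagged_biased]
    p = len(X_train.feature_ids)
    if not flagged_idx:
        return DebiasModel(
            feature_ids=list(X_train.feature_ids), center=basis.center,
            bias_directions=np.empty((p, 0)),
            per_direction_bias_es=np.empty(0), pca_flags=flags,
            config_used=config,
            refined_directions=np.empty((p, 0)), refined_bias_es=np.empty(0),
        )
    refined, refined_es = iterative_lda_refine(
        X_train, meta, basis.directions[:, flagged_idx], basis.center)
    Vb, es = select_bias_directions(refined, refined_es, config.es_bias_prime)
    return DebiasModel(
        feature_ids=list(X_train.feature_ids), center=basis.center,
        bias_directions=Vb, per_direction_bias_es=es, pca_flags=flags,
        config_used=config, refined_directions=refined,
        refined_bias_es=refined_es,
    )


def debias_transform(
    model: DebiasModel,
    X: FeatureMatrix,
    centered: bool = True,
) -> FeatureMatrix:
    """Remove the projection onto the selected bias directions.

    With ``centered=True`` (default) the projector acts on the matrix after
    subtracting the training-control mean and the mean is added back:
    ``X_adj = X - (X - 1·centerᵀ) V_bias V_biasᵀ``, which keeps the output
    on the original scale and makes an empty model the exact identity.
    ``centered=False`` applies the raw form ``X - X V_bias V_biasᵀ``.
    """
    if list(X.feature_ids) != list(model.feature_ids):
        missing = set(model.feature_ids) - set(X.feature_ids)
        extra = set(X.feature_ids) - set(model.feature_ids)
        raise ValueError(
            f"feature mismatch: missing {sorted(missing)[:5]}, "
            f"extra {sorted(extra)[:5]}"
        )
    Vb = model.bias_directions
    if Vb.shape[1] == 0:
        return FeatureMatrix(list(X.sample_ids), list(X.feature_ids),
                             X.values.copy())
    base = X.values - model.center if centered else X.values
    adj = X.values - (base @ Vb) @ Vb.T
    return FeatureMatrix(list(X.sample_ids), list(X.feature_ids), adj)
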