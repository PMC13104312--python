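"""Measurement toolkit: biased-feature testing, disease-subspace
construction, redundancy-analysis signal-loss quantification, feature-impact
ranking, marker selection, and the linear-SVM detection stage with per-group
AUROC reporting."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import LinearSVC
from sklearn.calibration import CalibratedClassifierCV

from .core import DebiasModel, _fix_signs, _leading_discriminant, project
from .io import FeatureMatrix, RunConfig, SampleMetadata
from .stats import (
    auroc,
    bh_adjust,
    cohens_d,
    delong_ci,
    delong_compare,
    permutation_t_test,
    permutation_t_test_features,
)

__all__ = [
    "BiasedFeatureReport",
    "DiseaseSubspace",
    "SignalLossReport",
    "DetectionReport",
    "identify_biased_features",
    "disease_subspace",
    "variance_explained_by_bias",
    "feature_impact",
    "select_markers",
    "select_markers_multi",
    "log_transform",
    "train_detector",
    "score_samples",
    "evaluate_detection",
]


@dataclass
class BiasedFeatureReport:
    table: pd.DataFrame  # feature_id, effect_size, p_raw, p_adjusted, biased
    alpha: float

    @property
    def n_biased(self) -> int:
        return int(self.table["biased"].sum())

    @property
    def fraction_biased(self) -> float:
        return float(self.table["biased"].mean())


def identify_biased_features(
    X: FeatureMatrix,
    meta: SampleMetadata,
    config: RunConfig | None = None,
    alternative: str = "two_sided",
) -> BiasedFeatureReport:
    """Per-feature demographic bias among controls.

    For each feature: |Cohen's d| between minority and majority controls, a
    seeded permutation Welch-t p-value, BH adjustment across all features,
    and a biased flag at ``alpha_features``.  Constant features in both
    groups get d = 0, p = 1 by convention.
    """
    config = config or RunConfig()
    meta = meta.aligned_to(X)
    ctrl = meta.is_control
    groups = meta.group[ctrl]
    levels, counts = np.unique(groups, return_counts=True)
    if levels.size != 2:
        raise ValueError("feature-level bias testing expects exactly 2 groups")
    if counts.min() < 2:
        raise ValueError("need >= 2 controls per group")
    maj = meta.majority if meta.majority in levels else levels[0]
    mino = [lv for lv in levels if lv != maj][0]
    Xc = X.values[ctrl]
    Xa = Xc[groups == mino]
    Xb = Xc[groups == maj]
    t_obs, p = permutation_t_test_features(
        Xa, Xb, alternative=alternative, n_perm=config.n_permutations,
        seed=config.seed)
    # effect sizes, vectorized pooled-SD Cohen's d
    na, nb = Xa.shape[0], Xb.shape[0]
    pooled = np.sqrt(((na - 1) * Xa.var(axis=0, ddof=1)
                      + (nb - 1) * Xb.var(axis=0, ddof=1)) / (na + nb - 2))
    diff = Xa.mean(axis=0) - Xb.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = diff / pooled
    d = np.where(pooled == 0.0, 0.0, d)
    p = np.where((pooled == 0.0) & (diff == 0.0), 1.0, p)
    adj = bh_adjust(p)
    table = pd.DataFrame({
        "feature_id": X.feature_ids,
        "effect_size": np.abs(d),
        "p_raw": p,
        "p_adjusted": adj,
        "biased": adj < config.alpha_features,
    })
    return BiasedFeatureReport(table, config.alpha_features)


@dataclass
class DiseaseSubspace:
    directions: np.ndarray          # (n_features, <=N), orthonormal
    effect_sizes: np.ndarray        # case/control |d| per direction


def disease_subspace(
    X_train: FeatureMatrix,
    meta: SampleMetadata,
    N: int = 50,
) -> DiseaseSubspace:
    """Greedy disease-specific subspace by iterative LDA with deflation.

    Works in a rank-limited PCA coordinate system of the training matrix
    (top samples-2 components) so LDA is well-posed in ambient dimensions
    far larger than the cohort, then maps each discriminant back to feature
    space, orthogonalizes against its predecessors, and deflates.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    meta = meta.aligned_to(X_train)
    y = np.where(meta.is_control, "control", "case")
    if np.unique(y).size != 2:
        raise ValueError("need both case and control samples")
    Xv = X_train.values
    center = Xv.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xv - center, full_matrices=False)
    keep = s > 1e-10 * s[0]
    rank = min(int(keep.sum()), Xv.shape[0] - 2)
    V = Vt[:rank].T                                # (p, rank) working basis
    if N > rank:
        warnings.warn(f"requested {N} dimensions but rank allows {rank}; "
                      "truncating")
        N = rank
    S_full = (Xv - center) @ V                     # samples in working coords
    R = np.eye(rank)
    dirs, es = [], []
    for _ in range(N):
        S = S_full @ R
        w = _leading_discriminant(S, y)
        d_span = R @ w
        d_span /= np.linalg.norm(d_span)
        dirs.append(V @ d_span)
        scores = S_full @ d_span
        es.append(abs(cohens_d(scores[y == "case"],
                               scores[y == "control"]).value))
        if R.shape[1] == 1:
            break
        P = R - np.outer(d_span, d_span @ R)
        Uc, sc, _ = np.linalg.svd(P, full_matrices=False)
        R = Uc[:, sc > 1e-10 * max(sc[0], 1e-300)][:, : R.shape[1] - 1]
    return DiseaseSubspace(_fix_signs(np.column_stack(dirs)), np.asarray(es))


@dataclass
class SignalLossReport:
    adjusted_r2: np.ndarray   # per dimension count 1..N (NaN where undefined)

    @property
    def mean_adjusted_r2(self) -> float:
        return float(np.nanmean(self.adjusted_r2))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n_dims": np.arange(1, len(self.adjusted_r2) + 1),
                             "adjusted_r2": self.adjusted_r2})


def _rda_adjusted_r2(Y: np.ndarray, Z: np.ndarray) -> float:
    """Redundancy-analysis adjusted R²: multivariate OLS of response block Y
    on predictor block Z (both column-centered), Ezekiel-corrected."""
    s = Y.shape[0]
    k = Z.shape[1]
    if s <= k + 1:
        return float("nan")
    Yc = Y - Y.mean(axis=0)
    Zc = Z - Z.mean(axis=0)
    tot = float((Yc ** 2).sum())
    if tot == 0.0:
        return float("nan")
    coef, *_ = np.linalg.lstsq(Zc, Yc, rcond=None)
    expl = float(((Zc @ coef) ** 2).sum())
    r2 = expl / tot
    return 1.0 - (1.0 - r2) * (s - 1) / (s - k - 1)


def variance_explained_by_bias(
    disease: DiseaseSubspace,
    model: DebiasModel,
    X: FeatureMatrix,
    N: Optional[int] = None,
) -> SignalLossReport:
    """Proportion of variance in the first n disease-subspace coordinates
    explained by the bias-subspace coordinates, for n = 1..N (redundancy
    analysis, Ezekiel-adjusted).  An empty bias subspace explains nothing."""
    N = disease.directions.shape[1] if N is None else min(
        N, disease.directions.shape[1])
    Y_all = project(X, model.center, disease.directions[:, :N])
    if model.n_selected == 0:
        return SignalLossReport(np.zeros(N))
    Z = project(X, model.center, model.bias_directions)
    out = np.array([_rda_adjusted_r2(Y_all[:, : n + 1], Z) for n in range(N)])
    return SignalLossReport(out)


def feature_impact(
    X_before: FeatureMatrix,
    X_after: FeatureMatrix,
    meta: SampleMetadata,
    impact_quantile: float = 0.25,
) -> list[str]:
    """Features whose control-sample variance changed most, relatively.

    Per feature: |var_after - var_before| / var_before over controls; the
    top ``impact_quantile`` fraction is returned (ties broken by feature ID
    order).  Zero-variance features are excluded with a warning.
    """
    if X_before.shape != X_after.shape or \
            list(X_before.feature_ids) != list(X_after.feature_ids):
        raise ValueError("matrices must share shape and feature IDs")
    meta = meta.aligned_to(X_before)
    ctrl = meta.is_control
    vb = X_before.values[ctrl].var(axis=0, ddof=1)
    va = X_after.values[ctrl].var(axis=0, ddof=1)
    ok = vb > 0
    if not ok.all():
        warnings.warn(f"excluding {int((~ok).sum())} zero-variance feature(s)")
    rel = np.abs(va[ok] - vb[ok]) / vb[ok]
    ids = np.asarray(X_before.feature_ids)[ok]
    n_top = int(round(impact_quantile * ids.size))
    if np.allclose(rel, 0.0):
        warnings.warn("no variance change anywhere; impact set is degenerate")
    order = np.lexsort((ids, -rel))  # impact descending, then ID ascending
    return list(ids[order][:n_top])


def select_markers(
    diff_matrix: np.ndarray | pd.DataFrame,
    feature_ids: Optional[Sequence[str]] = None,
    top_k: int = 5000,
) -> list[str]:
    """Rank regions by mean tumor-minus-normal difference, descending, and
    return the top ``top_k`` region IDs."""
    if isinstance(diff_matrix, pd.DataFrame):
        feature_ids = list(map(str, diff_matrix.columns))
        vals = diff_matrix.to_numpy(dtype=float)
    else:
        vals = np.atleast_2d(np.asarray(diff_matrix, dtype=float))
        if feature_ids is None:
            feature_ids = [str(j) for j in range(vals.shape[1])]
    if vals.shape[0] < 1:
        raise ValueError("need at least one tumor-normal difference row")
    if top_k > vals.shape[1]:
        warnings.warn(f"top_k={top_k} exceeds {vals.shape[1]} regions; "
                      "returning all")
        top_k = vals.shape[1]
    means = vals.mean(axis=0)
    ids = np.asarray(list(feature_ids))
    order = np.lexsort((ids, -means))
    return list(ids[order][:top_k])


def select_markers_multi(
    diff_matrices: dict[str, np.ndarray | pd.DataFrame],
    feature_ids: Optional[Sequence[str]] = None,
    top_k: int = 5000,
) -> list[str]:
    """Pan-disease markers: the union of per-type top lists, first-seen
    order preserved."""
    seen: dict[str, None] = {}
    for _, dm in diff_matrices.items():
        for f in select_markers(dm, feature_ids, top_k):
            seen.setdefault(f)
    return list(seen)


def log_transform(X: FeatureMatrix) -> FeatureMatrix:
    """Elementwise log(1 + 1000·x); raises when the argument is nonpositive
    (bias adjustment can create negative values — clip upstream)."""
    arg = 1.0 + 1000.0 * X.values
    if (arg <= 0).any():
        bad = np.argwhere(arg <= 0)[:5]
        cells = [(X.sample_ids[i], X.feature_ids[j]) for i, j in bad]
        raise ValueError(f"log transform undefined at cell(s) {cells}")
    return FeatureMatrix(list(X.sample_ids), list(X.feature_ids), np.log(arg))


@dataclass
class Detector:
    """Fitted linear-SVM scorer with its preprocessing contract."""

    svm: LinearSVC
    marker_ids: list[str]
    clip_negative: bool
    calibrated: Optional[CalibratedClassifierCV] = None


def _preprocess(X: FeatureMatrix, marker_ids: list[str],
                clip_negative: bool) -> np.ndarray:
    sub = X.subset_features(marker_ids)
    vals = np.maximum(sub.values, 0.0) if clip_negative else sub.values
    return log_transform(FeatureMatrix(sub.sample_ids, sub.feature_ids,
                                       vals)).values


def train_detector(
    X_train: FeatureMatrix,
    meta: SampleMetadata,
    marker_ids: Sequence[str],
    config: RunConfig | None = None,
    clip_negative: bool = True,
    probability: bool = False,
) -> Detector:
    """Linear SVM (L2 penalty, C from config) on log-transformed marker
    features.  Identical preprocessing is applied at training and scoring
    time.  ``probability=True`` additionally fits a Platt-calibrated copy."""
    config = config or RunConfig()
    meta = meta.aligned_to(X_train)
    y = (~meta.is_control).astype(int)
    if np.unique(y).size != 2:
        raise ValueError("training data must contain both classes")
    Z = _preprocess(X_train, list(marker_ids), clip_negative)
    svm = LinearSVC(C=config.svm_C, penalty="l2", dual="auto",
                    random_state=config.seed)
    svm.fit(Z, y)
    calibrated = None
    if probability:
        calibrated = CalibratedClassifierCV(
            LinearSVC(C=config.svm_C, penalty="l2", dual="auto",
                      random_state=config.seed), method="sigmoid", cv=3)
        calibrated.fit(Z, y)
    return Detector(svm, list(marker_ids), clip_negative, calibrated)


def score_samples(detector: Detector, X: FeatureMatrix,
                  kind: str = "margin") -> np.ndarray:
    """Per-sample cancer-like score: signed SVM margin (default, AUROC-rank
    equivalent to a probability) or Platt probability when available."""
    Z = _preprocess(X, detector.marker_ids, detector.clip_negative)
    if kind == "margin":
        return detector.svm.decision_function(Z)
    if kind == "probability":
        if detector.calibrated is None:
            raise ValueError("detector was trained without probability=True")
        return detector.calibrated.predict_proba(Z)[:, 1]
    raise ValueError(f"unknown score kind {kind!r}")


@dataclass
class DetectionReport:
    scores: np.ndarray
    overall: dict
    per_group: dict[str, dict]
    healthy_score_test: Optional[dict] = None
    baseline_comparison: Optional[dict] = None

    def to_summary(self) -> dict:
        out = {"auroc_overall": self.overall["auroc"],
               "auroc_overall_ci_lo": self.overall["ci"][0],
               "auroc_overall_ci_hi": self.overall["ci"][1]}
        for g, r in self.per_group.items():
            out[f"auroc_{g}"] = r["auroc"]
            if r["auroc"] is not None:
                out[f"auroc_{g}_ci_lo"] = r["ci"][0]
                out[f"auroc_{g}_ci_hi"] = r["ci"][1]
        if self.healthy_score_test is not None:
            out["healthy_score_perm_p"] = self.healthy_score_test["p_value"]
        if self.baseline_comparison is not None:
            out["delong_one_sided_p"] = self.baseline_comparison["p_value"]
        return out


def evaluate_detection(
    scores: Sequence[float],
    meta: SampleMetadata,
    baseline_scores: Optional[Sequence[float]] = None,
    n_permutations: int = 19_999,
    seed: int = 0,
) -> DetectionReport:
    """Overall and per-demographic-group AUROC with DeLong CIs, a one-sided
    permutation-t comparison of healthy-group score distributions
    (majority > minority, the direction in which training imbalance inflates
    majority scores), and optionally a one-sided DeLong test of these scores
    against a baseline score vector on the same samples."""
    s = np.asarray(scores, dtype=float)
    y = (~meta.is_control).astype(int)
    auc, lo, hi = delong_ci(s, y)
    overall = {"auroc": auc, "ci": (lo, hi)}
    per_group: dict[str, dict] = {}
    for g in np.unique(meta.group):
        m = meta.group == g
        if np.unique(y[m]).size < 2:
            per_group[str(g)] = {"auroc": None, "ci": None,
                                 "note": "group lacks both classes"}
            continue
        a, l2, h2 = delong_ci(s[m], y[m])
        per_group[str(g)] = {"auroc": a, "ci": (l2, h2)}
    healthy = None
    ctrl = meta.is_control
    glv = np.unique(meta.group[ctrl])
    if glv.size == 2:
        maj = meta.majority if meta.majority in glv else glv[0]
        mino = [g for g in glv if g != maj][0]
        x = s[ctrl & (meta.group == maj)]
        yv = s[ctrl & (meta.group == mino)]
        if x.size >= 2 and yv.size >= 2:
            res = permutation_t_test(x, yv, alternative="greater",
                                     n_perm=n_permutations, seed=seed)
            healthy = {"statistic": res.statistic, "p_value": res.p_value,
                       "majority": str(maj), "minority": str(mino)}
    baseline = None
    if baseline_scores is not None:
        res = delong_compare(s, np.asarray(baseline_scores, dtype=float), y,
                             alternative="greater")
        baseline = {"statistic": res.statistic, "p_value": res.p_value}
    return DetectionReport(s, overall, per_group, healthy, baseline)
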