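"""End-to-end experiment: stratified cross-validation with an unadjusted arm
and a bias-adjusted arm, leakage-safe fitting on training folds only, and a
before/after report bundle (per-fold and pooled)."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .core import DebiasModel, debias_fit, debias_transform
from .evaluation import (
    DetectionReport,
    disease_subspace,
    evaluate_detection,
    identify_biased_features,
    select_markers,
    score_samples,
    train_detector,
    variance_explained_by_bias,
)
from .io import FeatureMatrix, RunConfig, SampleMetadata
from .stats import delong_compare

logger = logging.getLogger("fairspace")

__all__ = ["ExperimentReport", "run_experiment", "stratified_folds"]


def stratified_folds(meta: SampleMetadata, n_folds: int = 3,
                     seed: int = 0) -> np.ndarray:
    """Fold assignment preserving class x demographic-group proportions.

    Honors an explicit ``fold`` column in the metadata when present.
    """
    t = meta.table
    if "fold" in t.columns and t["fold"].notna().all():
        return t["fold"].to_numpy(dtype=int)
    strata = np.char.add(np.char.add(meta.group.astype(str), "|"),
                         meta.disease.astype(str))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = np.empty(len(t), dtype=int)
    for i, (_, test_idx) in enumerate(skf.split(np.zeros(len(t)), strata)):
        folds[test_idx] = i + 1
    return folds


@dataclass
class ExperimentReport:
    """Per-fold and pooled results for both arms.

    ``fold_table`` has one row per (fold, arm); ``pooled_table`` one row per
    arm, where the pooled AUROC is computed on the concatenated test scores
    of all folds (not the mean of fold AUROCs).
    """

    fold_table: pd.DataFrame
    pooled_table: pd.DataFrame
    models: dict[int, DebiasModel]
    pooled_scores: dict[str, np.ndarray]
    pooled_meta: SampleMetadata

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.fold_table.to_csv(outdir / "folds.tsv", sep="\t", index=False)
        self.pooled_table.to_csv(outdir / "pooled.tsv", sep="\t", index=False)


def _arm_metrics(report: DetectionReport, meta: SampleMetadata,
                 majority: str) -> dict:
    out = {"auroc_overall": report.overall["auroc"]}
    for g, r in report.per_group.items():
        key = "majority" if g == majority else "minority"
        out[f"auroc_{key}"] = r["auroc"]
    if report.healthy_score_test is not None:
        out["healthy_score_perm_p"] = report.healthy_score_test["p_value"]
    return out


def run_experiment(
    X: FeatureMatrix,
    meta: SampleMetadata,
    diff_matrix: np.ndarray | pd.DataFrame,
    config: RunConfig | None = None,
    n_folds: int = 3,
    compute_biased_features: bool = True,
    compute_signal_loss: bool = True,
) -> ExperimentReport:
    """Cross-validated before/after comparison.

    Per fold: fit the bias-removal model on the training fold only,
    transform both folds, train one detector per arm on the training fold,
    score the test fold; biased-feature counts and redundancy-analysis
    signal loss are reported per fold.  Test scores are pooled across folds
    for the overall rows.  Folds lacking a class x group stratum are skipped
    with a warning.
    """
    config = config or RunConfig()
    meta = meta.aligned_to(X)
    folds = stratified_folds(meta, n_folds=n_folds, seed=config.seed)
    markers = select_markers(diff_matrix, feature_ids=X.feature_ids,
                             top_k=min(config.top_k_markers, X.shape[1]))
    majority = meta.majority
    rows = []
    models: dict[int, DebiasModel] = {}
    pooled_scores = {"unadjusted": [], "adjusted": []}
    pooled_idx: list[np.ndarray] = []
    for fold in sorted(set(folds)):
        test_mask = folds == fold
        train_mask = ~test_mask
        m_tr = meta.subset(train_mask)
        strata = pd.crosstab(m_tr.group, m_tr.disease)
        if (strata.to_numpy() < 2).any():
            warnings.warn(f"fold {fold}: a training stratum has < 2 samples; "
                          "skipping fold")
            continue
        X_tr = FeatureMatrix([X.sample_ids[i] for i in np.where(train_mask)[0]],
                             list(X.feature_ids), X.values[train_mask])
        X_te = FeatureMatrix([X.sample_ids[i] for i in np.where(test_mask)[0]],
                             list(X.feature_ids), X.values[test_mask])
        m_te = meta.subset(test_mask)
        model = debias_fit(X_tr, m_tr, config)
        models[int(fold)] = model
        logger.info("fold %s: selected bias dimension k=%d (of %d flagged)",
                    fold, model.n_selected,
                    sum(f.flagged_biased for f in model.pca_flags))
        arms = {
            "unadjusted": (X_tr, X_te),
            "adjusted": (debias_transform(model, X_tr),
                         debias_transform(model, X_te)),
        }
        for arm, (A_tr, A_te) in arms.items():
            det = train_detector(A_tr, m_tr, markers, config)
            s_te = score_samples(det, A_te)
            rep = evaluate_detection(
                s_te, m_te, n_permutations=min(config.n_permutations, 1999),
                seed=config.seed)
            row = {"fold": int(fold), "arm": arm, "k_selected": model.n_selected}
            row.update(_arm_metrics(rep, m_te, majority))
            if compute_biased_features:
                bf = identify_biased_features(A_tr, m_tr, config)
                row["n_biased_features"] = bf.n_biased
                row["fraction_biased"] = bf.fraction_biased
            if compute_signal_loss and arm == "unadjusted":
                ds = disease_subspace(X_tr, m_tr,
                                      N=config.disease_subspace_dims)
                sl = variance_explained_by_bias(ds, model, X_tr)
                row["mean_adjusted_r2"] = sl.mean_adjusted_r2
            rows.append(row)
            pooled_scores[arm].append(s_te)
        pooled_idx.append(np.where(test_mask)[0])
    if not rows:
        raise ValueError("no usable folds")
    fold_table = pd.DataFrame(rows)
    order = np.concatenate(pooled_idx)
    pooled_meta = meta.subset(np.isin(np.arange(len(folds)), order))
    # re-order pooled metadata to concatenation order
    pooled_meta = SampleMetadata(
        meta.table.iloc[order].reset_index(drop=True),
        meta.control_label, meta.majority)
    pooled_rows = []
    pooled_vectors: dict[str, np.ndarray] = {}
    for arm in ("unadjusted", "adjusted"):
        s_all = np.concatenate(pooled_scores[arm])
        pooled_vectors[arm] = s_all
        rep = evaluate_detection(s_all, pooled_meta,
                                 n_permutations=min(config.n_permutations, 1999),
                                 seed=config.seed)
        row = {"arm": arm}
        row.update(_arm_metrics(rep, pooled_meta, majority))
        pooled_rows.append(row)
    # one-sided DeLong: adjusted > unadjusted on pooled minority samples
    min_mask = pooled_meta.group != majority
    y_min = (~pooled_meta.is_control).astype(int)[min_mask]
    pooled_table = pd.DataFrame(pooled_rows)
    if np.unique(y_min).size == 2:
        try:
            cmp = delong_compare(pooled_vectors["adjusted"][min_mask],
                                 pooled_vectors["unadjusted"][min_mask],
                                 y_min)
            pooled_table["delong_minority_adj_gt_unadj_p"] = cmp.p_value
        except Exception:
            pooled_table["delong_minority_adj_gt_unadj_p"] = np.nan
    return ExperimentReport(fold_table, pooled_table, models, pooled_vectors,
                            pooled_meta)
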