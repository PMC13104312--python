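"""Statistical primitives: effect sizes, permutation tests, FDR, AUROC.

Every function here is pure and, where randomness is involved, seed-explicit.
These are the building blocks the subspace-removal core and the evaluation
harness call; they are deliberately free of any pipeline state.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DegenerateVarianceError",
    "EffectSize",
    "TestResult",
    "cohens_d",
    "cohens_f",
    "group_effect_size",
    "permutation_t_test",
    "permutation_t_test_features",
    "welch_t",
    "bh_adjust",
    "auroc",
    "delong_ci",
    "delong_compare",
]

Alternative = Literal["two_sided", "greater", "less"]


class DegenerateVarianceError(ValueError):
    """Raised when an effect size or test is undefined because all variance
    in the relevant stratum is zero while the means differ."""


@dataclass(frozen=True)
class EffectSize:
    """A standardized effect size.

    ``cohens_d`` is signed (first group minus second over pooled SD);
    ``cohens_f`` is nonnegative by construction.  Thresholding code always
    compares ``abs(value)`` because the orientation of a subspace direction
    is arbitrary.
    """

    value: float
    kind: Literal["cohens_d", "cohens_f"]

    def __post_init__(self) -> None:
        if self.kind == "cohens_f" and self.value < 0:
            raise ValueError("Cohen's f must be nonnegative")

    @property
    def magnitude(self) -> float:
        return abs(self.value)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n_permutations_used: int
    alternative: Alternative


def _as_vec(x: Sequence[float]) -> np.ndarray:
    v = np.asarray(x, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("each group needs at least 2 observations")
    return v


def cohens_d(x: Sequence[float], y: Sequence[float]) -> EffectSize:
    """Standardized mean difference (mean(x) - mean(y)) / pooled SD.

    Pooled SD uses (n-1) sample variances.  If both groups are constant and
    equal the difference is exactly zero and d = 0 is returned; constant
    groups with unequal means have an undefined d and raise
    :class:`DegenerateVarianceError`.
    """
    xv, yv = _as_vec(x), _as_vec(y)
    nx, ny = xv.size, yv.size
    pooled_var = ((nx - 1) * xv.var(ddof=1) + (ny - 1) * yv.var(ddof=1)) / (nx + ny - 2)
    diff = xv.mean() - yv.mean()
    if pooled_var == 0.0:
        if diff == 0.0:
            return EffectSize(0.0, "cohens_d")
        raise DegenerateVarianceError("zero pooled variance with unequal means")
    return EffectSize(float(diff / math.sqrt(pooled_var)), "cohens_d")


def cohens_f(groups: Sequence[Sequence[float]]) -> EffectSize:
    """Multi-group effect size: between-group SD over within-group SD.

    The between-group SD weights each group mean by its size and divides by
    the total N (population convention); the within-group SD is the pooled
    (n-1)-based SD.  For two equal-size groups this reduces to ``|d| / 2``.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    vecs = [_as_vec(g) for g in groups]
    ns = np.array([v.size for v in vecs])
    N = int(ns.sum())
    means = np.array([v.mean() for v in vecs])
    grand = float(np.sum(ns * means) / N)
    sigma_means = math.sqrt(float(np.sum(ns * (means - grand) ** 2) / N))
    pooled_var = float(
        sum((v.size - 1) * v.var(ddof=1) for v in vecs) / (N - len(vecs))
    )
    if pooled_var == 0.0:
        if sigma_means == 0.0:
            return EffectSize(0.0, "cohens_f")
        raise DegenerateVarianceError("zero within-group variance with unequal means")
    return EffectSize(sigma_means / math.sqrt(pooled_var), "cohens_f")


def group_effect_size(values: np.ndarray, labels: np.ndarray) -> EffectSize:
    """Dispatch to |Cohen's d| semantics for 2 groups, Cohen's f for more.

    ``labels`` are categorical; the returned object is signed d when there
    are exactly two groups (ordered by label sort order) and f otherwise.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    levels = np.unique(labels)
    if levels.size < 2:
        raise ValueError("need at least 2 groups")
    groups = [values[labels == lv] for lv in levels]
    if levels.size == 2:
        return cohens_d(groups[0], groups[1])
    return cohens_f(groups)


def welch_t(x: np.ndarray, y: np.ndarray) -> float:
    """Welch's t statistic; ±inf for constant-but-unequal groups, 0 when
    both groups are constant and equal."""
    nx, ny = x.size, y.size
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    diff = x.mean() - y.mean()
    denom = math.sqrt(vx / nx + vy / ny)
    if denom == 0.0:
        return 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    return float(diff / denom)


def permutation_t_test(
    x: Sequence[float],
    y: Sequence[float],
    alternative: Alternative = "two_sided",
    n_perm: int = 19_999,
    seed: int = 0,
) -> TestResult:
    """Permutation test on Welch's t statistic.

    The group labels are permuted jointly over the pooled sample.  When the
    number of distinct assignments C(n, nx) is at most ``n_perm`` the null is
    enumerated exhaustively and the p-value is exact (the observed assignment
    counts itself, so p >= 1/total); otherwise ``n_perm`` random permutations
    are drawn with a seeded generator and the add-one convention
    p = (1 + b) / (1 + B) applies, giving a floor of 1/(B+1).
    """
    if alternative not in ("two_sided", "greater", "less"):
        raise ValueError(f"unknown alternative: {alternative!r}")
    xv, yv = _as_vec(x), _as_vec(y)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pooled = np.concatenate([xv, yv])
    nx = xv.size
    t_obs = welch_t(xv, yv)

    def extreme(t_perm: float) -> bool:
        if alternative == "two_sided":
            return abs(t_perm) >= abs(t_obs) - 1e-12
        if alternative == "greater":
            return t_perm >= t_obs - 1e-12
        return t_perm <= t_obs + 1e-12

    n_total = pooled.size
    n_exact = math.comb(n_total, nx)
    if n_exact <= n_perm:
        hits = 0
        idx_all = np.arange(n_total)
        for comb in itertools.combinations(range(n_total), nx):
            mask = np.zeros(n_total, dtype=bool)
            mask[list(comb)] = True
            if extreme(welch_t(pooled[mask], pooled[~mask])):
                hits += 1
        del idx_all
        return TestResult(t_obs, hits / n_exact, n_exact, alternative)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n_total)
        if extreme(welch_t(pooled[perm[:nx]], pooled[perm[nx:]])):
            hits += 1
    return TestResult(t_obs, (1 + hits) / (1 + n_perm), n_perm, alternative)


def permutation_t_test_features(
    x: np.ndarray,
    y: np.ndarray,
    alternative: Alternative = "two_sided",
    n_perm: int = 19_999,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized permutation Welch-t test applied column-wise.

    ``x`` (n1 x p) and ``y`` (n2 x p) hold the two groups over the same p
    features.  All features share the same label permutations, which is both
    cheaper and preserves inter-feature dependence in the joint null.  Uses
    the add-one convention p = (1 + b)/(1 + B) per feature.

    Returns ``(t_obs, p)`` arrays of length p.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[1] != y.shape[1]:
        raise ValueError("groups must share features")
    n1, n2 = x.shape[0], y.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.vstack([x, y])
    n = n1 + n2

    def t_cols(mask: np.ndarray) -> np.ndarray:
        # mask: (B, n) boolean, True = group-1 membership
        b = mask.shape[0]
        maskf = mask.astype(float)
        s1 = maskf @ pooled
        s2 = (1.0 - maskf) @ pooled
        q1 = maskf @ (pooled ** 2)
        q2 = (1.0 - maskf) @ (pooled ** 2)
        m1, m2 = s1 / n1, s2 / n2
        v1 = np.maximum(q1 - n1 * m1 ** 2, 0.0) / (n1 - 1)
        v2 = np.maximum(q2 - n2 * m2 ** 2, 0.0) / (n2 - 1)
        denom = np.sqrt(v1 / n1 + v2 / n2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (m1 - m2) / denom
        diff = m1 - m2
        degen = denom == 0.0
        if degen.any():
            with np.errstate(invalid="ignore"):
                t[degen] = np.where(diff[degen] == 0.0, 0.0,
                                    np.sign(diff[degen]) * np.inf)
        return t.reshape(b, -1)

    obs_mask = np.zeros((1, n), dtype=bool)
    obs_mask[0, :n1] = True
    t_obs = t_cols(obs_mask)[0]

    rng = np.random.default_rng(seed)
    hits = np.zeros(pooled.shape[1], dtype=np.int64)
    # batch permutations to bound memory at ~batch x p floats
    batch = max(1, min(n_perm, int(2e7 // max(pooled.shape[1], 1))))
    done = 0
    tol = 1e-12
    while done < n_perm:
        b = min(batch, n_perm - done)
        masks = np.zeros((b, n), dtype=bool)
        for i in range(b):
            masks[i, rng.permutation(n)[:n1]] = True
        t_perm = t_cols(masks)
        if alternative == "two_sided":
            hits += (np.abs(t_perm) >= np.abs(t_obs)[None, :] - tol).sum(axis=0)
        elif alternative == "greater":
            hits += (t_perm >= t_obs[None, :] - tol).sum(axis=0)
        else:
            hits += (t_perm <= t_obs[None, :] + tol).sum(axis=0)
        done += b
    p = (1 + hits) / (1 + n_perm)
    return t_obs, p


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1, in the
    input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (Mann-Whitney form; ties count 1/2).

    ``labels`` are binary with 1 = positive class; both classes must be
    present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    if np.unique(y).size != 2:
        raise ValueError("labels must contain both classes")
    pos = s[y == 1]
    neg = s[y == 0]
    # midrank formulation, equivalent to pairwise counting with half-ties
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    return float((ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2)
                 / (pos.size * neg.size))


def _delong_placements(scores: np.ndarray, labels: np.ndarray):
    """Midrank placement values V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    allv = np.concatenate([pos, neg])
    r_all = sps.rankdata(allv)
    r_pos = sps.rankdata(pos)
    r_neg = sps.rankdata(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    return float(auc), v10, v01


def delong_ci(
    scores: Sequence[float], labels: Sequence[int], level: float = 0.95
) -> tuple[float, float, float]:
    """AUROC with DeLong Wald confidence interval clipped to [0, 1].

    Returns ``(auc, lo, hi)``.  A degenerate (zero) variance estimate —
    e.g. perfect separation — yields a zero-width interval at the point
    estimate.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if np.unique(y).size != 2:
        raise ValueError("labels must contain both classes")
    auc, v10, v01 = _delong_placements(s, y)
    var = v10.var(ddof=1) / v10.size + v01.var(ddof=1) / v01.size
    z = sps.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(max(var, 0.0))
    return auc, float(np.clip(auc - half, 0.0, 1.0)), float(np.clip(auc + half, 0.0, 1.0))


def delong_compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[int],
    alternative: Literal["greater"] = "greater",
) -> TestResult:
    """DeLong paired comparison of two AUROCs on the same samples.

    One-sided p for AUROC_a > AUROC_b under the asymptotic normal null.
    Identical score vectors give p = 0.5; a zero variance of the difference
    with unequal AUROCs raises :class:`DegenerateVarianceError`.
    """
    if alternative != "greater":
        raise ValueError("only alternative='greater' is supported")
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(int)
    if sa.shape != sb.shape or sa.shape != y.shape:
        raise ValueError("paired scores must align with labels")
    if np.unique(y).size != 2:
        raise ValueError("labels must contain both classes")
    auc_a, v10_a, v01_a = _delong_placements(sa, y)
    auc_b, v10_b, v01_b = _delong_placements(sb, y)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0:
        if diff == 0.0:
            return TestResult(0.0, 0.5, 0, "greater")
        raise DegenerateVarianceError("zero variance of AUROC difference")
    z = diff / math.sqrt(var_diff)
    return TestResult(float(z), float(sps.norm.sf(z)), 0, "greater")
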