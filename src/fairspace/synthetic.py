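"""Synthetic demographically confounded cohorts with known planted structure.

The generator emulates the structure of imbalanced case-control cohorts in
which a minority demographic group is under-represented overall and its
cases are rarer still: a low-dimensional demographic-bias subspace shifts
every minority sample (bias is a property of the person, not the disease),
a separate low-dimensional disease subspace shifts every case, and the rest
is feature-wise Gaussian noise.  Because the planted bases are returned,
every downstream operation has a ground-truth oracle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io import FeatureMatrix, SampleMetadata
import pandas as pd

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate_cohort",
           "generate_tissue_differences"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Cohort recipe.

    Default cell sizes (majority 300 control / 300 case; minority 150
    control / 15 case) emulate the heavy demographic imbalance and unequal
    case:control ratio typical of real biobank cohorts.  Effect sizes are on
    the Cohen's-d scale of the generating direction: a planted direction with
    ``bias_effect_sizes[j] = 0.8`` shifts minority samples by
    ``0.8 * noise_sd`` along that (unit) direction.  ``overlap_angle`` is the
    principal angle in degrees between the bias span and the disease span
    (90 = orthogonal, 0 = coincident).
    """

    n_majority_control: int = 300
    n_majority_case: int = 300
    n_minority_control: int = 150
    n_minority_case: int = 15
    n_features: int = 2000
    bias_dims: int = 3
    bias_effect_sizes: tuple[float, ...] = (0.8, 0.8, 0.8)
    disease_dims: int = 5
    disease_effect_sizes: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0)
    overlap_angle: float = 90.0
    noise_sd: float = 1.0
    baseline: float = 0.0
    seed: int = 0
    lognormal_counts: bool = False
    bias_basis: Optional[np.ndarray] = None     # optional explicit bases
    disease_basis: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if len(self.bias_effect_sizes) != self.bias_dims:
            raise ValueError("bias_effect_sizes length must equal bias_dims")
        if len(self.disease_effect_sizes) != self.disease_dims:
            raise ValueError("disease_effect_sizes length must equal disease_dims")
        if min(self.n_majority_control, self.n_majority_case,
               self.n_minority_control, self.n_minority_case) < 0:
            raise ValueError("cell sizes must be >= 0")
        if self.bias_dims + self.disease_dims > self.n_features:
            raise ValueError("planted dimensions exceed n_features")
        if not 0.0 <= self.overlap_angle <= 90.0:
            raise ValueError("overlap_angle must lie in [0, 90] degrees")

    def replace(self, **kw) -> "SyntheticSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class SyntheticTruth:
    """Planted orthonormal bases and the spec that produced them."""

    bias_basis: np.ndarray      # (n_features, bias_dims)
    disease_basis: np.ndarray   # (n_features, disease_dims)
    spec: SyntheticSpec


def _random_orthonormal(rng: np.random.Generator, p: int, k: int) -> np.ndarray:
    A = rng.normal(size=(p, k))
    Q, _ = np.linalg.qr(A)
    return Q[:, :k]


def _make_bases(spec: SyntheticSpec, rng: np.random.Generator):
    if spec.bias_basis is not None or spec.disease_basis is not None:
        B = np.asarray(spec.bias_basis, dtype=float)
        U = np.asarray(spec.disease_basis, dtype=float)
        return B, U
    b, d = spec.bias_dims, spec.disease_dims
    theta = np.deg2rad(spec.overlap_angle)
    # joint frame: b bias columns, d "companion" columns, all orthonormal
    frame = _random_orthonormal(rng, spec.n_features, b + d)
    B = frame[:, :b]
    W = frame[:, b:]
    U = np.empty((spec.n_features, d))
    # pair the first min(b, d) disease directions with bias directions at the
    # prescribed principal angle; any remaining are orthogonal to the bias span
    for l in range(d):
        if l < b:
            U[:, l] = np.cos(theta) * B[:, l] + np.sin(theta) * W[:, l]
        else:
            U[:, l] = W[:, l]
    return B, U


def generate_cohort(spec: SyntheticSpec) -> tuple[FeatureMatrix, SampleMetadata,
                                                  SyntheticTruth]:
    """Draw a cohort: X = baseline + bias shifts + disease shifts + noise.

    Minority membership adds ``d_bias[j] * noise_sd`` along each bias
    direction for *all* minority samples; case status adds
    ``d_dis[l] * noise_sd`` along each disease direction.  Noise is i.i.d.
    Normal(0, noise_sd^2) per feature (optionally exponentiated into
    lognormal counts).  Fixed seed gives a bit-identical cohort.
    """
    rng = np.random.default_rng(spec.seed)
    B, U = _make_bases(spec, rng)
    cells = [
        ("majority", "control", spec.n_majority_control),
        ("majority", "case", spec.n_majority_case),
        ("minority", "control", spec.n_minority_control),
        ("minority", "case", spec.n_minority_case),
    ]
    groups, diseases = [], []
    for g, dlab, n in cells:
        groups += [g] * n
        diseases += [dlab] * n
    groups = np.array(groups)
    diseases = np.array(diseases)
    n = len(groups)
    X = spec.baseline + rng.normal(scale=spec.noise_sd,
                                   size=(n, spec.n_features))
    is_min = (groups == "minority").astype(float)
    is_case = (diseases == "case").astype(float)
    if spec.bias_dims:
        shift = spec.noise_sd * np.asarray(spec.bias_effect_sizes)
        X += np.outer(is_min, (B * shift).sum(axis=1))
    if spec.disease_dims:
        shift = spec.noise_sd * np.asarray(spec.disease_effect_sizes)
        X += np.outer(is_case, (U * shift).sum(axis=1))
    if spec.lognormal_counts:
        X = np.exp(X)
    sample_ids = [f"S{i:04d}" for i in range(n)]
    feature_ids = [f"F{j:05d}" for j in range(spec.n_features)]
    fm = FeatureMatrix(sample_ids, feature_ids, X)
    meta = SampleMetadata(
        pd.DataFrame({"sample_id": sample_ids, "disease_label": diseases,
                      "group_label": groups}),
        control_label="control", majority="majority",
    )
    return fm, meta, SyntheticTruth(B, U, spec)


def generate_tissue_differences(
    spec: SyntheticSpec,
    truth: SyntheticTruth,
    n_pairs: int = 30,
    noise_sd: Optional[float] = None,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Tumor-minus-normal difference rows for marker selection.

    Each row is the summed disease-direction loading pattern plus noise, so
    features genuinely loaded on the disease span rank highest on average.
    """
    if spec.disease_dims < 1:
        raise ValueError("need at least one planted disease direction")
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    sd = spec.noise_sd if noise_sd is None else noise_sd
    loading = (truth.disease_basis
               * (np.asarray(spec.disease_effect_sizes) * spec.noise_sd)).sum(axis=1)
    return loading + rng.normal(scale=sd, size=(n_pairs, spec.n_features))
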