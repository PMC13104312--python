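"""Data containers, TSV readers/writers, configuration and model persistence.

All tabular artifacts are plain tab-separated UTF-8 text with '.' decimals:
diff-able, language-portable, and loss-free at >= 12 significant digits.
Feature matrices are written samples-in-rows with feature IDs in the header
and sample IDs in the first column.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FeatureMatrix",
    "SampleMetadata",
    "RunConfig",
    "LoadError",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_metadata",
    "write_metadata",
    "read_config",
    "save_model",
    "load_model",
]

_FLOAT_FMT = "%.15g"


class LoadError(ValueError):
    """A file violated the format contract (missing values, duplicate IDs,
    non-numeric cells, empty matrix, missing columns)."""


@dataclass
class FeatureMatrix:
    """A samples x features real matrix with row/column identifiers.

    ``values`` are normalized fragment counts or any comparable omics
    features; negativity is allowed (bias adjustment can create it).
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise LoadError("matrix values must be 2-D")
        n, p = self.values.shape
        if n == 0 or p == 0:
            raise LoadError("empty matrix")
        if len(self.sample_ids) != n or len(self.feature_ids) != p:
            raise LoadError("id lengths do not match matrix shape")
        for name, ids in (("sample", self.sample_ids), ("feature", self.feature_ids)):
            dup = pd.Index(ids)[pd.Index(ids).duplicated()]
            if len(dup):
                raise LoadError(f"duplicate {name} ID(s): {list(dup[:5])}")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise LoadError(
                f"missing/non-finite value at sample "
                f"{self.sample_ids[bad[0]]!r}, feature {self.feature_ids[bad[1]]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.feature_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        return cls(list(map(str, df.index)), list(map(str, df.columns)),
                   df.to_numpy(dtype=float))

    def subset_features(self, feature_ids: list[str]) -> "FeatureMatrix":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in pos]
        if missing:
            raise LoadError(f"unknown feature ID(s): {missing[:5]}")
        idx = [pos[f] for f in feature_ids]
        return FeatureMatrix(list(self.sample_ids), list(feature_ids),
                             self.values[:, idx])


@dataclass
class SampleMetadata:
    """Per-sample disease label and demographic group label.

    ``control_label`` names the disease level treated as control; the
    ``majority`` group is the designated over-represented demographic
    stratum (defaults to the largest control group).
    """

    table: pd.DataFrame
    control_label: str = "control"
    majority: Optional[str] = None

    REQUIRED = ("sample_id", "disease_label", "group_label")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise LoadError(f"metadata missing required column {col!r}")
        t = self.table.copy()
        for col in self.REQUIRED:
            t[col] = t[col].astype(str)
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise LoadError(f"duplicated sample_id {dup!r}")
        if "fold" in t.columns and t["fold"].notna().any():
            t["fold"] = t["fold"].astype("Int64")
        t = t.set_index("sample_id", drop=False)
        self.table = t
        if self.majority is None:
            ctrl = t[t["disease_label"] == self.control_label]
            counts = ctrl["group_label"].value_counts()
            if len(counts):
                self.majority = str(counts.index[0])

    def aligned_to(self, fm: FeatureMatrix) -> "SampleMetadata":
        """Reorder to the matrix's samples; every sample must be annotated."""
        missing = [s for s in fm.sample_ids if s not in self.table.index]
        if missing:
            raise LoadError(f"metadata missing sample(s): {missing[:5]}")
        return SampleMetadata(self.table.loc[fm.sample_ids].reset_index(drop=True),
                              self.control_label, self.majority)

    @property
    def disease(self) -> np.ndarray:
        return self.table["disease_label"].to_numpy()

    @property
    def group(self) -> np.ndarray:
        return self.table["group_label"].to_numpy()

    @property
    def is_control(self) -> np.ndarray:
        return self.disease == self.control_label

    def subset(self, mask: np.ndarray) -> "SampleMetadata":
        return SampleMetadata(self.table.loc[np.asarray(mask)].reset_index(drop=True),
                              self.control_label, self.majority)


@dataclass(frozen=True)
class RunConfig:
    """Tunable parameters of the pipeline (defaults follow the method's
    published defaults where one exists)."""

    es_bias: float = 0.1
    es_disease: float = 0.5
    es_bias_prime: float = 0.1
    n_permutations: int = 19_999
    alpha_features: float = 0.05
    seed: int = 0
    max_components: Optional[int] = None
    disease_subspace_dims: int = 50
    top_k_markers: int = 5000
    impact_quantile: float = 0.25
    svm_C: float = 1.0

    def __post_init__(self) -> None:
        if min(self.es_bias, self.es_disease, self.es_bias_prime) < 0:
            raise ValueError("effect-size thresholds must be >= 0")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.alpha_features < 1:
            raise ValueError("alpha_features must lie in (0, 1)")

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)


def read_feature_matrix(path: str | Path, transpose: bool = False) -> FeatureMatrix:
    """Read a TSV matrix (header = feature IDs, first column = sample IDs)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise LoadError(f"cannot parse matrix TSV {path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise LoadError(f"empty matrix in {path}")
    if transpose:
        df = df.T
    bad = df.columns[[not np.issubdtype(dt, np.number) for dt in df.dtypes]]
    if len(bad):
        raise LoadError(f"non-numeric cells in column(s) {list(bad[:5])}")
    return FeatureMatrix.from_frame(df)


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    fm.to_frame().to_csv(path, sep="\t", float_format=_FLOAT_FMT,
                         index_label="sample_id")


def read_metadata(path: str | Path, control_label: str = "control",
                  majority: Optional[str] = None) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return SampleMetadata(df, control_label=control_label, majority=majority)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


def read_config(path: str | Path) -> RunConfig:
    """Parse a flat key-value YAML file into a RunConfig."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise LoadError("config must be a flat mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise LoadError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**raw)


def save_model(model, outdir: str | Path) -> None:
    """Persist a fitted debias model as two TSVs plus a YAML manifest.

    ``center.tsv`` holds the training-control mean per feature;
    ``bias_directions.tsv`` holds one selected direction per column with
    feature IDs as rows; ``manifest.yaml`` records config and diagnostics.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.Series(model.center, index=model.feature_ids, name="center").to_csv(
        outdir / "center.tsv", sep="\t", float_format=_FLOAT_FMT,
        index_label="feature_id")
    k = model.bias_directions.shape[1]
    pd.DataFrame(model.bias_directions, index=model.feature_ids,
                 columns=[f"dir_{i+1}" for i in range(k)]).to_csv(
        outdir / "bias_directions.tsv", sep="\t", float_format=_FLOAT_FMT,
        index_label="feature_id")
    manifest = {
        "n_features": len(model.feature_ids),
        "n_selected": k,
        "per_direction_bias_es": [float(v) for v in model.per_direction_bias_es],
        "config": dataclasses.asdict(model.config_used),
        "n_pca_directions": len(model.pca_flags),
        "n_flagged_biased": int(sum(f.flagged_biased for f in model.pca_flags)),
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def load_model(outdir: str | Path):
    from .core import DebiasModel  # local import to avoid a cycle

    outdir = Path(outdir)
    center = pd.read_csv(outdir / "center.tsv", sep="\t", index_col=0)["center"]
    dirs = pd.read_csv(outdir / "bias_directions.tsv", sep="\t", index_col=0)
    if list(dirs.index) != list(center.index):
        raise LoadError("model files disagree on feature IDs")
    with open(outdir / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    cfg = RunConfig(**manifest["config"])
    return DebiasModel(
        feature_ids=list(map(str, center.index)),
        center=center.to_numpy(dtype=float),
        bias_directions=dirs.to_numpy(dtype=float),
        per_direction_bias_es=np.asarray(
            manifest.get("per_direction_bias_es", []), dtype=float),
        pca_flags=[],
        config_used=cfg,
    )
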