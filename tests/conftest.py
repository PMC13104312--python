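import numpy as np
import pandas as pd
import pytest

from fairspace import FeatureMatrix, SampleMetadata, SyntheticSpec, generate_cohort


@pytest.fixture
def small_cohort():
    """Low-dimensional cohort with strong planted structure, for fast
    geometry-sensitive checks."""
    spec = SyntheticSpec(
        n_features=30,
        n_majority_control=200, n_majority_case=200,
        n_minority_control=200, n_minority_case=50,
        bias_dims=2, bias_effect_sizes=(1.5, 1.5),
        disease_dims=2, disease_effect_sizes=(1.5, 1.5),
        seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture
def tiny_matrix():
    rng = np.random.default_rng(5)
    vals = rng.normal(size=(8, 4))
    fm = FeatureMatrix([f"s{i}" for i in range(8)],
                       [f"f{j}" for j in range(4)], vals)
    meta = SampleMetadata(pd.DataFrame({
        "sample_id": fm.sample_ids,
        "disease_label": ["control"] * 5 + ["case"] * 3,
        "group_label": ["maj", "maj", "maj", "min", "min",
                        "maj", "maj", "min"],
    }))
    return fm, meta
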