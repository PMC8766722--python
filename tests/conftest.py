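import numpy as np
import pytest

from roifuse import CohortConfig, FeatureTable, ModalitySpec, \
    generate_multimodal_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_table(rng) -> FeatureTable:
    """20+20 subjects, 10 features, the first 3 informative (d = 1.5)."""
    cfg = CohortConfig(
        n_per_group=20, seed=101,
        modalities=(ModalitySpec("smri", 10, 3, effect_size=1.5),))
    return generate_multimodal_cohort(cfg)["smri"]


@pytest.fixture
def null_table() -> FeatureTable:
    """20+20 subjects, 10 pure-noise features."""
    cfg = CohortConfig(
        n_per_group=20, seed=202,
        modalities=(ModalitySpec("noise", 10, 0),))
    return generate_multimodal_cohort(cfg)["noise"]


def make_table(values, labels, prefix="f") -> FeatureTable:
    values = np.asarray(values, dtype=float)
    names = tuple(f"{prefix}{j + 1}" for j in range(values.shape[1]))
    ids = tuple(f"S{i + 1:03d}" for i in range(values.shape[0]))
    return FeatureTable(ids, np.asarray(labels), names, values)
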