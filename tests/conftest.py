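import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import atlasrules as ar

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def tiny_dataset():
    """3 cells x 2 genes, labels (A, A, B) — hand-checkable fixture."""
    return ar.ExpressionDataset(
        matrix=np.array([[1.0, 0.0], [2.0, 0.5], [0.0, 3.0]]),
        gene_ids=["g0", "g1"],
        cell_ids=["c0", "c1", "c2"],
        labels=["A", "A", "B"],
    )


@pytest.fixture(scope="session")
def small_synth():
    """3-class synthetic dataset with clear markers, shared across tests."""
    spec = ar.SyntheticSpec(
        n_classes=3, class_sizes=(100, 100, 100), markers_per_class=2,
        n_noise_genes=100, effect_size=2.0, noise_sd=1.0,
        dropout_rate=0.0, seed=1,
    )
    return ar.generate_dataset(spec)
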