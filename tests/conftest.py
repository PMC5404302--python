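import numpy as np
import pytest

from mces import BuildingBlockSet, LabeledDataset, SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def blocks():
    return BuildingBlockSet(feature_names=("x1", "x2", "x3", "x4"))


@pytest.fixture
def tiny_dataset():
    """12 samples, 3 classes, 5 features; feature g1 separates perfectly."""
    rng = np.random.default_rng(0)
    n_per = 4
    g1 = np.concatenate([
        rng.normal(0, 0.1, n_per),
        rng.normal(5, 0.1, n_per),
        rng.normal(10, 0.1, n_per),
    ])
    noise = rng.standard_normal((3 * n_per, 4))
    matrix = np.column_stack([g1, noise])
    labels = ["a"] * n_per + ["b"] * n_per + ["c"] * n_per
    return LabeledDataset(
        matrix=matrix,
        feature_names=["g1", "g2", "g3", "g4", "g5"],
        labels=labels,
    )


@pytest.fixture(scope="session")
def synthetic_easy():
    """4 classes x 10 samples, 60 features, 3 informative with a strong shift."""
    spec = SyntheticSpec(
        n_classes=4, samples_per_class=10, n_features=60, n_informative=3,
        effect_size=3.0, seed=7,
    )
    return generate(spec)
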