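import numpy as np
import pytest

from pseucnn import (
    GeneratorConfig,
    extract_features,
    feature_arrays,
    generate_dataset,
)


@pytest.fixture(scope="session")
def strong_signal_set():
    """200 windows of length 21, full compositional signal."""
    return generate_dataset(
        GeneratorConfig(n_pos=100, n_neg=100, window_length=21, signal_strength=1.0, seed=0)
    )


@pytest.fixture(scope="session")
def strong_signal_features(strong_signal_set):
    X, y, ids = feature_arrays(extract_features(strong_signal_set))
    return X, y, ids


@pytest.fixture(scope="session")
def null_signal_features():
    sset = generate_dataset(
        GeneratorConfig(n_pos=100, n_neg=100, window_length=21, signal_strength=0.0, seed=0)
    )
    X, y, _ = feature_arrays(extract_features(sset))
    return X, y


@pytest.fixture(scope="session")
def separable_blobs():
    """Two Gaussian blobs at distance 10 sigma: trivially separable features."""
    rng = np.random.default_rng(42)
    n = 60
    X = np.vstack(
        [rng.normal(0.0, 1.0, size=(n, 40)), rng.normal(10.0, 1.0, size=(n, 40))]
    )
    y = np.concatenate([np.zeros(n, dtype=int), np.ones(n, dtype=int)])
    return X, y
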