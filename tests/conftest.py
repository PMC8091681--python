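import numpy as np
import pytest

from jembed.datatypes import CountMatrix, JointConfig, ModalityView


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def quick_config():
    """Small inner schedules so joint runs stay fast in unit tests."""
    return JointConfig(
        lambda_reg=3.0,
        perplexity=10.0,
        n_neighbors=8,
        inner_iters_first=200,
        inner_iters_later=50,
        seed=0,
    )


@pytest.fixture()
def small_counts(rng):
    values = rng.poisson(5.0, size=(12, 7))
    values[0] += 1  # guard against an all-zero cell
    return CountMatrix(
        values=values,
        cell_ids=[f"c{i}" for i in range(12)],
        feature_ids=[f"g{j}" for j in range(7)],
        modality_name="RNA",
    )


@pytest.fixture()
def blob_views(rng):
    """Two well-separated Gaussian blobs, handy for graph/embedding tests."""
    n_per, dim = 30, 5
    a = rng.normal(size=(n_per, dim))
    b = rng.normal(size=(n_per, dim)) + 20.0
    X = np.vstack([a, b])
    labels = np.array(["A"] * n_per + ["B"] * n_per)
    return ModalityView(X, "blobs"), labels
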