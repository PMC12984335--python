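import numpy as np
import pytest

from mffae.matrix import AbundanceMatrix


@pytest.fixture
def tiny_matrix():
    """2 samples x 3 proteins, fully observed."""
    return AbundanceMatrix(["A", "B"], ["p1", "p2", "p3"],
                           np.array([[5.0, 2.0, 3.0], [4.0, 1.0, 4.0]]))


@pytest.fixture
def matrix_with_missing():
    return AbundanceMatrix(["A", "B"], ["p1", "p2"],
                           np.array([[1.0, np.nan], [3.0, 2.0]]))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_training_matrix(rng):
    """40 samples x 60 proteins with latent low-rank structure, standardized."""
    factors = rng.normal(size=(40, 4))
    loadings = rng.normal(size=(4, 60))
    x = factors @ loadings + 0.3 * rng.normal(size=(40, 60))
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    return AbundanceMatrix([f"s{i}" for i in range(40)],
                           [f"p{j}" for j in range(60)], x)
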