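import numpy as np
import pytest

from convimpute import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts(rng):
    """A 50-gene x 20-cell random integer counts matrix with no empty rows."""
    vals = rng.integers(1, 30, size=(50, 20)).astype(float)
    return ExpressionMatrix(
        vals,
        [f"g{i}" for i in range(50)],
        [f"c{j}" for j in range(20)],
        "counts",
    )


@pytest.fixture
def sparse_counts(rng):
    """A sparse counts matrix with some all-zero genes and cells."""
    vals = rng.integers(0, 5, size=(30, 15)).astype(float)
    vals[vals < 3] = 0.0
    vals[0, :] = 1.0  # keep at least one nonzero row/col
    vals[:, 0] = np.maximum(vals[:, 0], 1.0)
    vals[4, :] = 0.0
    vals[11, :] = 0.0
    vals[:, 7] = 0.0
    return ExpressionMatrix(
        vals,
        [f"g{i}" for i in range(30)],
        [f"c{j}" for j in range(15)],
        "counts",
    )
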