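import numpy as np
import pytest

from mrmr_ifs.data import ExpressionMatrix, LabelVector


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples with distinct, hand-readable values."""
    vals = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [10.0, 0.0, 10.0, 0.0],
            [-1.5, 2.5, 0.0, 1.0],
        ]
    )
    return ExpressionMatrix(("gA", "gB", "gC"), ("s1", "s2", "s3", "s4"), vals)


@pytest.fixture
def tiny_labels() -> LabelVector:
    return LabelVector(("s1", "s2", "s3", "s4"), np.array([1, 1, 0, 0]))


@pytest.fixture
def clouds():
    """Two well-separated Gaussian clouds (20 vs 20, 4 sd apart), plus
    held-out points from the same clouds."""
    rng = np.random.default_rng(7)
    pos = rng.normal(4.0, 1.0, size=(20, 3))
    neg = rng.normal(0.0, 1.0, size=(20, 3))
    X = np.vstack([pos, neg])
    y = np.array([1] * 20 + [0] * 20)
    test_pos = rng.normal(4.0, 1.0, size=(5, 3))
    test_neg = rng.normal(0.0, 1.0, size=(5, 3))
    test_X = np.vstack([test_pos, test_neg])
    test_y = np.array([1] * 5 + [0] * 5)
    return X, y, test_X, test_y
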