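import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from gmkit import grid_template, make_sample, sample_mardia_dryden


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def square():
    """Unit square, 4 landmarks, 2D."""
    return np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


@pytest.fixture
def grid5():
    return grid_template(5, 5)


@pytest.fixture
def md_sample(grid5):
    """Small Mardia-Dryden sample on the 5x5 grid."""
    return sample_mardia_dryden(grid5, n=40, sigma=0.02, seed=7)


def random_rotation(k, rng):
    """Random proper rotation matrix."""
    A = rng.normal(size=(k, k))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
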