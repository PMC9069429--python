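import numpy as np
import pytest

from mvshift.data_model import MatrixSample


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sample(rng):
    """20 observations of 2×3 matrices with two loose groups."""
    x = rng.normal(size=(20, 2, 3))
    x[10:] += 4.0
    return MatrixSample(x)


def fd_gradient(f, q, eps=1e-5):
    """Central finite-difference gradient of a scalar field on matrices."""
    q = np.asarray(q, dtype=float)
    g = np.zeros_like(q)
    for i in range(q.shape[0]):
        for j in range(q.shape[1]):
            qp = q.copy()
            qp[i, j] += eps
            qm = q.copy()
            qm[i, j] -= eps
            g[i, j] = (f(qp) - f(qm)) / (2 * eps)
    return g
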