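import numpy as np
import pytest

from penselect import Dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(rng, n=80, p=5, beta=None, sigma=1.0, corr=None):
    """Random Gaussian dataset with optional true beta and correlation."""
    if corr is None:
        X = rng.standard_normal((n, p))
    else:
        X = rng.standard_normal((n, p)) @ np.linalg.cholesky(corr).T
    beta = np.zeros(p) if beta is None else np.asarray(beta, float)
    y = X @ beta + rng.normal(0.0, sigma, n)
    return Dataset(X, y, [f"x{j}" for j in range(p)])


def make_orthonormal_dataset(rng, n=50, p=3, sigma=1.0, beta=None):
    """Design with X'X/n exactly the identity and exactly centered columns."""
    A = rng.standard_normal((n, p))
    A -= A.mean(axis=0)
    Q, _ = np.linalg.qr(A)
    Q -= Q.mean(axis=0)  # re-center; QR columns of a centered matrix stay centered
    Q, _ = np.linalg.qr(Q)
    X = Q * np.sqrt(n)
    beta = np.zeros(p) if beta is None else np.asarray(beta, float)
    y = X @ beta + rng.normal(0.0, sigma, n)
    return Dataset(X, y, [f"x{j}" for j in range(p)])


@pytest.fixture
def dataset(rng):
    return make_dataset(rng, beta=[2.0, 0.0, -1.0, 0.0, 0.5])
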