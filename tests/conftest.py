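import numpy as np
import pytest

from jointdeconv import (
    PeakShape,
    SyntheticTruth,
    build_DtD,
    make_spectrum,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noise_free():
    """Noise-free synthetic benchmark spectrum with its ground truth."""
    spec, truth = make_spectrum(SyntheticTruth(sigma_noise=0.0, seed=1))
    return spec, truth


@pytest.fixture(scope="session")
def small_shape():
    """Narrow Gaussian kernel for fast small-n problems."""
    return PeakShape.gaussian(2.0)


def dense_DtD(n: int) -> np.ndarray:
    diag, off = build_DtD(n)
    return np.diag(diag) + np.diag(off, 1) + np.diag(off, -1)


def dense_B(mu: float, n: int) -> np.ndarray:
    return np.eye(n) + mu * dense_DtD(n)


def dense_A(mu: float, n: int) -> np.ndarray:
    return np.eye(n) - np.linalg.inv(dense_B(mu, n))
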