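import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_psd(rng):
    """Factory for random symmetric PSD matrices."""

    def make(n: int) -> np.ndarray:
        A = rng.standard_normal((n, n))
        return A @ A.T / n

    return make


@pytest.fixture
def two_block_views():
    """Two small views whose Gaussian kernels share an exact 2-block structure."""
    from ecmc import ViewSet

    n, half = 20, 10
    base = np.zeros((2, n))
    base[:, half:] = 8.0
    r = np.random.default_rng(7)
    views = [base + 0.05 * r.standard_normal((2, n)) for _ in range(2)]
    truth = np.repeat([1, 2], half)
    return ViewSet(views), truth
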