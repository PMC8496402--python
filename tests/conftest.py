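import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def psd_kernel(rng):
    """Factory for random dense PSD Gram matrices."""

    def make(n: int, scale: float = 1.0) -> np.ndarray:
        A = rng.standard_normal((n, n))
        K = (A @ A.T) / n * scale
        return (K + K.T) / 2.0

    return make
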