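import numpy as np
import pytest

from aphidseg import ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_cfg():
    """A narrow network for fast training-loop tests (widths still double)."""
    return ModelConfig(
        widths=(8, 16, 32, 64, 128),
        feam_scales=((2, 4), (4, 8), (8, 16), (16, 32)),
    )


def finite_difference(f, x: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Central finite-difference gradient of scalar f at x (float64 probing)."""
    g = np.zeros(x.shape, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = x[i]
        x[i] = old + eps
        fp = f()
        x[i] = old - eps
        fm = f()
        x[i] = old
        g[i] = (fp - fm) / (2 * eps)
    return g
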