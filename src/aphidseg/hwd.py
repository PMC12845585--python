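"""Haar Wavelet Downsampling (HWD).

Replaces max pooling by a lossless, orthonormal single-level 2-D Haar
decomposition (approximation + horizontal/vertical/diagonal detail, stacked
to 4C channels at half resolution) followed by a learned representation
head: 1x1 convolution, batch normalisation and ReLU. The wavelet stage has
no parameters and conserves energy exactly; every learnable weight of the
block lives in the head.

Subband order in the 4C stack is fixed as (A, horizontal, vertical,
diagonal); "horizontal detail" means the response of the high-pass filter
applied along the width axis.
"""

from __future__ import annotations

import numpy as np

from .nn import BatchNorm2d, Conv2d, Module, Tensor
from .nn.functional import haar_dwt2, haar_idwt2

__all__ = ["haar_dwt2", "haar_idwt2", "HWD", "hwd_apply", "hwd_param_count"]


def hwd_param_count(in_channels: int, out_channels: int) -> int:
    """Closed-form parameter count of the head: 1x1 conv (with bias) + BN."""
    return 4 * in_channels * out_channels + out_channels + 2 * out_channels


class HWD(Module):
    """Haar analysis followed by a 1x1 conv + BN + ReLU head (4C -> out)."""

    def __init__(self, in_channels: int, out_channels: int | None = None,
                 conv_bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        out_channels = in_channels if out_channels is None else out_channels
        self.conv = Conv2d(4 * in_channels, out_channels, kernel=1, bias=conv_bias, rng=rng)
        self.bn = BatchNorm2d(out_channels)
        self.in_channels = in_channels
        self.out_channels = out_channels

    def forward(self, x: Tensor) -> Tensor:
        sub = haar_dwt2(x)
        return self.bn(self.conv(sub)).relu()


def hwd_apply(x: Tensor | np.ndarray, out_channels: int,
              rng: np.random.Generator | None = None) -> Tensor:
    """Build a fresh HWD block for ``x`` and run it once (training mode)."""
    if not isinstance(x, Tensor):
        x = Tensor(x)
    if out_channels <= 0:
        raise ValueError("out_channels must be positive")
    c = x.shape[-3]
    return HWD(c, out_channels, rng=rng)(x)
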