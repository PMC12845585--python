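"""Efficient Multi-scale Attention (EMA) for the encoder-decoder bottleneck.

The block splits the C channels into g groups and, per group of width
c = C/g, runs two branches:

* a 1x1 branch over the concatenated directional (height/width) average-pool
  descriptors, split back and applied as sigmoid gates, followed by a group
  normalisation;
* a 3x3 branch capturing local structure.

Cross-spatial aggregation then forms a spatial map from softmax-weighted
inner products between each branch's global descriptor and the other
branch's spatial response; a final sigmoid turns the sum into a modulation
map in (0, 1) that rescales the group.

Learnable state per block: one 1x1 conv (c->c), one 3x3 conv (c->c) and one
affine group norm over c channels - (c^2+c) + (9c^2+c) + 2c parameters,
shared across groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Conv2d, GroupNorm, Module, Tensor, concat

__all__ = ["EmaConfig", "directional_pool", "EMA", "ema_apply", "ema_param_count"]


@dataclass
class EmaConfig:
    channels: int
    groups: int = 8

    def __post_init__(self):
        if self.channels <= 0 or self.groups <= 0:
            raise ValueError("channels and groups must be positive")
        if self.channels % self.groups:
            raise ValueError(
                f"channels ({self.channels}) must be divisible by groups ({self.groups})"
            )

    @property
    def group_width(self) -> int:
        return self.channels // self.groups


def directional_pool(x: Tensor) -> tuple[Tensor, Tensor]:
    """1-D global average pools of a (..., c, H, W) map along each spatial axis.

    Returns the row descriptor (mean over the width axis, shape (..., c, H, 1))
    and the column descriptor (mean over the height axis, shape (..., c, 1, W)).
    """
    row = x.mean(axis=-1, keepdims=True)
    col = x.mean(axis=-2, keepdims=True)
    return row, col


def ema_param_count(channels: int, groups: int) -> int:
    """Closed-form learnable-parameter count of one EMA block."""
    c = EmaConfig(channels, groups).group_width
    return (c * c + c) + (9 * c * c + c) + 2 * c


class EMA(Module):
    def __init__(self, cfg: EmaConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        c = cfg.group_width
        self.cfg = cfg
        self.conv1x1 = Conv2d(c, c, kernel=1, bias=True, rng=rng)
        self.conv3x3 = Conv2d(c, c, kernel=3, padding=1, bias=True, rng=rng)
        self.gn = GroupNorm(c, c)  # per-channel normalisation within the group

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        cfg = self.cfg
        if C != cfg.channels:
            raise ValueError(f"EMA built for {cfg.channels} channels, got {C}")
        g, c = cfg.groups, cfg.group_width
        xg = x.reshape(N * g, c, H, W)

        # 1x1 pathway on stacked directional descriptors
        row, col = directional_pool(xg)                      # (Ng,c,H,1), (Ng,c,1,W)
        col_t = col.transpose(0, 1, 3, 2)                    # (Ng,c,W,1)
        hw = self.conv1x1(concat([row, col_t], axis=2))      # (Ng,c,H+W,1)
        gate_h = hw[:, :, :H, :].sigmoid()                   # (Ng,c,H,1)
        gate_w = hw[:, :, H:, :].transpose(0, 1, 3, 2).sigmoid()  # (Ng,c,1,W)
        x1 = self.gn(xg * gate_h * gate_w)

        # 3x3 pathway
        x2 = self.conv3x3(xg)

        # cross-spatial aggregation: softmaxed global descriptors of one branch
        # weight the flattened response of the other
        d1 = x1.mean(axis=(2, 3)).softmax(axis=-1).reshape(N * g, 1, c)
        d2 = x2.mean(axis=(2, 3)).softmax(axis=-1).reshape(N * g, 1, c)
        f1 = x2.reshape(N * g, c, H * W)
        f2 = x1.reshape(N * g, c, H * W)
        spatial = (d1 @ f1 + d2 @ f2).reshape(N * g, 1, H, W)
        out = xg * spatial.sigmoid()
        return out.reshape(N, C, H, W)


def ema_apply(x: Tensor | np.ndarray, cfg: EmaConfig,
              rng: np.random.Generator | None = None) -> Tensor:
    """Functional convenience: build a fresh EMA block and run it once."""
    if not isinstance(x, Tensor):
        x = Tensor(x)
    return EMA(cfg, rng=rng)(x)
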