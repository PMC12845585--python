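"""Parameter-free per-neuron energy attention (SimAM).

Each neuron ``t`` of a channel plane is scored by the minimum of a linear
separability energy: a neuron whose activation stands out from the rest of
its channel attains a *low* minimum energy and therefore a *high* attention
weight. With mean mu and population variance sigma^2 taken over all M = H*W
neurons of the channel, the minimum has the closed form

    e*(t) = 4 (sigma^2 + lambda) / ((t - mu)^2 + 2 sigma^2 + 2 lambda)

and the refined feature map is ``sigmoid(1/E) * X``, applied independently
per channel. The block introduces no learnable parameters.

The population-variance (divisor M) convention is deliberate: with it, the
closed form is the *exact* minimiser of the underlying energy objective in
which every neuron of the plane acts as a neighbour, which the test suite
verifies against a brute-force numerical minimiser. A Bessel-corrected
variance would only agree up to O(1/M).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Module, Tensor

__all__ = ["EnergyMap", "simam_energy", "simam_apply", "SimAM"]

DEFAULT_LAMBDA = 1e-4


@dataclass
class EnergyMap:
    """Per-neuron minimum energies for one channel plane."""

    values: np.ndarray  # same shape as the plane, strictly positive
    lam: float

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("EnergyMap requires lambda > 0")


def _plane_stats(plane: np.ndarray) -> tuple[float, float]:
    mu = float(plane.mean())
    var = float(((plane - mu) ** 2).mean())  # population variance, divisor M
    return mu, var


def simam_energy(plane: np.ndarray, lam: float = DEFAULT_LAMBDA) -> EnergyMap:
    """Closed-form minimum energy for every neuron of a 2-D channel plane.

    Raises ``ValueError`` for non-positive ``lam`` or a plane with fewer than
    two elements (the variance would be meaningless).
    """
    plane = np.asarray(plane, dtype=np.float64)
    if lam <= 0:
        raise ValueError(f"lambda must be positive, got {lam}")
    if plane.ndim != 2:
        raise ValueError(f"expected a 2-D plane, got shape {plane.shape}")
    if plane.size < 2:
        raise ValueError("plane must contain at least 2 elements")
    mu, var = _plane_stats(plane)
    values = 4.0 * (var + lam) / ((plane - mu) ** 2 + 2.0 * var + 2.0 * lam)
    return EnergyMap(values=values, lam=lam)


def simam_apply(x: Tensor | np.ndarray, lam: float = DEFAULT_LAMBDA) -> Tensor:
    """Apply SimAM re-weighting ``sigmoid(1/E) * X`` channel by channel.

    ``x`` is (..., C, H, W); statistics are computed per channel plane, so the
    operation commutes with any channel permutation. Differentiable end to end
    (gradients flow through the channel statistics as well).
    """
    if not isinstance(x, Tensor):
        x = Tensor(x)
    if lam <= 0:
        raise ValueError(f"lambda must be positive, got {lam}")
    H, W = x.shape[-2], x.shape[-1]
    M = H * W
    if M < 2:
        raise ValueError("SimAM needs at least 2 spatial positions per channel")
    mu = x.mean(axis=(-2, -1), keepdims=True)
    centered = x - mu
    var = (centered ** 2).mean(axis=(-2, -1), keepdims=True)
    inv_energy = (centered ** 2) / ((var + lam) * 4.0) + 0.5  # = 1 / e*(t)
    return x * inv_energy.sigmoid()


class SimAM(Module):
    """Module wrapper so the block can sit inside a Sequential encoder stage."""

    def __init__(self, lam: float = DEFAULT_LAMBDA):
        super().__init__()
        if lam <= 0:
            raise ValueError(f"lambda must be positive, got {lam}")
        self.lam = lam

    def forward(self, x: Tensor) -> Tensor:
        return simam_apply(x, self.lam)
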