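"""Layer/module system: parameter containers over the autodiff engine."""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = [
    "Module",
    "Sequential",
    "Identity",
    "ReLU",
    "Sigmoid",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "GroupNorm",
    "Linear",
]


class Module:
    """Base class. Submodules, parameters and buffers are discovered through
    attribute assignment, mirroring the conventions of mainstream DL stacks."""

    def __init__(self):
        object.__setattr__(self, "_params", OrderedDict())
        object.__setattr__(self, "_buffers", OrderedDict())
        object.__setattr__(self, "_modules", OrderedDict())
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, array: np.ndarray):
        self._buffers[name] = array
        object.__setattr__(self, name, array)

    # -- traversal ------------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield (prefix + name, p)
        for mname, mod in self._modules.items():
            yield from mod.named_parameters(prefix + mname + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name in self._buffers:
            yield (prefix + name, getattr(self, name))
        for mname, mod in self._modules.items():
            yield from mod.named_buffers(prefix + mname + ".")

    def modules(self):
        yield self
        for mod in self._modules.values():
            yield from mod.modules()

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    # -- (de)serialisation ----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state["buffer:" + name] = np.asarray(buf).copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for name, p in self.named_parameters():
            if name not in state:
                raise KeyError(f"missing parameter {name!r} in state dict")
            if state[name].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name!r}")
            p.data[...] = state[name]
        for fq, _ in list(self.named_buffers()):
            key = "buffer:" + fq
            if key in state:
                self._assign_buffer(fq, state[key])
        return self

    def _assign_buffer(self, fqname: str, value: np.ndarray):
        parts = fqname.split(".")
        mod = self
        for part in parts[:-1]:
            mod = mod._modules[part]
        mod._buffers[parts[-1]] = value.copy()
        object.__setattr__(mod, parts[-1], mod._buffers[parts[-1]])

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, str(i), m)
        self._seq = mods

    def forward(self, x):
        for m in self._seq:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    std = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, std, size=shape).astype(np.float32), requires_grad=True)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, padding: int = 0,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        self.weight = _kaiming(rng, (out_ch, in_ch, kernel, kernel), fan_in)
        self.bias = (
            Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True) if bias else None
        )
        self.padding = padding

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, padding=self.padding)


class ConvTranspose2d(Module):
    """2x2, stride-2 transposed convolution (the UNet up-sampling step)."""

    def __init__(self, in_ch: int, out_ch: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = _kaiming(rng, (in_ch, out_ch, 2, 2), in_ch * 4)
        self.bias = (
            Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True) if bias else None
        )

    def forward(self, x):
        return F.conv_transpose2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.weight = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.eps = eps
        self.momentum = momentum
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float32))

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean[...] = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data.ravel()
            )
            self.running_var[...] = (
                (1 - self.momentum) * self.running_var + self.momentum * var.data.ravel()
            )
            xhat = (x - mu) / ((var + self.eps).sqrt())
        else:
            mu = self.running_mean.reshape(1, -1, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, -1, 1, 1)
            xhat = (x - Tensor(mu)) / Tensor(sd)
        w = self.weight.reshape(1, -1, 1, 1)
        b = self.bias.reshape(1, -1, 1, 1)
        return xhat * w + b


class GroupNorm(Module):
    def __init__(self, groups: int, channels: int, eps: float = 1e-5, affine: bool = True):
        super().__init__()
        if channels % groups:
            raise ValueError("GroupNorm: channels must be divisible by groups")
        self.groups = groups
        self.eps = eps
        if affine:
            self.weight = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
            self.bias = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        else:
            self.weight = None
            self.bias = None

    def forward(self, x):
        N, C, H, W = x.shape
        g = self.groups
        xg = x.reshape(N, g, C // g, H, W)
        mu = xg.mean(axis=(2, 3, 4), keepdims=True)
        var = ((xg - mu) ** 2).mean(axis=(2, 3, 4), keepdims=True)
        xhat = ((xg - mu) / ((var + self.eps).sqrt())).reshape(N, C, H, W)
        if self.weight is not None:
            xhat = xhat * self.weight.reshape(1, -1, 1, 1) + self.bias.reshape(1, -1, 1, 1)
        return xhat


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = _kaiming(rng, (out_features, in_features), in_features)
        self.bias = (
            Tensor(np.zeros(out_features, dtype=np.float32), requires_grad=True)
            if bias
            else None
        )

    def forward(self, x):
        y = x @ self.weight.transpose(1, 0)
        if self.bias is not None:
            y = y + self.bias
        return y
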