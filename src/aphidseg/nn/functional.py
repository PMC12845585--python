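"""Hand-differentiated array operations used by the network layers.

Each function takes and returns :class:`~aphidseg.nn.tensor.Tensor` objects
and registers an explicit backward closure. Convolutions use an
im2col/GEMM formulation so the heavy lifting happens inside BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor

__all__ = [
    "conv2d",
    "conv_transpose2x2",
    "max_pool2x2",
    "bilinear_resize",
    "spectral_modulate",
    "haar_dwt2",
    "haar_idwt2",
]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, padding: int = 0) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation), NCHW layout.

    ``w`` has shape (O, C, kh, kw); ``b`` is (O,) or None.
    """
    N, C, H, W = x.data.shape
    O, Cw, kh, kw = w.data.shape
    if Cw != C:
        raise ValueError(f"conv2d: input has {C} channels, kernel expects {Cw}")
    p = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    Ho, Wo = xp.shape[2] - kh + 1, xp.shape[3] - kw + 1

    # (N, C, Ho, Wo, kh, kw) view -> (N, Ho*Wo, C*kh*kw) columns
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        N, Ho * Wo, C * kh * kw
    )
    wmat = w.data.reshape(O, C * kh * kw)
    out = cols @ wmat.T  # (N, Ho*Wo, O)
    if b is not None:
        out += b.data
    out_data = np.ascontiguousarray(out.transpose(0, 2, 1)).reshape(N, O, Ho, Wo)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        L = Ho * Wo
        gmat = np.ascontiguousarray(g.reshape(N, O, L).transpose(0, 2, 1)).reshape(N * L, O)
        if b is not None and b.requires_grad:
            b._accumulate(gmat.sum(axis=0))
        if w.requires_grad:
            gw = gmat.T @ cols.reshape(N * L, C * kh * kw)
            w._accumulate(gw.reshape(O, C, kh, kw))
        if x.requires_grad:
            dcols = (gmat @ wmat).reshape(N, Ho, Wo, C, kh, kw)
            # one big transpose so each tap add is contiguous
            dct = np.ascontiguousarray(dcols.transpose(4, 5, 0, 3, 1, 2))
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + Ho, j : j + Wo] += dct[i, j]
            dx = dxp[:, :, p : p + H, p : p + W] if p else dxp
            x._accumulate(dx)

    return Tensor._make(out_data, parents, backward)


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """2x2 stride-2 transposed convolution: each pixel expands to a 2x2 block.

    ``w`` has shape (C_in, C_out, 2, 2).
    """
    N, C, H, W = x.data.shape
    Cin, O, kh, kw = w.data.shape
    if Cin != C:
        raise ValueError(f"conv_transpose2x2: input has {C} channels, kernel expects {Cin}")
    # (N,H,W,O,2,2)
    t = np.tensordot(x.data, w.data, axes=([1], [0]))
    out_data = np.ascontiguousarray(t.transpose(0, 3, 1, 4, 2, 5)).reshape(
        N, O, 2 * H, 2 * W
    )
    if b is not None:
        out_data += b.data[None, :, None, None]

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        blocks = g.reshape(N, O, H, 2, W, 2).transpose(0, 2, 4, 1, 3, 5)  # N,H,W,O,2,2
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.tensordot(x.data, blocks, axes=([0, 2, 3], [0, 1, 2]))
            w._accumulate(gw)
        if x.requires_grad:
            gx = np.tensordot(blocks, w.data, axes=([3, 4, 5], [1, 2, 3]))
            x._accumulate(np.ascontiguousarray(gx.transpose(0, 3, 1, 2)))

    return Tensor._make(out_data, parents, backward)


def max_pool2x2(x: Tensor) -> Tensor:
    """2x2 stride-2 max pooling; requires even spatial dims."""
    N, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("max_pool2x2 requires even spatial dimensions")
    r = x.data.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = np.ascontiguousarray(r).reshape(N, C, H // 2, W // 2, 4)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
        grad = gflat.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(grad.reshape(N, C, H, W))

    return Tensor._make(out_data, (x,), backward)


def _bilinear_coeffs(n_in: int, n_out: int):
    """Index/weight pairs for 1-D bilinear interpolation, corners aligned."""
    if n_out == 1 or n_in == 1:
        pos = np.zeros(n_out)
    else:
        pos = np.arange(n_out) * (n_in - 1) / (n_out - 1)
    lo = np.floor(pos).astype(np.int64)
    lo = np.minimum(lo, n_in - 1)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = (pos - lo).astype(np.float32)
    return lo, hi, frac


def bilinear_resize(grid: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Bilinear interpolation of a 2-D grid to ``out_hw``, corners aligned.

    Identity when the target size equals the stored size; exactly preserves
    constant grids.
    """
    Hin, Win = grid.data.shape
    Hout, Wout = out_hw
    if (Hin, Win) == (Hout, Wout):
        return grid * 1.0  # graph-preserving identity
    rlo, rhi, rf = _bilinear_coeffs(Hin, Hout)
    clo, chi, cf = _bilinear_coeffs(Win, Wout)
    g = grid.data
    top = g[rlo][:, clo] * (1 - cf) + g[rlo][:, chi] * cf
    bot = g[rhi][:, clo] * (1 - cf) + g[rhi][:, chi] * cf
    out_data = top * (1 - rf[:, None]) + bot * rf[:, None]

    def backward(gout):
        gg = np.zeros_like(g)
        w_tl = (1 - rf[:, None]) * (1 - cf)
        w_tr = (1 - rf[:, None]) * cf
        w_bl = rf[:, None] * (1 - cf)
        w_br = rf[:, None] * cf
        np.add.at(gg, (rlo[:, None], clo[None, :]), gout * w_tl)
        np.add.at(gg, (rlo[:, None], chi[None, :]), gout * w_tr)
        np.add.at(gg, (rhi[:, None], clo[None, :]), gout * w_bl)
        np.add.at(gg, (rhi[:, None], chi[None, :]), gout * w_br)
        grid._accumulate(gg)

    return Tensor._make(out_data.astype(np.float32), (grid,), backward)


def spectral_modulate(x: Tensor, alpha: Tensor, beta: Tensor) -> Tensor:
    """Per-channel frequency modulation ``Re(F^-1(F(x) * (alpha + i beta)))``.

    The 2-D FFT uses the unitary ("ortho") normalisation, so Parseval's
    identity holds exactly. ``alpha``/``beta`` are (H, W) planes broadcast over
    batch and channels; frequency bins follow NumPy ordering (zero frequency
    at the index origin, no shifting).
    """
    H, W = x.data.shape[-2:]
    if alpha.data.shape != (H, W) or beta.data.shape != (H, W):
        raise ValueError(
            f"spectral_modulate: weight planes {alpha.data.shape} do not match "
            f"feature spatial dims {(H, W)}"
        )
    wfreq = alpha.data + 1j * beta.data
    X = np.fft.fft2(x.data, norm="ortho")
    out_data = np.fft.ifft2(X * wfreq, norm="ortho").real.astype(np.float32)

    def backward(g):
        G = np.fft.fft2(g, norm="ortho")
        if x.requires_grad:
            dx = np.fft.ifft2(np.conj(wfreq) * G, norm="ortho").real
            x._accumulate(dx.astype(np.float32))
        if alpha.requires_grad or beta.requires_grad:
            prod = np.conj(G) * X  # (..., H, W)
            prod = prod.reshape(-1, H, W).sum(axis=0)
            if alpha.requires_grad:
                alpha._accumulate(prod.real.astype(np.float32))
            if beta.requires_grad:
                beta._accumulate((-prod.imag).astype(np.float32))

    return Tensor._make(out_data, (x, alpha, beta), backward)


# Orthonormal single-level 2-D Haar analysis. Per non-overlapping 2x2 block
# [[a, b], [c, d]] the four subband coefficients are
#   A = (a+b+c+d)/2   approximation
#   H = (a-b+c-d)/2   horizontal detail (high-pass along the width axis)
#   V = (a+b-c-d)/2   vertical detail   (high-pass along the height axis)
#   D = (a-b-c+d)/2   diagonal detail
# which is the separable product of the 1/sqrt(2)-normalised Haar pair.


def _haar_split(data: np.ndarray):
    a = data[..., 0::2, 0::2]
    b = data[..., 0::2, 1::2]
    c = data[..., 1::2, 0::2]
    d = data[..., 1::2, 1::2]
    return a, b, c, d


def _haar_forward(data: np.ndarray) -> np.ndarray:
    a, b, c, d = _haar_split(data)
    return np.concatenate(
        [
            0.5 * (a + b + c + d),
            0.5 * (a - b + c - d),
            0.5 * (a + b - c - d),
            0.5 * (a - b - c + d),
        ],
        axis=-3,
    ).astype(np.float32)


def _haar_inverse(sub: np.ndarray) -> np.ndarray:
    C4 = sub.shape[-3]
    C = C4 // 4
    A, Hd, Vd, Dd = (sub[..., i * C : (i + 1) * C, :, :] for i in range(4))
    h, w = sub.shape[-2:]
    out_shape = sub.shape[:-3] + (C, 2 * h, 2 * w)
    out = np.empty(out_shape, dtype=np.float32)
    out[..., 0::2, 0::2] = 0.5 * (A + Hd + Vd + Dd)
    out[..., 0::2, 1::2] = 0.5 * (A - Hd + Vd - Dd)
    out[..., 1::2, 0::2] = 0.5 * (A + Hd - Vd - Dd)
    out[..., 1::2, 1::2] = 0.5 * (A - Hd - Vd + Dd)
    return out


def haar_dwt2(x: Tensor) -> Tensor:
    """Single-level orthonormal 2-D Haar transform.

    Halves both spatial dims and stacks the four subbands along the channel
    axis in the fixed order (approximation, horizontal, vertical, diagonal),
    so a (..., C, H, W) input becomes (..., 4C, H/2, W/2). The transform is
    orthonormal: it has no parameters, conserves energy exactly and is
    inverted by :func:`haar_idwt2`.
    """
    H, W = x.data.shape[-2:]
    if H % 2 or W % 2:
        raise ValueError(f"haar_dwt2 requires even spatial dims, got {(H, W)}")
    out_data = _haar_forward(x.data)

    def backward(g):
        # adjoint of an orthonormal map is its inverse
        x._accumulate(_haar_inverse(g))

    return Tensor._make(out_data, (x,), backward)


def haar_idwt2(s: Tensor) -> Tensor:
    """Inverse of :func:`haar_dwt2`; expects a (..., 4C, h, w) subband stack."""
    C4 = s.data.shape[-3]
    if C4 % 4:
        raise ValueError(f"haar_idwt2 expects a channel count divisible by 4, got {C4}")
    out_data = _haar_inverse(s.data)

    def backward(g):
        s._accumulate(_haar_forward(g))

    return Tensor._make(out_data, (s,), backward)
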