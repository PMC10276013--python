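"""Convolution, normalization and resampling primitives with custom gradients.

All feature maps are NHWC (batch, height, width, channels).  Convolutions
are cross-correlations (deep-learning convention) computed tap by tap: for
each of the kh*kw kernel taps a contiguous spatial slice of the padded
input is multiplied (one BLAS matmul) with that tap's (C_in, C_out) matrix
and accumulated.  This keeps every memory copy in long contiguous runs,
which on one CPU core is much faster than an im2col gather in NHWC layout.
The tap slices are cached on the graph node and reused for the weight
gradient; the input gradient is the matching scatter with transposed tap
matrices.

Kernels are stored as (out_channels, in_channels, kh, kw).
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "conv2d_same",
    "conv2d_down2",
    "batch_norm",
    "upsample_nearest2x",
    "add_bias",
]


def _pad_same(x: np.ndarray, kh: int, kw: int, dilation: int) -> np.ndarray:
    ph = dilation * (kh - 1) // 2
    pw = dilation * (kw - 1) // 2
    if ph == 0 and pw == 0:
        return x
    return np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))


def _tap_slices(xp: np.ndarray, kh: int, kw: int, dilation: int,
                h: int, w: int) -> list[np.ndarray]:
    """Contiguous (N*H*W, C) views of the padded input, one per kernel tap."""
    c = xp.shape[3]
    out = []
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, i * dilation:i * dilation + h, j * dilation:j * dilation + w, :]
            out.append(np.ascontiguousarray(xs).reshape(-1, c))
    return out


def conv2d_same(x: Tensor, weight: Tensor, dilation: int = 1) -> Tensor:
    """Stride-1 same-padded (dilated) convolution.

    Kernel sides must be odd so that zero same-padding is symmetric.
    """
    o, c_in, kh, kw = weight.data.shape
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError(f"same-padded convolution requires odd kernel sides, got {kh}x{kw}")
    n, h, w, c = x.data.shape
    if c != c_in:
        raise ValueError("input channels do not match kernel")

    taps = weight.data.transpose(2, 3, 1, 0).reshape(kh * kw, c_in, o)
    if kh == 1 and kw == 1:
        slices = [x.data.reshape(-1, c)]
    else:
        slices = _tap_slices(_pad_same(x.data, kh, kw, dilation), kh, kw, dilation, h, w)
    acc = slices[0] @ taps[0]
    tmp = np.empty_like(acc)
    for s, t in zip(slices[1:], taps[1:]):
        np.matmul(s, t, out=tmp)
        acc += tmp
    out_data = acc.reshape(n, h, w, o)
    if not weight.requires_grad:
        slices = None  # free the cache when the weight gradient is not needed

    def backward(g):
        g2d = np.ascontiguousarray(g).reshape(-1, o)
        if weight.requires_grad:
            gw = np.empty((kh * kw, c_in, o), dtype=np.float32)
            for k, s in enumerate(slices):
                np.matmul(s.T, g2d, out=gw[k])
            weight._accum(gw.reshape(kh, kw, c_in, o).transpose(3, 2, 0, 1))
        if x.requires_grad:
            ph = dilation * (kh - 1) // 2
            pw = dilation * (kw - 1) // 2
            gxp = np.zeros((n, h + 2 * ph, w + 2 * pw, c_in), dtype=np.float32)
            tmp_g = np.empty((g2d.shape[0], c_in), dtype=np.float32)
            k = 0
            for i in range(kh):
                for j in range(kw):
                    np.matmul(g2d, taps[k].T, out=tmp_g)
                    gxp[:, i * dilation:i * dilation + h,
                        j * dilation:j * dilation + w, :] += tmp_g.reshape(n, h, w, c_in)
                    k += 1
            if ph or pw:
                gxp = gxp[:, ph:ph + h, pw:pw + w, :]
            x._accum(np.ascontiguousarray(gxp))

    return Tensor._make(out_data, (x, weight), backward)


def conv2d_down2(x: Tensor, weight: Tensor) -> Tensor:
    """2x2 convolution with stride 2 (exact 2x downscale, no padding)."""
    n, h, w, c = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"strided 2x downsample requires even spatial size, got {h}x{w}")
    o = weight.data.shape[0]
    if weight.data.shape[1:] != (c, 2, 2):
        raise ValueError("kernel must be (out, in, 2, 2)")
    ho, wo = h // 2, w // 2
    # (N,H,W,C) -> (N,Ho,2,Wo,2,C) -> contiguous (N*Ho*Wo, 2*2*C)
    cols = np.ascontiguousarray(
        x.data.reshape(n, ho, 2, wo, 2, c).transpose(0, 1, 3, 2, 4, 5)
    ).reshape(n * ho * wo, 4 * c)
    w2d = np.ascontiguousarray(weight.data.transpose(2, 3, 1, 0).reshape(4 * c, o))
    out_data = (cols @ w2d).reshape(n, ho, wo, o)

    def backward(g):
        g2d = np.ascontiguousarray(g).reshape(n * ho * wo, o)
        if weight.requires_grad:
            gw = (cols.T @ g2d).reshape(2, 2, c, o).transpose(3, 2, 0, 1)
            weight._accum(gw)
        if x.requires_grad:
            gcols = g2d @ w2d.T  # (N*Ho*Wo, 2*2*C)
            gx = gcols.reshape(n, ho, wo, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
            x._accum(np.ascontiguousarray(gx).reshape(n, h, w, c))

    return Tensor._make(out_data, (x, weight), backward)


def add_bias(x: Tensor, bias: Tensor) -> Tensor:
    """Add a per-channel bias (C,) to an NHWC tensor."""
    out_data = x.data + bias.data

    def backward(g):
        if x.requires_grad:
            x._accum(g)
        if bias.requires_grad:
            bias._accum(g.sum(axis=(0, 1, 2)))

    return Tensor._make(out_data, (x, bias), backward)


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.9,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over (N, H, W) of an NHWC tensor.

    In training mode batch statistics are used and the running buffers are
    updated in place; in inference mode the op is a fixed per-channel affine.
    """
    if training:
        mu = x.data.mean(axis=(0, 1, 2))
        var = x.data.var(axis=(0, 1, 2))
        running_mean *= momentum
        running_mean += (1.0 - momentum) * mu
        running_var *= momentum
        running_var += (1.0 - momentum) * var
    else:
        mu, var = running_mean, running_var
    inv_std = (1.0 / np.sqrt(var + eps)).astype(np.float32)
    xhat = (x.data - mu) * inv_std
    out_data = gamma.data * xhat + beta.data

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 1, 2)))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 1, 2)))
        if x.requires_grad:
            scale = gamma.data * inv_std
            if training:
                m = g.shape[0] * g.shape[1] * g.shape[2]
                g_mean = g.mean(axis=(0, 1, 2))
                gx_mean = (g * xhat).sum(axis=(0, 1, 2)) / m
                x._accum(scale * (g - g_mean - xhat * gx_mean))
            else:
                x._accum(scale * g)

    return Tensor._make(out_data, (x, gamma, beta), backward)


def upsample_nearest2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling of an NHWC tensor."""
    n, h, w, c = x.data.shape
    out_data = np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2)

    def backward(g):
        if x.requires_grad:
            gx = g.reshape(n, h, 2, w, 2, c).sum(axis=(2, 4))
            x._accum(gx)

    return Tensor._make(out_data, (x,), backward)
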