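"""Structured tensor operations: convolution, pooling, resampling, shifts.

All arrays are NCHW.  Convolution uses im2col + BLAS matmul; its backward
pass is the standard col2im scatter.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from cropstress.nn.tensor import Tensor

__all__ = [
    "conv2d",
    "maxpool2x2",
    "upsample_bilinear2x",
    "upsample_nearest2x",
    "shift2d",
    "softmax_channels",
]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, pad: int = 0) -> Tensor:
    N, C, H, W = x.shape
    F, C2, KH, KW = w.shape
    if C != C2:
        raise ValueError(f"channel mismatch: input {C}, kernel {C2}")
    xd = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    OH = (H + 2 * pad - KH) // stride + 1
    OW = (W + 2 * pad - KW) // stride + 1
    win = sliding_window_view(xd, (KH, KW), axis=(2, 3))[:, :, ::stride, ::stride]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        N * OH * OW, C * KH * KW
    )
    Wm = w.data.reshape(F, -1)
    val = cols @ Wm.T
    if b is not None:
        val = val + b.data.reshape(1, F)
    val = val.reshape(N, OH, OW, F).transpose(0, 3, 1, 2)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(val, any(p.requires_grad for p in parents), parents)

    def bwd(g):
        gcols = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, F)
        if w.requires_grad:
            w._accum((gcols.T @ cols).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(gcols.sum(axis=0).reshape(b.data.shape))
        if x.requires_grad:
            dcols = (gcols @ Wm).reshape(N, OH, OW, C, KH, KW).transpose(0, 3, 1, 2, 4, 5)
            dxp = np.zeros((N, C, H + 2 * pad, W + 2 * pad))
            for kh in range(KH):
                for kw in range(KW):
                    dxp[:, :, kh : kh + stride * OH : stride,
                        kw : kw + stride * OW : stride] += dcols[:, :, :, :, kh, kw]
            x._accum(dxp[:, :, pad : pad + H, pad : pad + W] if pad else dxp)

    out._backward = bwd
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    N, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2x2 requires even spatial dims")
    r = x.data.reshape(N, C, H // 2, 2, W // 2, 2)
    val = r.max(axis=(3, 5))
    out = Tensor(val, x.requires_grad, (x,))
    mask = r == val[:, :, :, None, :, None]
    # ties share the gradient equally (valid subgradient)
    counts = mask.sum(axis=(3, 5), keepdims=True)

    def bwd(g):
        if x.requires_grad:
            gr = (mask / counts) * g[:, :, :, None, :, None]
            x._accum(gr.reshape(N, C, H, W))

    out._backward = bwd
    return out


def _linear_resample_indices(n_out: int, n_in: int):
    # pixel-center mapping (align_corners = False convention)
    pos = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    i0 = np.floor(pos).astype(np.int64)
    frac = pos - i0
    i0c = np.clip(i0, 0, n_in - 1)
    i1c = np.clip(i0 + 1, 0, n_in - 1)
    return i0c, i1c, 1.0 - frac, frac


def upsample_bilinear2x(x: Tensor) -> Tensor:
    N, C, H, W = x.shape
    r0, r1, wr0, wr1 = _linear_resample_indices(2 * H, H)
    c0, c1, wc0, wc1 = _linear_resample_indices(2 * W, W)
    xh = x.data[:, :, r0, :] * wr0[None, None, :, None] + x.data[:, :, r1, :] * wr1[None, None, :, None]
    val = xh[:, :, :, c0] * wc0[None, None, None, :] + xh[:, :, :, c1] * wc1[None, None, None, :]
    out = Tensor(val, x.requires_grad, (x,))

    def bwd(g):
        if not x.requires_grad:
            return
        gh = np.zeros((N, C, 2 * H, W))
        np.add.at(gh.transpose(3, 0, 1, 2), c0, (g * wc0[None, None, None, :]).transpose(3, 0, 1, 2))
        np.add.at(gh.transpose(3, 0, 1, 2), c1, (g * wc1[None, None, None, :]).transpose(3, 0, 1, 2))
        gx = np.zeros((N, C, H, W))
        np.add.at(gx.transpose(2, 0, 1, 3), r0, (gh * wr0[None, None, :, None]).transpose(2, 0, 1, 3))
        np.add.at(gx.transpose(2, 0, 1, 3), r1, (gh * wr1[None, None, :, None]).transpose(2, 0, 1, 3))
        x._accum(gx)

    out._backward = bwd
    return out


def upsample_nearest2x(x: Tensor) -> Tensor:
    N, C, H, W = x.shape
    val = x.data.repeat(2, axis=2).repeat(2, axis=3)
    out = Tensor(val, x.requires_grad, (x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)))

    out._backward = bwd
    return out


def _shift1d(x: Tensor, offset: int, axis: int) -> Tensor:
    n = x.shape[axis]
    idx = np.clip(np.arange(n) + offset, 0, n - 1)
    out = Tensor(np.take(x.data, idx, axis=axis), x.requires_grad, (x,))

    def bwd(g):
        if x.requires_grad:
            gm = np.moveaxis(g, axis, 0)
            full = np.zeros(np.moveaxis(x.data, axis, 0).shape)
            np.add.at(full, idx, gm)
            x._accum(np.moveaxis(full, 0, axis))

    out._backward = bwd
    return out


def shift2d(x: Tensor, dy: int, dx: int) -> Tensor:
    """Edge-replicated shift of the last two axes (zero-flux boundary)."""
    out = x
    if dy:
        out = _shift1d(out, dy, -2)
    if dx:
        out = _shift1d(out, dx, -1)
    return out


def softmax_channels(x: Tensor) -> Tensor:
    """Numerically stable softmax over the channel axis (axis 1)."""
    shifted = x - Tensor(x.data.max(axis=1, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=1, keepdims=True)
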