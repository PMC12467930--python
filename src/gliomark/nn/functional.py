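"""Differentiable volumetric operations: 3D convolution, trilinear resizing,
non-overlapping patch pooling/merging, dropout.

Convolution uses im2col + BLAS matmul in the forward pass and a 27-slice
col2im accumulation in the backward pass, which keeps both directions fast on
a single CPU without any compiled extension.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, as_tensor

__all__ = [
    "conv3d",
    "patchify",
    "unpatchify",
    "avg_pool3d",
    "upsample_trilinear",
    "resize_trilinear",
    "dropout",
    "embedding_lookup",
]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,C,H,W,D) -> (N, OH*OW*OD, C*k^3) windows for stride-1 convolution."""
    win = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
    n, c, oh, ow, od = win.shape[:5]
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n, oh * ow * od, c * k**3)
    return np.ascontiguousarray(cols), (oh, ow, od)


def conv3d(x: Tensor, weight: Tensor, bias: Tensor | None = None, padding: int | None = None) -> Tensor:
    """Stride-1 3D convolution (cross-correlation).

    x: (N, C, H, W, D); weight: (Co, C, k, k, k); bias: (Co,).
    `padding` defaults to k//2 ("same" for odd k).
    """
    x, weight = as_tensor(x), as_tensor(weight)
    if bias is not None:
        bias = as_tensor(bias)
    co, ci, k = weight.shape[0], weight.shape[1], weight.shape[2]
    if x.shape[1] != ci:
        raise ValueError(f"conv3d: input has {x.shape[1]} channels, kernel expects {ci}")
    p = k // 2 if padding is None else padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    cols, (oh, ow, od) = _im2col(xp, k)
    wmat = weight.data.reshape(co, ci * k**3)
    out = cols @ wmat.T  # (N, O, Co)
    n = x.shape[0]
    out_t = out.transpose(0, 2, 1).reshape(n, co, oh, ow, od)

    def bw(g):
        gmat = g.reshape(n, co, oh * ow * od)  # (N, Co, O)
        # dW: one big BLAS product over all batch entries and voxels
        gw = (
            gmat.transpose(1, 0, 2).reshape(co, -1) @ cols.reshape(-1, ci * k**3)
        ).reshape(weight.shape)
        # dX: col2im via 27 contiguous slice-adds in (N, F, O) layout
        dcols = (wmat.T @ gmat).reshape(n, ci, k, k, k, oh, ow, od)
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    dxp[:, :, i : i + oh, j : j + ow, l : l + od] += dcols[:, :, i, j, l]
        h, w_, d = x.shape[2:]
        gx = dxp[:, :, p : p + h, p : p + w_, p : p + d]
        gb = g.sum(axis=(0, 2, 3, 4)) if bias is not None else None
        return (gx, gw) if bias is None else (gx, gw, gb)

    parents = (x, weight) if bias is None else (x, weight, bias)
    out_tensor = Tensor._make(
        out_t if bias is None else out_t + bias.data.reshape(1, co, 1, 1, 1),
        parents,
        bw,
    )
    return out_tensor


def patchify(x: Tensor, k: int) -> Tensor:
    """Space-to-depth: (N,C,H,W,D) -> (N, C*k^3, H/k, W/k, D/k).

    Exactly the token layout of a kernel-k stride-k convolution; composing
    with a 1x1x1 linear map gives strided ("patch embedding") convolutions.
    """
    n, c, h, w, d = x.shape
    if h % k or w % k or d % k:
        raise ValueError(f"patchify: shape {(h, w, d)} not divisible by {k}")
    t = x.reshape(n, c, h // k, k, w // k, k, d // k, k)
    t = t.transpose(0, 1, 3, 5, 7, 2, 4, 6)  # (N,C,k,k,k,H/k,W/k,D/k)
    return t.reshape(n, c * k**3, h // k, w // k, d // k)


def unpatchify(x: Tensor, k: int) -> Tensor:
    """Inverse of :func:`patchify`."""
    n, ck, h, w, d = x.shape
    c = ck // k**3
    t = x.reshape(n, c, k, k, k, h, w, d)
    t = t.transpose(0, 1, 5, 2, 6, 3, 7, 4)
    return t.reshape(n, c, h * k, w * k, d * k)


def avg_pool3d(x: Tensor, k: int) -> Tensor:
    """Non-overlapping average pooling by factor k."""
    n, c, h, w, d = x.shape
    t = x.reshape(n, c, h // k, k, w // k, k, d // k, k)
    return t.mean(axis=(3, 5, 7))


def _linear_coords(n_out: int, n_in: int, scale: float):
    """Voxel-center-aligned source coordinates for 1-D linear resize."""
    src = (np.arange(n_out) + 0.5) / scale - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    w_hi = src - lo
    return lo, hi, w_hi


def resize_trilinear(x: Tensor, out_shape: tuple[int, int, int]) -> Tensor:
    """Trilinear resize of (N,C,H,W,D) to `out_shape`, voxel centers aligned."""
    x = as_tensor(x)
    n, c, h, w, d = x.shape
    oh, ow, od = out_shape
    ax = [
        _linear_coords(oh, h, oh / h),
        _linear_coords(ow, w, ow / w),
        _linear_coords(od, d, od / d),
    ]
    data = x.data
    out = np.zeros((n, c, oh, ow, od), dtype=data.dtype)
    corner_info = []
    for bi in range(2):
        ih = ax[0][bi]
        wh = ax[0][2] if bi else 1.0 - ax[0][2]
        for bj in range(2):
            iw = ax[1][bj]
            ww = ax[1][2] if bj else 1.0 - ax[1][2]
            for bk in range(2):
                idd = ax[2][bk]
                wd = ax[2][2] if bk else 1.0 - ax[2][2]
                wgt = (
                    wh[:, None, None] * ww[None, :, None] * wd[None, None, :]
                )  # (oh,ow,od)
                out += wgt * data[:, :, ih[:, None, None], iw[None, :, None], idd[None, None, :]]
                corner_info.append((ih, iw, idd, wgt))

    def bw(g):
        gx = np.zeros((n, c, h, w, d), dtype=g.dtype)
        for ih, iw, idd, wgt in corner_info:
            np.add.at(
                gx,
                (
                    slice(None),
                    slice(None),
                    ih[:, None, None],
                    iw[None, :, None],
                    idd[None, None, :],
                ),
                g * wgt,
            )
        return (gx,)

    return Tensor._make(out, (x,), bw)


def upsample_trilinear(x: Tensor, scale: int = 2) -> Tensor:
    n, c, h, w, d = x.shape
    return resize_trilinear(x, (h * scale, w * scale, d * scale))


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return as_tensor(x)
    mask = (rng.random(x.shape) >= rate).astype(x.dtype) / (1.0 - rate)
    return as_tensor(x) * Tensor(mask)


def embedding_lookup(table: Tensor, index: np.ndarray) -> Tensor:
    """Gather rows of `table` (differentiable); used for relative position bias."""
    table = as_tensor(table)

    def bw(g):
        gt = np.zeros_like(table.data)
        np.add.at(gt, index, g)
        return (gt,)

    return Tensor._make(table.data[index], (table,), bw)
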