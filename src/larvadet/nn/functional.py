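"""Differentiable operations.

Feature maps are 4D ``(N, C, H, W)`` throughout; fully connected activations
are 2D ``(N, D)``.  Convolution is im2col + matmul; RoIAlign follows the
usual bilinear-sampling semantics with half-pixel alignment and a fixed
number of samples per output bin.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, as_tensor


# ---------------------------------------------------------------------------
# broadcasting helpers
# ---------------------------------------------------------------------------

def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data + b.data, parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.data.shape))

    out._bwd = bwd
    return out


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data * b.data, parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * a.data, b.data.shape))

    out._bwd = bwd
    return out


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(x.data * mask, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x.accumulate(g * mask)

    out._bwd = bwd
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x.accumulate(g * s * (1.0 - s))

    out._bwd = bwd
    return out


# ---------------------------------------------------------------------------
# shape ops
# ---------------------------------------------------------------------------

def reshape(x: Tensor, shape) -> Tensor:
    old = x.data.shape
    out = Tensor(x.data.reshape(shape), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x.accumulate(g.reshape(old))

    out._bwd = bwd
    return out


def transpose(x: Tensor, axes) -> Tensor:
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    out = Tensor(x.data.transpose(axes), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x.accumulate(g.transpose(inv))

    out._bwd = bwd
    return out


def concat(xs, axis=1) -> Tensor:
    xs = [as_tensor(x) for x in xs]
    sizes = [x.data.shape[axis] for x in xs]
    out = Tensor(np.concatenate([x.data for x in xs], axis=axis), parents=tuple(xs))
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for x, a, b in zip(xs, offsets[:-1], offsets[1:]):
            if x.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                x.accumulate(g[tuple(sl)])

    out._bwd = bwd
    return out


def slice_channels(x: Tensor, a: int, b: int) -> Tensor:
    out = Tensor(x.data[:, a:b], parents=(x,))

    def bwd(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            full[:, a:b] = g
            x.accumulate(full)

    out._bwd = bwd
    return out


def take_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows of a 2D tensor (with repetition allowed)."""
    idx = np.asarray(idx, dtype=np.intp)
    out = Tensor(x.data[idx], parents=(x,))

    def bwd(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            np.add.at(full, idx, g)
            x.accumulate(full)

    out._bwd = bwd
    return out


def select_per_row(x: Tensor, col_idx: np.ndarray, width: int = 4) -> Tensor:
    """From ``x`` of shape (n, K*width) pick the ``width`` columns starting at
    ``col_idx[i]*width`` for each row i.  Used for per-class box deltas."""
    n = x.data.shape[0]
    rows = np.arange(n)[:, None]
    cols = np.asarray(col_idx, dtype=np.intp)[:, None] * width + np.arange(width)[None, :]
    out = Tensor(x.data[rows, cols], parents=(x,))

    def bwd(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            np.add.at(full, (rows, cols), g)
            x.accumulate(full)

    out._bwd = bwd
    return out


def sum_(x: Tensor) -> Tensor:
    out = Tensor(x.data.sum(), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x.accumulate(np.full_like(x.data, float(g)))

    out._bwd = bwd
    return out


def mean_(x: Tensor) -> Tensor:
    n = x.data.size
    out = Tensor(x.data.mean(), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x.accumulate(np.full_like(x.data, float(g) / n))

    out._bwd = bwd
    return out


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, *, stride: int = 1,
           padding: int = 0, dilation: int = 1) -> Tensor:
    """2D convolution on (N, C, H, W) with square stride/padding/dilation."""
    if dilation < 1:
        raise ValueError(f"dilation must be >= 1, got {dilation}")
    N, C, H, W = x.data.shape
    Co, Ci, kh, kw = w.data.shape
    if Ci != C:
        raise ValueError(f"channel mismatch: input {C}, kernel expects {Ci}")
    s, p, d = stride, padding, dilation
    eh, ew = (kh - 1) * d + 1, (kw - 1) * d + 1
    Ho = (H + 2 * p - eh) // s + 1
    Wo = (W + 2 * p - ew) // s + 1
    if Ho < 1 or Wo < 1:
        raise ValueError("empty spatial extent after convolution")

    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    v = sliding_window_view(xp, (eh, ew), axis=(2, 3))  # (N,C,H',W',eh,ew)
    v = v[:, :, ::s, ::s][:, :, :Ho, :Wo, ::d, ::d]     # (N,C,Ho,Wo,kh,kw)
    cols = np.ascontiguousarray(v.transpose(0, 1, 4, 5, 2, 3)).reshape(
        N, C * kh * kw, Ho * Wo)
    Wm = w.data.reshape(Co, C * kh * kw)
    out_data = np.einsum("ok,nkl->nol", Wm, cols, optimize=True).reshape(N, Co, Ho, Wo)
    if b is not None:
        out_data = out_data + b.data.reshape(1, Co, 1, 1)

    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, parents=parents)

    def bwd(g):
        gm = g.reshape(N, Co, Ho * Wo)
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            dW = np.einsum("nol,nkl->ok", gm, cols, optimize=True)
            w.accumulate(dW.reshape(w.data.shape))
        if x.requires_grad:
            dcols = np.einsum("ok,nol->nkl", Wm, gm, optimize=True).reshape(
                N, C, kh, kw, Ho, Wo)
            dxp = np.zeros((N, C, H + 2 * p, W + 2 * p))
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i * d:i * d + Ho * s:s, j * d:j * d + Wo * s:s] += \
                        dcols[:, :, i, j]
            x.accumulate(dxp[:, :, p:p + H, p:p + W] if p else dxp)

    out._bwd = bwd
    return out


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Affine map on (N, Din) with weight (Dout, Din)."""
    out_data = x.data @ w.data.T
    if b is not None:
        out_data = out_data + b.data
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, parents=parents)

    def bwd(g):
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=0))
        if w.requires_grad:
            w.accumulate(g.T @ x.data)
        if x.requires_grad:
            x.accumulate(g @ w.data)

    out._bwd = bwd
    return out


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resize_nearest(x: Tensor, out_hw) -> Tensor:
    """Nearest-neighbour resize of (N,C,H,W); exact 2x repeat when doubling."""
    N, C, H, W = x.data.shape
    Ho, Wo = out_hw
    iy = (np.arange(Ho) * H) // Ho
    ix = (np.arange(Wo) * W) // Wo
    out = Tensor(x.data[:, :, iy][:, :, :, ix], parents=(x,))

    def bwd(g):
        if x.requires_grad:
            t = np.zeros((N, C, Ho, W))
            np.add.at(t, (slice(None), slice(None), slice(None), ix), g)
            full = np.zeros((N, C, H, W))
            np.add.at(full, (slice(None), slice(None), iy, slice(None)), t)
            x.accumulate(full)

    out._bwd = bwd
    return out


def subsample2(x: Tensor) -> Tensor:
    """Stride-2 spatial subsampling (used to derive the extra proposal level)."""
    out = Tensor(x.data[:, :, ::2, ::2], parents=(x,))

    def bwd(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            full[:, :, ::2, ::2] = g
            x.accumulate(full)

    out._bwd = bwd
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C,1,1)."""
    N, C, H, W = x.data.shape
    out = Tensor(x.data.mean(axis=(2, 3), keepdims=True), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x.accumulate(np.broadcast_to(g / (H * W), x.data.shape))

    out._bwd = bwd
    return out


def broadcast_hw(x: Tensor, out_hw) -> Tensor:
    """Broadcast (N,C,1,1) across a spatial extent."""
    N, C = x.data.shape[:2]
    Ho, Wo = out_hw
    out = Tensor(np.broadcast_to(x.data, (N, C, Ho, Wo)).copy(), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x.accumulate(g.sum(axis=(2, 3), keepdims=True))

    out._bwd = bwd
    return out


# ---------------------------------------------------------------------------
# RoIAlign
# ---------------------------------------------------------------------------

def roi_align(fm: Tensor, boxes: np.ndarray, *, spatial_scale: float,
              out_size: int = 7, sampling: int = 2) -> Tensor:
    """Pool each box into an ``out_size``² patch by averaging bilinear samples.

    ``fm`` is (1, C, H, W); ``boxes`` is (n, 4) in image coordinates
    (x1, y1, x2, y2).  Uses half-pixel alignment and ``sampling``² samples
    per bin.  Boxes are treated as constants (no gradient w.r.t. geometry).
    """
    boxes = np.asarray(boxes, dtype=np.float64)
    n = boxes.shape[0]
    _, C, H, W = fm.data.shape
    if np.any(boxes[:, 2] <= boxes[:, 0]) or np.any(boxes[:, 3] <= boxes[:, 1]):
        raise ValueError("degenerate box passed to roi_align")
    o, ns = out_size, sampling

    x1 = boxes[:, 0] * spatial_scale - 0.5
    y1 = boxes[:, 1] * spatial_scale - 0.5
    bw = np.maximum((boxes[:, 2] - boxes[:, 0]) * spatial_scale, 1e-6) / o
    bh = np.maximum((boxes[:, 3] - boxes[:, 1]) * spatial_scale, 1e-6) / o

    # sample coordinates: (n, o, ns)
    offs = (np.arange(ns) + 0.5) / ns
    sy = y1[:, None, None] + (np.arange(o)[None, :, None] + offs[None, None, :]) * bh[:, None, None]
    sx = x1[:, None, None] + (np.arange(o)[None, :, None] + offs[None, None, :]) * bw[:, None, None]

    # full grid (n, o, ns, o, ns) for y × x
    Y = np.broadcast_to(sy[:, :, :, None, None], (n, o, ns, o, ns))
    X = np.broadcast_to(sx[:, None, None, :, :], (n, o, ns, o, ns))
    Yf, Xf = Y.reshape(-1), X.reshape(-1)

    Yc = np.clip(Yf, 0.0, H - 1.0)
    Xc = np.clip(Xf, 0.0, W - 1.0)
    y0 = np.floor(Yc).astype(np.intp)
    x0 = np.floor(Xc).astype(np.intp)
    y1i = np.minimum(y0 + 1, H - 1)
    x1i = np.minimum(x0 + 1, W - 1)
    wy1 = Yc - y0
    wx1 = Xc - x0
    wy0 = 1.0 - wy1
    wx0 = 1.0 - wx1
    # samples that fall entirely outside the map contribute zero
    valid = (Yf > -1.0) & (Yf < H) & (Xf > -1.0) & (Xf < W)
    w00 = wy0 * wx0 * valid
    w01 = wy0 * wx1 * valid
    w10 = wy1 * wx0 * valid
    w11 = wy1 * wx1 * valid

    f = fm.data[0].reshape(C, H * W)  # (C, HW)
    i00, i01 = y0 * W + x0, y0 * W + x1i
    i10, i11 = y1i * W + x0, y1i * W + x1i
    vals = (f[:, i00] * w00 + f[:, i01] * w01 +
            f[:, i10] * w10 + f[:, i11] * w11)          # (C, P)
    out_data = vals.reshape(C, n, o, ns, o, ns).mean(axis=(3, 5)).transpose(1, 0, 2, 3)

    out = Tensor(out_data, parents=(fm,))

    def bwd(g):
        if not fm.requires_grad:
            return
        # (n,C,o,o) -> per-sample gradient (C,P)
        gs = (g.transpose(1, 0, 2, 3)[:, :, :, None, :, None] / (ns * ns))
        gs = np.broadcast_to(gs, (C, n, o, ns, o, ns)).reshape(C, -1)
        dflat = np.zeros(C * H * W)
        choff = (np.arange(C) * (H * W))[:, None]
        for idx, wgt in ((i00, w00), (i01, w01), (i10, w10), (i11, w11)):
            dflat += np.bincount((choff + idx[None, :]).ravel(),
                                 weights=(gs * wgt[None, :]).ravel(),
                                 minlength=C * H * W)
        fm.accumulate(dflat.reshape(1, C, H, W))

    out._bwd = bwd
    return out


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy over rows; labels are integer class indices."""
    labels = np.asarray(labels, dtype=np.intp)
    n = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - lse
    loss = -logp[np.arange(n), labels].mean()
    out = Tensor(loss, parents=(logits,))

    def bwd(g):
        if logits.requires_grad:
            p = np.exp(logp)
            p[np.arange(n), labels] -= 1.0
            logits.accumulate(float(g) * p / n)

    out._bwd = bwd
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on a 1D logit vector."""
    t = np.asarray(targets, dtype=np.float64)
    z = logits.data
    loss = (np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))).mean()
    out = Tensor(loss, parents=(logits,))

    def bwd(g):
        if logits.requires_grad:
            s = 1.0 / (1.0 + np.exp(-z))
            logits.accumulate(float(g) * (s - t) / z.size)

    out._bwd = bwd
    return out


def smooth_l1(x):
    """Elementwise Smooth L1: 0.5 x² for |x| < 1, |x| − 0.5 otherwise."""
    x = np.asarray(x, dtype=np.float64)
    ax = np.abs(x)
    return np.where(ax < 1.0, 0.5 * x * x, ax - 0.5)


def smooth_l1_loss(pred: Tensor, target: np.ndarray, *, normalizer: float) -> Tensor:
    """Sum of elementwise Smooth L1 divided by ``normalizer``."""
    t = np.asarray(target, dtype=np.float64)
    diff = pred.data - t
    loss = smooth_l1(diff).sum() / normalizer
    out = Tensor(loss, parents=(pred,))

    def bwd(g):
        if pred.requires_grad:
            d = np.clip(diff, -1.0, 1.0)
            pred.accumulate(float(g) * d / normalizer)

    out._bwd = bwd
    return out
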