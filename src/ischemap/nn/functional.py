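"""Differentiable primitives: convolutions, warping, nonlinearities, losses.

Layout conventions follow the usual NCHW ordering.  Convolution weights are
``(C_out, C_in, kh, kw)``; transposed-convolution weights ``(C_in, C_out,
kh, kw)``.  Displacement fields are ``(N, 2, H, W)`` with channel 0 = Δrow,
channel 1 = Δcol, in pixels, added to target coordinates when sampling the
source (border replication outside bounds).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

from ischemap.nn.autograd import Tensor


# ---------------------------------------------------------------------------
# pointwise
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    m = x.data > 0
    return Tensor._op(np.where(m, x.data, 0.0), (x,),
                      lambda g: x._accumulate(np.where(m, g, 0.0)))


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    m = x.data > 0
    return Tensor._op(np.where(m, x.data, slope * x.data), (x,),
                      lambda g: x._accumulate(np.where(m, g, slope * g)))


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)
    return Tensor._op(y, (x,), lambda g: x._accumulate(g * (1.0 - y * y)))


def sigmoid(x: Tensor) -> Tensor:
    y = expit(x.data)
    return Tensor._op(y, (x,), lambda g: x._accumulate(g * y * (1.0 - y)))


def softplus(x: Tensor) -> Tensor:
    """log(1 + exp(x)), numerically stable."""
    y = np.logaddexp(0.0, x.data)
    return Tensor._op(y, (x,), lambda g: x._accumulate(g * expit(x.data)))


def abs_(x: Tensor) -> Tensor:
    s = np.sign(x.data)
    return Tensor._op(np.abs(x.data), (x,), lambda g: x._accumulate(g * s))


def sqrt(x: Tensor) -> Tensor:
    y = np.sqrt(x.data)
    return Tensor._op(y, (x,), lambda g: x._accumulate(g * 0.5 / y))


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._op(data, tensors, bw)


# ---------------------------------------------------------------------------
# convolution machinery
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    """Windows of an already-padded NCHW array -> (N, C, Ho, Wo, kh, kw)."""
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return win[:, :, ::sh, ::sw]


def _col2im_add(t: np.ndarray, out_shape, sh: int, sw: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add (N, Ho, Wo, C, kh, kw) windows."""
    n, ho, wo, c, kh, kw = t.shape
    out = np.zeros(out_shape, dtype=t.dtype)
    tt = t.transpose(0, 3, 1, 2, 4, 5)  # N,C,Ho,Wo,kh,kw
    for i in range(kh):
        for j in range(kw):
            out[:, :, i:i + sh * ho:sh, j:j + sw * wo:sw] += tt[:, :, :, :, i, j]
    return out


def _flatten_cols(cols: np.ndarray) -> np.ndarray:
    """(N, C, Ho, Wo, kh, kw) windows -> contiguous (N·Ho·Wo, C·kh·kw)."""
    n, c, ho, wo, kh, kw = cols.shape
    return np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * ho * wo, c * kh * kw)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None,
           stride: int = 1, padding: int = 0) -> Tensor:
    s, p = stride, padding
    co, ci, kh, kw = w.data.shape
    n = x.data.shape[0]
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    cols = _im2col(xp, kh, kw, s, s)                       # N,C,Ho,Wo,kh,kw
    ho, wo = cols.shape[2], cols.shape[3]
    colsf = _flatten_cols(cols)                            # (NHoWo, Ckhkw)
    wf = w.data.reshape(co, -1)
    y = (colsf @ wf.T).reshape(n, ho, wo, co).transpose(0, 3, 1, 2)
    y = np.ascontiguousarray(y)
    if b is not None:
        y += b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        gf = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, co)
        if w.requires_grad:
            w._accumulate((gf.T @ colsf).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(gf.sum(axis=0))
        if x.requires_grad:
            t = (gf @ wf).reshape(n, ho, wo, ci, kh, kw)
            dxp = _col2im_add(t, xp.shape, s, s)
            x._accumulate(dxp[:, :, p:xp.shape[2] - p, p:xp.shape[3] - p]
                          if p else dxp)

    return Tensor._op(y, parents, bw)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None,
                     stride: int = 2, padding: int = 1) -> Tensor:
    s, p = stride, padding
    ci, co, kh, kw = w.data.shape
    n, _, hi, wi = x.data.shape
    xf = np.ascontiguousarray(x.data.transpose(0, 2, 3, 1)).reshape(-1, ci)
    wf = w.data.reshape(ci, -1)                            # (Ci, Co·kh·kw)
    t = (xf @ wf).reshape(n, hi, wi, co, kh, kw)
    full = ((hi - 1) * s + kh, (wi - 1) * s + kw)
    ypad = _col2im_add(t, (n, co, *full), s, s)
    y = ypad[:, :, p:full[0] - p, p:full[1] - p] if p else ypad
    y = np.ascontiguousarray(y)
    if b is not None:
        y += b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        gp = np.pad(g, ((0, 0), (0, 0), (p, p), (p, p))) if p else g
        dtf = _flatten_cols(_im2col(gp, kh, kw, s, s))     # (NHiWi, Cokhkw)
        if x.requires_grad:
            dx = (dtf @ wf.T).reshape(n, hi, wi, ci)
            x._accumulate(np.ascontiguousarray(dx.transpose(0, 3, 1, 2)))
        if w.requires_grad:
            w._accumulate((xf.T @ dtf).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    return Tensor._op(y, parents, bw)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    f = factor
    y = x.data.repeat(f, axis=2).repeat(f, axis=3)
    n, c, h, w = x.data.shape

    def bw(g):
        x._accumulate(g.reshape(n, c, h, f, w, f).sum(axis=(3, 5)))

    return Tensor._op(y, (x,), bw)


def avg_pool2d(x: Tensor, k: int) -> Tensor:
    n, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError(f"avg_pool2d: {h}x{w} not divisible by {k}")
    y = x.data.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def bw(g):
        gg = np.broadcast_to(g[:, :, :, None, :, None] / (k * k),
                             (n, c, h // k, k, w // k, k))
        x._accumulate(gg.reshape(n, c, h, w))

    return Tensor._op(y, (x,), bw)


def warp_bilinear(img: Tensor, field: Tensor) -> Tensor:
    """Sample ``img`` at (r + Δrow, c + Δcol) with bilinear interpolation.

    Border replication outside bounds; differentiable w.r.t. both the image
    and the displacement field (field gradients vanish where sampling is
    clamped to the border).
    """
    n, c, h, w = img.data.shape
    if field.data.shape != (n, 2, h, w):
        raise ValueError("field shape must be (N, 2, H, W) matching the image")
    dt = field.data.dtype
    rows = np.arange(h, dtype=dt)[None, :, None]
    cols = np.arange(w, dtype=dt)[None, None, :]
    r = rows + field.data[:, 0]
    cc = cols + field.data[:, 1]
    in_r = (r >= 0.0) & (r <= h - 1.0)
    in_c = (cc >= 0.0) & (cc <= w - 1.0)
    r = np.clip(r, 0.0, h - 1.0)
    cc = np.clip(cc, 0.0, w - 1.0)
    r0 = np.minimum(np.floor(r), h - 2).astype(np.intp)
    c0 = np.minimum(np.floor(cc), w - 2).astype(np.intp)
    fr = r - r0
    fc = cc - c0
    nn = np.arange(n)[:, None, None]
    i00 = img.data[nn, :, r0, c0].transpose(0, 3, 1, 2)
    i01 = img.data[nn, :, r0, c0 + 1].transpose(0, 3, 1, 2)
    i10 = img.data[nn, :, r0 + 1, c0].transpose(0, 3, 1, 2)
    i11 = img.data[nn, :, r0 + 1, c0 + 1].transpose(0, 3, 1, 2)
    w00 = ((1 - fr) * (1 - fc))[:, None]
    w01 = ((1 - fr) * fc)[:, None]
    w10 = (fr * (1 - fc))[:, None]
    w11 = (fr * fc)[:, None]
    y = w00 * i00 + w01 * i01 + w10 * i10 + w11 * i11

    def bw(g):
        if img.requires_grad:
            dimg = np.zeros_like(img.data)
            nb = np.broadcast_to(nn[:, None], (n, c, h, w))
            cb = np.broadcast_to(np.arange(c)[None, :, None, None], (n, c, h, w))
            for wgt, rr, ccx in ((w00, r0, c0), (w01, r0, c0 + 1),
                                 (w10, r0 + 1, c0), (w11, r0 + 1, c0 + 1)):
                np.add.at(dimg, (nb, cb,
                                 np.broadcast_to(rr[:, None], (n, c, h, w)),
                                 np.broadcast_to(ccx[:, None], (n, c, h, w))),
                          g * wgt)
            img._accumulate(dimg)
        if field.requires_grad:
            d_dr = ((1 - fc)[:, None] * (i10 - i00) + fc[:, None] * (i11 - i01))
            d_dc = ((1 - fr)[:, None] * (i01 - i00) + fr[:, None] * (i11 - i10))
            gr = (g * d_dr).sum(axis=1) * in_r
            gc = (g * d_dc).sum(axis=1) * in_c
            field._accumulate(np.stack([gr, gc], axis=1))

    return Tensor._op(y, (img, field), bw)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def l1_loss(a: Tensor, b: Tensor) -> Tensor:
    """Mean absolute difference."""
    return abs_(a - b).mean()


def bce_with_logits(logits: Tensor, target: float) -> Tensor:
    """Binary cross-entropy on raw scores against a constant label (0 or 1)."""
    t = float(target)
    return (softplus(logits) - logits * t).mean()
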