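"""Minimal reverse-mode automatic differentiation over numpy arrays.

Only the operations the generator and its losses need are implemented:
elementwise arithmetic, ReLU, |x|, reductions, stride-1 (dilated) 2-D
convolution, 2x2 max pooling with ceil semantics, bilinear upsampling and
channel concatenation.  Convolution is evaluated as k*k accumulated
``tensordot`` contractions so the heavy lifting stays inside BLAS.

Gradient correctness is enforced by finite-difference tests; every backward
closure below is hand-derived.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return mul(self, -1.0)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray):
    # gradients are only ever rebound, never mutated in place, so holding a
    # view here is safe
    if not t.requires_grad:
        return
    t.grad = g if t.grad is None else t.grad + g


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    if g.shape == tuple(shape):
        return g
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# -- elementwise ----------------------------------------------------------
def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def bw(g):
        _accum(a, _unbroadcast(g, a.shape))
        _accum(b, _unbroadcast(g, b.shape))

    return _node(out_data, (a, b), bw)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def bw(g):
        _accum(a, _unbroadcast(g * b.data, a.shape))
        _accum(b, _unbroadcast(g * a.data, b.shape))

    return _node(out_data, (a, b), bw)


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data / b.data

    def bw(g):
        _accum(a, _unbroadcast(g / b.data, a.shape))
        _accum(b, _unbroadcast(-g * a.data / (b.data * b.data), b.shape))

    return _node(out_data, (a, b), bw)


def relu(a) -> Tensor:
    a = as_tensor(a)
    pos = a.data > 0
    out_data = np.where(pos, a.data, 0)

    def bw(g):
        _accum(a, g * pos)

    return _node(out_data, (a,), bw)


def absolute(a) -> Tensor:
    a = as_tensor(a)
    sgn = np.sign(a.data)

    def bw(g):
        _accum(a, g * sgn)

    return _node(np.abs(a.data), (a,), bw)


def tsum(a) -> Tensor:
    a = as_tensor(a)

    def bw(g):
        _accum(a, np.broadcast_to(g, a.shape).astype(a.dtype, copy=False))

    return _node(np.asarray(a.data.sum()), (a,), bw)


def tmean(a) -> Tensor:
    a = as_tensor(a)
    n = a.data.size

    def bw(g):
        _accum(a, np.broadcast_to(g / n, a.shape).astype(a.dtype, copy=False))

    return _node(np.asarray(a.data.mean()), (a,), bw)


def channel_slice(a, start: int, stop: int) -> Tensor:
    """Slice channels (axis 1) of an (N, C, H, W) tensor."""
    a = as_tensor(a)

    def bw(g):
        full = np.zeros_like(a.data)
        full[:, start:stop] = g
        _accum(a, full)

    return _node(a.data[:, start:stop], (a,), bw)


def concat(tensors: Sequence, axis: int = 1) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in ts]
    out_data = np.concatenate([t.data for t in ts], axis=axis)

    def bw(g):
        offset = 0
        for t, s in zip(ts, sizes):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(offset, offset + s)
            _accum(t, g[tuple(sl)])
            offset += s

    return _node(out_data, tuple(ts), bw)


# -- convolution ----------------------------------------------------------
def conv2d(x, w, b=None, dilation: int = 1, padding: str = "same") -> Tensor:
    """Stride-1 2-D convolution (cross-correlation) on (N, C, H, W).

    ``padding='same'`` keeps the spatial shape for odd kernels; ``'valid'``
    performs no padding.  ``dilation`` spaces the kernel taps.
    """
    x, w = as_tensor(x), as_tensor(w)
    xd, wd = x.data, w.data
    N, C, H, W = xd.shape
    O, C2, kh, kw = wd.shape
    if C2 != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {C2}")
    d = int(dilation)
    if padding == "same":
        ph, pw = d * (kh // 2), d * (kw // 2)
    elif padding == "valid":
        ph = pw = 0
    else:
        raise ValueError(f"unknown padding {padding!r}")
    Ho = H + 2 * ph - d * (kh - 1)
    Wo = W + 2 * pw - d * (kw - 1)
    if Ho < 1 or Wo < 1:
        raise ValueError(f"conv2d: kernel {kh}x{kw} dilation {d} exceeds input {H}x{W}")
    xp = np.pad(xd, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else xd

    def _col():
        # im2col: one (N*Ho*Wo, C*kh*kw) matrix so the whole conv is one GEMM
        s = xp.strides
        win = np.lib.stride_tricks.as_strided(
            xp, shape=(N, C, Ho, Wo, kh, kw),
            strides=(s[0], s[1], s[2], s[3], s[2] * d, s[3] * d))
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(N * Ho * Wo, C * kh * kw)

    Wmat = wd.reshape(O, C * kh * kw)
    out_data = np.ascontiguousarray(
        (_col() @ Wmat.T).reshape(N, Ho, Wo, O).transpose(0, 3, 1, 2))
    if b is not None:
        b = as_tensor(b)
        out_data += b.data.reshape(1, -1, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        gl = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(N * Ho * Wo, O)
        if w.requires_grad:
            _accum(w, (gl.T @ _col()).reshape(wd.shape))
        if x.requires_grad:
            dcol = (gl @ Wmat).reshape(N, Ho, Wo, C, kh, kw)
            Hp, Wp = H + 2 * ph, W + 2 * pw
            dxp = np.zeros((N, Hp, Wp, C), dtype=xd.dtype)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, i * d:i * d + Ho, j * d:j * d + Wo, :] += dcol[:, :, :, :, i, j]
            dx = dxp.transpose(0, 3, 1, 2)
            if ph or pw:
                dx = dx[:, :, ph:ph + H, pw:pw + W]
            _accum(x, np.ascontiguousarray(dx))
        if b is not None and b.requires_grad:
            _accum(b, gl.sum(axis=0).reshape(b.shape))

    return _node(out_data, parents, bw)


def box_mean_valid(x, window: int) -> Tensor:
    """Mean over every window x window patch ('valid' positions), via integral
    images — the uniform-window filter behind the sliding-window SSIM."""
    x = as_tensor(x)
    xd = x.data
    H, W = xd.shape[-2:]
    win = int(window)
    if win > min(H, W):
        raise ValueError(f"box window {win} exceeds input {H}x{W}")
    inv = 1.0 / (win * win)

    def _sums(a):
        c = np.pad(a.astype(np.float64).cumsum(-2).cumsum(-1),
                   [(0, 0)] * (a.ndim - 2) + [(1, 0), (1, 0)])
        return (c[..., win:, win:] - c[..., :-win, win:]
                - c[..., win:, :-win] + c[..., :-win, :-win])

    out_data = (_sums(xd) * inv).astype(xd.dtype)

    def bw(g):
        # adjoint of a box sum is the box sum of the zero-padded gradient
        gp = np.pad(g, [(0, 0)] * (g.ndim - 2) + [(win - 1, win - 1)] * 2)
        _accum(x, (_sums(gp) * inv).astype(xd.dtype))

    return _node(out_data, (x,), bw)


# -- pooling / resampling -------------------------------------------------
def maxpool2(x) -> Tensor:
    """2x2 stride-2 max pooling with ceil semantics (odd sides round up)."""
    x = as_tensor(x)
    xd = x.data
    N, C, H, W = xd.shape
    H2, W2 = math.ceil(H / 2), math.ceil(W / 2)
    if (H, W) != (2 * H2, 2 * W2):
        pad_val = -np.inf if np.issubdtype(xd.dtype, np.floating) else np.iinfo(xd.dtype).min
        xp = np.full((N, C, 2 * H2, 2 * W2), pad_val, dtype=xd.dtype)
        xp[:, :, :H, :W] = xd
    else:
        xp = xd
    v = xp.reshape(N, C, H2, 2, W2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H2, W2, 4)
    idx = v.argmax(axis=-1)
    out_data = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        gv = np.zeros((N, C, H2, W2, 4), dtype=g.dtype)
        np.put_along_axis(gv, idx[..., None], g[..., None], axis=-1)
        gx = gv.reshape(N, C, H2, W2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, 2 * H2, 2 * W2)
        _accum(x, np.ascontiguousarray(gx[:, :, :H, :W]))

    return _node(out_data, (x,), bw)


_INTERP_CACHE: dict = {}


def _interp_matrix(n_out: int, n_in: int, dtype) -> np.ndarray:
    key = (n_out, n_in, np.dtype(dtype).str)
    m = _INTERP_CACHE.get(key)
    if m is not None:
        return m
    A = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        A[:, 0] = 1
    else:
        # half-pixel-centre convention (align_corners=False)
        s = np.clip((np.arange(n_out) + 0.5) * n_in / n_out - 0.5, 0, n_in - 1)
        i0 = np.floor(s).astype(int)
        i1 = np.minimum(i0 + 1, n_in - 1)
        f = (s - i0).astype(dtype)
        np.add.at(A, (np.arange(n_out), i0), 1 - f)
        np.add.at(A, (np.arange(n_out), i1), f)
    _INTERP_CACHE[key] = A
    return A


def upsample_bilinear(x, size) -> Tensor:
    """Bilinear resize of (N, C, H, W) to spatial ``size`` = (Ho, Wo)."""
    x = as_tensor(x)
    N, C, H, W = x.shape
    Ho, Wo = int(size[0]), int(size[1])
    A = _interp_matrix(Ho, H, x.dtype)   # (Ho, H)
    B = _interp_matrix(Wo, W, x.dtype)   # (Wo, W)
    out_data = np.matmul(A, x.data @ B.T)

    def bw(g):
        _accum(x, np.ascontiguousarray(np.matmul(A.T, g @ B)))

    return _node(out_data, (x,), bw)


# -- batch normalisation --------------------------------------------------
def batchnorm2d_train(x, gamma, beta, eps: float = 1e-5):
    """Batch-statistics normalisation over (N, H, W) per channel.

    Returns ``(out, batch_mean, batch_var)``; the caller owns running-stat
    bookkeeping.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    xd = x.data
    axes = (0, 2, 3)
    M = xd.shape[0] * xd.shape[2] * xd.shape[3]
    mu = xd.mean(axis=axes, keepdims=True)
    var = xd.var(axis=axes, keepdims=True)
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu) * invstd
    gd = gamma.data.reshape(1, -1, 1, 1)
    out_data = gd * xhat + beta.data.reshape(1, -1, 1, 1)

    def bw(g):
        if gamma.requires_grad:
            _accum(gamma, (g * xhat).sum(axis=axes).reshape(gamma.shape))
        if beta.requires_grad:
            _accum(beta, g.sum(axis=axes).reshape(beta.shape))
        if x.requires_grad:
            dxhat = g * gd
            t1 = dxhat.sum(axis=axes, keepdims=True)
            t2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
            _accum(x, (invstd / M) * (M * dxhat - t1 - xhat * t2))

    out = _node(out_data, (x, gamma, beta), bw)
    return out, mu.reshape(-1), var.reshape(-1)
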