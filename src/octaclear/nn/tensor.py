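"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This module provides the small set of differentiable operations needed by
the de-striping and enhancement networks: elementwise arithmetic,
reductions, 2-D convolution, pooling/upsampling, instance normalization and
singular-value soft-thresholding.  Gradients are accumulated on a dynamic
tape; calling :meth:`Tensor.backward` on a scalar walks the tape in reverse
topological order.

All computation is in float64.  The implementation favours clarity and
numerical robustness over raw speed; the networks in this package are sized
for a single CPU.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "sub",
    "mul",
    "div",
    "concat",
    "conv2d",
    "instance_norm",
    "leaky_relu",
    "maxpool2",
    "relu",
    "svd_shrink",
    "upsample2",
]


class Tensor:
    """A NumPy array carrying an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], Sequence[np.ndarray | None]] | None = None

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    # -- autodiff ------------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return getitem(self, idx)

    # -- reductions / elementwise helpers exposed as methods -----------------
    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def abs(self):
        return tabs(self)

    def sqrt(self):
        return tsqrt(self)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, axes):
        return transpose(self, axes)

    def clip(self, lo, hi):
        return clip(self, lo, hi)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient down to the shape of the broadcast input."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data

    def backward(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

    return _make(data, (a, b), backward)


def sub(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data - b.data

    def backward(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(-g, b.data.shape)

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data

    def backward(g):
        return (
            _unbroadcast(g * b.data, a.data.shape),
            _unbroadcast(g * a.data, b.data.shape),
        )

    return _make(data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data / b.data

    def backward(g):
        return (
            _unbroadcast(g / b.data, a.data.shape),
            _unbroadcast(-g * a.data / (b.data**2), b.data.shape),
        )

    return _make(data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    data = a.data**p

    def backward(g):
        return (g * p * a.data ** (p - 1),)

    return _make(data, (a,), backward)


def tabs(a) -> Tensor:
    a = as_tensor(a)
    data = np.abs(a.data)

    def backward(g):
        return (g * np.sign(a.data),)

    return _make(data, (a,), backward)


def tsqrt(a) -> Tensor:
    """Elementwise square root; the gradient is guarded at zero."""
    a = as_tensor(a)
    data = np.sqrt(a.data)

    def backward(g):
        return (g * 0.5 / np.maximum(data, 1e-12),)

    return _make(data, (a,), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    data = np.where(mask, a.data, 0.0)

    def backward(g):
        return (g * mask,)

    return _make(data, (a,), backward)


def leaky_relu(a, alpha: float = 0.2) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    data = np.where(mask, a.data, alpha * a.data)

    def backward(g):
        return (g * np.where(mask, 1.0, alpha),)

    return _make(data, (a,), backward)


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp to [lo, hi]; the subgradient is zero outside the open interval."""
    a = as_tensor(a)
    data = np.clip(a.data, lo, hi)
    mask = (a.data > lo) & (a.data < hi)

    def backward(g):
        return (g * mask,)

    return _make(data, (a,), backward)


# ---------------------------------------------------------------------------
# reductions, shape manipulation
# ---------------------------------------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            return (np.broadcast_to(g, a.data.shape).copy(),)
        g2 = g
        if not keepdims:
            g2 = np.expand_dims(g, axis)
        return (np.broadcast_to(g2, a.data.shape).copy(),)

    return _make(data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    data = a.data.reshape(shape)

    def backward(g):
        return (g.reshape(a.data.shape),)

    return _make(data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        return (g.transpose(inv),)

    return _make(data, (a,), backward)


def getitem(a, idx) -> Tensor:
    a = as_tensor(a)
    data = a.data[idx]

    def backward(g):
        out = np.zeros_like(a.data)
        out[idx] += g
        return (out,)

    return _make(data, (a,), backward)


def concat(tensors: Sequence, axis: int = 1) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return _make(data, ts, backward)


# ---------------------------------------------------------------------------
# neural-network structured ops
# ---------------------------------------------------------------------------

def conv2d(x, w, b, stride: int = 1, pad: int = 1) -> Tensor:
    """2-D convolution (cross-correlation) over NCHW input.

    ``x``: (B, Cin, H, W); ``w``: (Cout, Cin, k, k); ``b``: (Cout,).
    Zero padding of ``pad`` pixels on each spatial border.
    """
    x, w, b = as_tensor(x), as_tensor(w), as_tensor(b)
    B, Cin, H, W = x.data.shape
    Cout, Cin2, k, _ = w.data.shape
    if Cin != Cin2:
        raise ValueError(f"conv2d channel mismatch: input {Cin}, weight {Cin2}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho = (Hp - k) // stride + 1
    Wo = (Wp - k) // stride + 1
    # im2col with offset-major row order: building the column matrix is a
    # sequence of contiguous block writes (no transposes), and each pass is
    # a single batched GEMM.
    npix = Ho * Wo
    kk = k * k
    cols = np.empty((B, kk * Cin, npix))
    for t in range(kk):
        ki, kj = divmod(t, k)
        cols[:, t * Cin : (t + 1) * Cin, :] = xp[
            :, :, ki : ki + stride * Ho : stride, kj : kj + stride * Wo : stride
        ].reshape(B, Cin, npix)
    # w2[f, t*Cin + c] = w[f, c, ki, kj]
    w2 = w.data.reshape(Cout, Cin, kk).transpose(0, 2, 1).reshape(Cout, kk * Cin)
    data = (w2 @ cols).reshape(B, Cout, Ho, Wo) + b.data[None, :, None, None]

    def backward(g):
        g2 = np.ascontiguousarray(g).reshape(B, Cout, npix)
        db = g2.sum(axis=(0, 2))
        dw2 = np.matmul(g2, cols.transpose(0, 2, 1)).sum(axis=0)
        dw = dw2.reshape(Cout, kk, Cin).transpose(0, 2, 1).reshape(w.data.shape)
        dcols = np.matmul(w2.T, g2)  # (B, kk*Cin, npix)
        dxp = np.zeros((B, Cin, Hp, Wp))
        for t in range(kk):
            ki, kj = divmod(t, k)
            dxp[:, :, ki : ki + stride * Ho : stride, kj : kj + stride * Wo : stride] += dcols[
                :, t * Cin : (t + 1) * Cin, :
            ].reshape(B, Cin, Ho, Wo)
        dx = dxp[:, :, pad : Hp - pad, pad : Wp - pad] if pad else dxp
        return dx, dw, db

    return _make(data, (x, w, b), backward)


def maxpool2(x) -> Tensor:
    """2x2 max pooling with stride 2; spatial dims must be even."""
    x = as_tensor(x)
    B, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2 requires even spatial dimensions")
    win = x.data.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        B, C, H // 2, W // 2, 4
    )
    idx = win.argmax(axis=-1)
    data = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gwin = np.zeros((B, C, H // 2, W // 2, 4))
        np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
        dx = gwin.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            B, C, H, W
        )
        return (dx,)

    return _make(data, (x,), backward)


def upsample2(x) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    x = as_tensor(x)
    data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        B, C, H2, W2 = g.shape
        return (g.reshape(B, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5)),)

    return _make(data, (x,), backward)


def instance_norm(x, gamma, beta, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalization over the spatial axes."""
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    mu = x.data.mean(axis=(2, 3), keepdims=True)
    var = x.data.var(axis=(2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    gam = gamma.data[None, :, None, None]
    data = gam * xhat + beta.data[None, :, None, None]
    n = x.data.shape[2] * x.data.shape[3]

    def backward(g):
        dgamma = (g * xhat).sum(axis=(0, 2, 3))
        dbeta = g.sum(axis=(0, 2, 3))
        dxhat = g * gam
        s1 = dxhat.sum(axis=(2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(2, 3), keepdims=True)
        dx = inv / n * (n * dxhat - s1 - xhat * s2)
        return dx, dgamma, dbeta

    return _make(data, (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# singular-value soft-thresholding with a differentiable SVD
# ---------------------------------------------------------------------------

def _svd_shrink_forward(a: np.ndarray, lam: float):
    u, s, vt = np.linalg.svd(a, full_matrices=False)
    gs = np.maximum(s - lam, 0.0)
    return (u * gs) @ vt, u, s, vt, gs


def _svd_shrink_backward(g: np.ndarray, u, s, vt, gs, lam: float) -> np.ndarray:
    """Gradient of D(A) = U.shrink(S).V^T through the SVD of A.

    Uses the standard reduced-SVD adjoint with guarded denominators: terms
    with (near-)coincident squared singular values or vanishing singular
    values are zeroed, i.e. a subgradient is returned at non-smooth points.
    """
    v = vt.T
    k = s.size
    gv = g @ v  # (m, k)
    du = gv * gs[None, :]
    ds = np.einsum("ik,ik->k", u, gv) * (s > lam)
    dv = g.T @ u * gs[None, :]

    s2 = s * s
    denom = s2[None, :] - s2[:, None]
    tol = 1e-10 * max(float(s2.max(initial=0.0)), 1.0)
    f = np.where(np.abs(denom) > tol, 1.0 / np.where(denom == 0, 1.0, denom), 0.0)
    np.fill_diagonal(f, 0.0)

    utdu = u.T @ du
    vtdv = v.T @ dv
    inner = (f * (utdu - utdu.T)) * s[None, :] + s[:, None] * (f * (vtdv - vtdv.T))
    inner[np.diag_indices(k)] += ds
    da = u @ inner @ vt

    sinv = np.where(s > tol, 1.0 / np.maximum(s, tol), 0.0)
    m, n = g.shape
    if m > k:
        da += (du - u @ utdu) * sinv[None, :] @ vt
    if n > k:
        da += u @ ((dv - v @ vtdv) * sinv[None, :]).T
    return da


def svd_shrink(x, lam: float) -> Tensor:
    """Apply singular-value soft-thresholding to each matrix in a batch.

    ``x`` has shape (H, W) or (B, H, W).  Output singular values equal
    max(sigma_i - lam, 0).
    """
    x = as_tensor(x)
    if not np.all(np.isfinite(x.data)):
        raise ValueError("svd_shrink: input contains non-finite entries")
    single = x.data.ndim == 2
    batch = x.data[None] if single else x.data
    outs, caches = [], []
    for a in batch:
        d, u, s, vt, gs = _svd_shrink_forward(a, lam)
        outs.append(d)
        caches.append((u, s, vt, gs))
    data = outs[0] if single else np.stack(outs)

    def backward(g):
        gb = g[None] if single else g
        das = [
            _svd_shrink_backward(gi, *cache, lam) for gi, cache in zip(gb, caches)
        ]
        da = np.stack(das)
        return (da[0] if single else da,)

    return _make(data, (x,), backward)
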