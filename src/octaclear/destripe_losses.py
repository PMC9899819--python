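"""Composite de-striping objective.

The de-striping stage is trained to split a corrupted angiogram I into an
additive stripe-noise map N and a clean vessel image C (I = N + C).  Its
objective combines three terms::

    L_destripe = alpha * L_recon + beta * L_stripe + gamma * L_ATV

* ``L_recon`` ties the predicted decomposition back to the input:
  half the Frobenius norm of I_in - (N_out + C_out).
* ``L_stripe`` exploits the low-rank structure of stripe artifacts: both
  the reference and the predicted noise maps are passed through a
  singular-value soft-thresholding "stripe degradation" operator (the
  proximal operator of the nuclear norm) and compared in Frobenius norm.
* ``L_ATV`` preserves edge sharpness: the anisotropic total variation
  (sum of L1 norms of horizontal and vertical forward differences) of the
  predicted clean image is matched to that of the reference clean image.

Every function accepts either plain NumPy arrays (returning a float) or
autodiff :class:`~octaclear.nn.Tensor` objects (returning a scalar tensor),
so the same code serves analytic tests and network training.  Images may be
single 2-D arrays or batches shaped (B, 1, H, W); batched losses are the
mean of the per-image values.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
from pydantic import BaseModel, field_validator

from .nn.tensor import Tensor, as_tensor, svd_shrink, tabs, tsqrt, tsum

__all__ = [
    "DestripeWeights",
    "atv",
    "atv_loss",
    "destripe_loss",
    "reconstruction_loss",
    "shrink_singular_values",
    "stripe_degrade",
    "stripe_loss",
]


class DestripeWeights(BaseModel):
    """Weights of the composite de-stripe objective.

    ``alpha``, ``beta``, ``gamma`` balance the reconstruction, stripe and
    ATV terms; ``lam`` is the singular-value shrinkage threshold applied on
    the [0, 1] intensity scale.  Defaults follow the reference training
    recipe (alpha=0.5, beta=2, gamma=1, lam=0.002).
    """

    alpha: float = 0.5
    beta: float = 2.0
    gamma: float = 1.0
    lam: float = 0.002
    atv_variant: Literal["scalar", "map"] = "scalar"
    norm_variant: Literal["plain", "squared"] = "plain"

    @field_validator("alpha", "beta", "gamma")
    @classmethod
    def _nonneg(cls, v, info):
        if v < 0:
            raise ValueError(f"{info.field_name} must be >= 0")
        return v

    @field_validator("lam")
    @classmethod
    def _pos(cls, v):
        if v <= 0:
            raise ValueError("lam must be > 0")
        return v


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _any_tensor(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def _ret(value: Tensor, tensor_mode: bool):
    return value if tensor_mode else float(value.data)

def _check_same_shape(*xs, names: tuple[str, ...]) -> None:
    shapes = [as_tensor(x).data.shape for x in xs]
    if len({s for s in shapes}) > 1:
        pairs = ", ".join(f"{n}={s}" for n, s in zip(names, shapes))
        raise ValueError(f"shape mismatch: {pairs}")


def _image_axes(x: Tensor) -> tuple[int, ...]:
    """Axes to reduce for a per-image scalar: all but a leading batch axis."""
    if x.data.ndim <= 2:
        return tuple(range(x.data.ndim))
    return tuple(range(1, x.data.ndim))


def _fro(x: Tensor, squared: bool = False) -> Tensor:
    """Per-image Frobenius norm, averaged over any batch axis."""
    axes = _image_axes(x)
    sq = tsum(x * x, axis=axes if x.data.ndim > 2 else None)
    val = sq if squared else tsqrt(sq)
    return val.mean() if x.data.ndim > 2 else val


# ---------------------------------------------------------------------------
# the loss terms
# ---------------------------------------------------------------------------

def reconstruction_loss(i_in, n_out, c_out, norm_variant: str = "plain"):
    """1/2 * ||I_in - (N_out + C_out)||_F (unsquared by default)."""
    _check_same_shape(i_in, n_out, c_out, names=("i_in", "n_out", "c_out"))
    tm = _any_tensor(i_in, n_out, c_out)
    r = as_tensor(i_in) - (as_tensor(n_out) + as_tensor(c_out))
    return _ret(0.5 * _fro(r, squared=norm_variant == "squared"), tm)


def shrink_singular_values(s, lam: float) -> np.ndarray:
    """Soft-threshold a non-increasing vector of singular values."""
    s = np.asarray(s, dtype=np.float64)
    if np.any(s < 0):
        raise ValueError("singular values must be non-negative")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    return np.maximum(s - lam, 0.0)


def stripe_degrade(n, lam: float):
    """U . shrink(S) . V^T for N = U.S.V^T (per matrix in a batch).

    This is the closed-form proximal operator of ``lam *`` nuclear norm:
    it reconstructs the dominant (low-rank) stripe component and discards
    singular values below ``lam``.
    """
    if isinstance(n, Tensor):
        x = n
        squeeze = x.data.ndim == 4
        if squeeze:  # (B, 1, H, W) -> (B, H, W)
            x = x.reshape((x.shape[0], x.shape[2], x.shape[3]))
        out = svd_shrink(x, lam)
        if squeeze:
            out = out.reshape((out.shape[0], 1, out.shape[1], out.shape[2]))
        return out
    a = np.asarray(n, dtype=np.float64)
    if not np.all(np.isfinite(a)):
        raise ValueError("stripe_degrade: input contains non-finite entries")
    single = a.ndim == 2
    batch = a[None] if single else a.reshape((-1,) + a.shape[-2:])
    outs = []
    for m in batch:
        u, s, vt = np.linalg.svd(m, full_matrices=False)
        outs.append((u * np.maximum(s - lam, 0.0)) @ vt)
    return np.stack(outs).reshape(a.shape)


def stripe_loss(n_ref, n_out, lam: float, norm_variant: str = "plain"):
    """||Stripe(N_ref) - Stripe(N_out)||_F, averaged over any batch axis."""
    _check_same_shape(n_ref, n_out, names=("n_ref", "n_out"))
    tm = _any_tensor(n_ref, n_out)
    d_ref = stripe_degrade(n_ref, lam)
    d_out = stripe_degrade(n_out, lam)
    diff = as_tensor(d_ref) - as_tensor(d_out)
    return _ret(_fro(diff, squared=norm_variant == "squared"), tm)


def _atv_per_image(c: Tensor) -> Tensor:
    """ATV of each image; scalar for 2-D input, (B,) tensor for batches."""
    nd = c.data.ndim
    h_ax, w_ax = nd - 2, nd - 1
    ncols = c.data.shape[w_ax]
    nrows = c.data.shape[h_ax]
    sl = [slice(None)] * nd

    def shifted(ax, lo, hi):
        s = list(sl)
        s[ax] = slice(lo, hi)
        return c[tuple(s)]

    dh = shifted(w_ax, 1, None) - shifted(w_ax, 0, ncols - 1)
    dv = shifted(h_ax, 1, None) - shifted(h_ax, 0, nrows - 1)
    axes = _image_axes(c)
    if nd <= 2:
        return tabs(dh).sum() + tabs(dv).sum()
    return tsum(tabs(dh), axis=axes) + tsum(tabs(dv), axis=axes)


def atv(c):
    """Anisotropic total variation: L1 of horizontal plus vertical forward
    differences, with no wrap-around at the boundaries."""
    tm = isinstance(c, Tensor)
    ct = as_tensor(c)
    if ct.data.ndim < 2 or ct.data.shape[-1] < 2 or ct.data.shape[-2] < 2:
        raise ValueError("atv requires an image of at least 2x2 pixels")
    val = _atv_per_image(ct)
    if ct.data.ndim > 2:
        val = val.mean()
    return _ret(val, tm)


def atv_loss(c_ref, c_out, variant: str = "scalar"):
    """|ATV(C_ref) - ATV(C_out)| (scalar variant, the literal reading).

    The ``map`` variant compares the absolute horizontal and vertical
    gradient maps elementwise (Frobenius norm of their differences), which
    localizes edge discrepancies instead of matching a single number.
    """
    _check_same_shape(c_ref, c_out, names=("c_ref", "c_out"))
    tm = _any_tensor(c_ref, c_out)
    a, b = as_tensor(c_ref), as_tensor(c_out)
    if a.data.ndim < 2 or a.data.shape[-1] < 2 or a.data.shape[-2] < 2:
        raise ValueError("atv_loss requires images of at least 2x2 pixels")
    if variant == "scalar":
        diff = _atv_per_image(a) - _atv_per_image(b)
        val = tabs(diff)
        if a.data.ndim > 2:
            val = val.mean()
        return _ret(val, tm)
    if variant != "map":
        raise ValueError(f"unknown atv variant: {variant!r}")

    nd = a.data.ndim
    h_ax, w_ax = nd - 2, nd - 1

    def grads(x: Tensor):
        sl = [slice(None)] * nd
        sh = list(sl)
        sh[w_ax] = slice(1, None)
        sh2 = list(sl)
        sh2[w_ax] = slice(0, x.data.shape[w_ax] - 1)
        sv = list(sl)
        sv[h_ax] = slice(1, None)
        sv2 = list(sl)
        sv2[h_ax] = slice(0, x.data.shape[h_ax] - 1)
        return tabs(x[tuple(sh)] - x[tuple(sh2)]), tabs(x[tuple(sv)] - x[tuple(sv2)])

    ah, av = grads(a)
    bh, bv = grads(b)
    val = _fro(ah - bh) + _fro(av - bv)
    return _ret(val, tm)


def destripe_loss(i_in, n_out, c_out, n_ref, c_ref, weights: DestripeWeights | None = None):
    """alpha*L_recon + beta*L_stripe + gamma*L_ATV (differentiable in
    ``n_out`` and ``c_out`` when those are tensors)."""
    w = weights or DestripeWeights()
    tm = _any_tensor(i_in, n_out, c_out, n_ref, c_ref)
    lr = reconstruction_loss(i_in, n_out, c_out, norm_variant=w.norm_variant)
    ls = stripe_loss(n_ref, n_out, w.lam, norm_variant=w.norm_variant)
    la = atv_loss(c_ref, c_out, variant=w.atv_variant)
    total = w.alpha * as_tensor(lr) + w.beta * as_tensor(ls) + w.gamma * as_tensor(la)
    return _ret(total, tm)
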