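"""Perceptual-structure GAN for unpaired contrast enhancement.

Low- and high-contrast angiograms are treated as two unpaired domains X
and Y.  Two generators (G_XY, G_YX) and two patch discriminators (D_X,
D_Y) are trained with the usual bi-directional translation objective —
least-squares adversarial loss, image-level cycle consistency and identity
loss — augmented by two structural terms:

* the *cyclic perceptual loss* re-imposes cycle consistency in the feature
  space of a fixed extractor, at a shallow and a deep tap simultaneously,
  so reconstruction is constrained at several scales:

      L_p = sum_l ||phi_l(x) - phi_l(G_YX(G_XY(x)))||_F^2
          + ||phi_l(y) - phi_l(G_XY(G_YX(y)))||_F^2

* the *structure loss* penalizes, window by window, the decay of the SSIM
  structure term (covariance over product of standard deviations) between
  an image and its translation:

      L_s(G, X) = E_x [ 1 - (1/M) sum_i (cov_i + c) / (sd_i sd'_i + c) ]

The total generator objective is  L_bl + xi*L_p + rho1*L_s(G_XY, X) +
rho2*L_s(G_YX, Y).  Setting xi = rho1 = rho2 = 0 recovers the baseline
exactly, which is the ablation axis used in testing.

The feature extractor is pluggable.  The default is a seeded-random small
CNN with taps after its 2nd and 5th pooling stages — fixed, deterministic
and fully offline; a linear (identity) extractor is provided for the
equivalence check that feature-level cycle consistency with phi(x) = x
reduces to the image-level cycle error.

Generators are residual: output = clamp(input + correction, 0, 1), with a
zero-initialized final convolution, so an untrained generator is exactly
the identity map.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import nn
from .nn.tensor import Tensor, clip, relu, tabs, tmean, tsqrt, tsum

__all__ = [
    "EnhanceWeights",
    "LinearFeatureExtractor",
    "PSGANConfig",
    "PSGANModels",
    "RandomFeatureExtractor",
    "baseline_loss",
    "build_extractor",
    "build_psgan",
    "cyclic_perceptual_loss",
    "discriminator_loss",
    "enhance",
    "load_psgan",
    "psgan_loss",
    "save_psgan",
    "structure_loss",
    "train_psgan",
]


class EnhanceWeights(BaseModel):
    """Weights of the enhancement objective beyond the baseline.

    ``xi`` scales the cyclic perceptual loss; ``rho1``/``rho2`` the two
    structure-loss terms; ``c`` is the SSIM-style stabilizer of the
    structure term on the [0, 1] intensity scale and ``window`` the side
    of the non-overlapping local windows.
    """

    xi: float = 0.5
    rho1: float = 0.5
    rho2: float = 0.5
    c: float = 0.03**2 / 2
    window: int = 8
    feature_layers: tuple[int, ...] = (2, 5)

    @field_validator("xi", "rho1", "rho2")
    @classmethod
    def _nonneg(cls, v, info):
        if v < 0:
            raise ValueError(f"{info.field_name} must be >= 0")
        return v

    @field_validator("c")
    @classmethod
    def _c(cls, v):
        if v <= 0:
            raise ValueError("c must be > 0")
        return v

    @field_validator("window")
    @classmethod
    def _w(cls, v):
        if v < 2:
            raise ValueError("window must be >= 2")
        return v


class BaselineWeights(BaseModel):
    """Cycle-consistency and identity weights of the baseline objective."""

    lambda_cyc: float = 10.0
    lambda_idt: float = 5.0


class PSGANConfig(BaseModel):
    base_channels: int = 32
    n_res_blocks: int = 4
    disc_channels: int = 32
    batch_size: int = 1
    lr: float = 2e-4
    epochs_constant: int = 100
    epochs_decay: int = 100
    image_size: int = 400
    seed: int = 0
    weights: EnhanceWeights = Field(default_factory=EnhanceWeights)
    baseline: BaselineWeights = Field(default_factory=BaselineWeights)
    extractor: str = "random"
    buffer_size: int = 50

    @field_validator("base_channels", "disc_channels", "batch_size", "image_size")
    @classmethod
    def _pos(cls, v, info):
        if v < 1:
            raise ValueError(f"{info.field_name} must be positive")
        return v

    @property
    def epochs(self) -> int:
        return self.epochs_constant + self.epochs_decay

    @classmethod
    def tiny(cls, **overrides) -> "PSGANConfig":
        base = dict(
            base_channels=8,
            n_res_blocks=1,
            disc_channels=8,
            image_size=64,
            lr=1e-3,
            epochs_constant=5,
            epochs_decay=5,
        )
        base.update(overrides)
        return cls(**base)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

class _ResBlock(nn.Module):
    def __init__(self, ch, rng):
        self.c1 = nn.Conv2d(ch, ch, 3, rng=rng)
        self.n1 = nn.InstanceNorm2d(ch)
        self.c2 = nn.Conv2d(ch, ch, 3, rng=rng)
        self.n2 = nn.InstanceNorm2d(ch)

    def forward(self, x):
        h = relu(self.n1(self.c1(x)))
        return x + self.n2(self.c2(h))


class ResnetGenerator(nn.Module):
    """Residual image-to-image generator: clamp(x + f(x), 0, 1).

    The final convolution is zero-initialized, so a freshly built
    generator is the identity map on [0, 1] images.
    """

    def __init__(self, base: int, n_res: int, rng):
        self.inc = nn.Conv2d(1, base, 3, rng=rng)
        self.inn = nn.InstanceNorm2d(base)
        self.down = nn.Conv2d(base, 2 * base, 3, stride=2, rng=rng)
        self.dnn = nn.InstanceNorm2d(2 * base)
        self.blocks = [_ResBlock(2 * base, rng) for _ in range(n_res)]
        self.up = nn.Conv2d(2 * base, base, 3, rng=rng)
        self.upn = nn.InstanceNorm2d(base)
        self.out = nn.Conv2d(base, 1, 3, rng=rng, zero_init=True)

    def forward(self, x):
        h = relu(self.inn(self.inc(x)))
        h = relu(self.dnn(self.down(h)))
        for blk in self.blocks:
            h = blk(h)
        h = relu(self.upn(self.up(nn.upsample2(h))))
        return clip(x + self.out(h), 0.0, 1.0)


class PatchDiscriminator(nn.Module):
    """Small strided-convolution discriminator producing a score map."""

    def __init__(self, base: int, rng):
        self.c1 = nn.Conv2d(1, base, 4, stride=2, pad=1, rng=rng)
        self.c2 = nn.Conv2d(base, 2 * base, 4, stride=2, pad=1, rng=rng)
        self.n2 = nn.InstanceNorm2d(2 * base)
        self.c3 = nn.Conv2d(2 * base, 1, 4, stride=1, pad=1, rng=rng)
        self.act = nn.LeakyReLU(0.2)

    def forward(self, x):
        h = self.act(self.c1(x))
        h = self.act(self.n2(self.c2(h)))
        return self.c3(h)


class PSGANModels(NamedTuple):
    g_xy: ResnetGenerator
    g_yx: ResnetGenerator
    d_x: PatchDiscriminator
    d_y: PatchDiscriminator


def build_psgan(config: PSGANConfig | None = None) -> PSGANModels:
    config = config or PSGANConfig()
    if config.image_size % 2:
        raise ValueError("image_size must be even (one 2x downsampling in the generator)")
    rng = np.random.default_rng(config.seed)
    return PSGANModels(
        g_xy=ResnetGenerator(config.base_channels, config.n_res_blocks, rng),
        g_yx=ResnetGenerator(config.base_channels, config.n_res_blocks, rng),
        d_x=PatchDiscriminator(config.disc_channels, rng),
        d_y=PatchDiscriminator(config.disc_channels, rng),
    )


# ---------------------------------------------------------------------------
# feature extractors
# ---------------------------------------------------------------------------

class RandomFeatureExtractor:
    """Fixed random CNN with taps after configured pooling stages.

    Emulates the role of a pretrained perceptual backbone while staying
    deterministic and dependency-free: convolution + ReLU + 2x max-pool
    stages with He-initialized frozen weights; features are returned after
    the pooling stages listed in ``layers`` (1-based).
    """

    identifier = "seeded-random-CNN"

    def __init__(self, seed: int = 0, layers: tuple[int, ...] = (2, 5), base: int = 8):
        if not layers or any(l < 1 for l in layers):
            raise ValueError("layers must be positive 1-based pooling indices")
        self.layers = tuple(sorted(layers))
        rng = np.random.default_rng(seed)
        depth = max(self.layers)
        chans = [min(base * 2**i, 4 * base) for i in range(depth)]
        self.convs = []
        cin = 1
        for ch in chans:
            conv = nn.Conv2d(cin, ch, 3, rng=rng)
            conv.w.requires_grad = False
            conv.b.requires_grad = False
            self.convs.append(conv)
            cin = ch

    def __call__(self, x) -> list[Tensor]:
        t = nn.as_tensor(x)
        if t.data.ndim == 2:
            t = t.reshape((1, 1) + t.data.shape)
        min_side = min(t.data.shape[2], t.data.shape[3])
        if min_side < 2 ** max(self.layers):
            raise ValueError(
                f"image side {min_side} too small for {max(self.layers)} pooling stages"
            )
        feats = []
        h = t
        for i, conv in enumerate(self.convs, start=1):
            h = nn.maxpool2(relu(conv(h)))
            if i in self.layers:
                feats.append(h)
        return feats


class LinearFeatureExtractor:
    """phi(x) = x; with this extractor the cyclic perceptual loss equals
    the squared image-space cycle error."""

    identifier = "linear"
    layers = (1,)

    def __call__(self, x) -> list[Tensor]:
        t = nn.as_tensor(x)
        if t.data.ndim == 2:
            t = t.reshape((1, 1) + t.data.shape)
        return [t]


def build_extractor(name: str, seed: int = 0, layers: tuple[int, ...] = (2, 5)):
    if name == "random":
        return RandomFeatureExtractor(seed=seed, layers=layers)
    if name == "linear":
        return LinearFeatureExtractor()
    raise ValueError(f"unknown extractor {name!r} (available: random, linear)")


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _maybe_float(val: Tensor, tensor_mode: bool):
    return val if tensor_mode else float(val.data)


def _to_batch(x) -> Tensor:
    t = nn.as_tensor(x)
    if t.data.ndim == 2:
        t = t.reshape((1, 1) + t.data.shape)
    return t


def _sq_fro(x: Tensor) -> Tensor:
    return tsum(x * x)


def cyclic_perceptual_loss(x, y, g_xy, g_yx, extractor):
    """Feature-level cycle consistency at every configured extractor tap."""
    tm = isinstance(x, Tensor) or isinstance(y, Tensor)
    xb, yb = _to_batch(x), _to_batch(y)
    rx = g_yx(g_xy(xb))
    ry = g_xy(g_yx(yb))
    total = None
    for fx, frx in zip(extractor(xb), extractor(rx)):
        term = _sq_fro(fx - frx)
        total = term if total is None else total + term
    for fy, fry in zip(extractor(yb), extractor(ry)):
        total = total + _sq_fro(fy - fry)
    total = total * (1.0 / xb.data.shape[0])
    return _maybe_float(total, tm)


def structure_loss(x, gx, weights: EnhanceWeights | None = None):
    """1 - mean per-window SSIM structure term between x and G(x).

    Windows are non-overlapping ``window`` x ``window`` tiles (partial edge
    tiles dropped); standard deviations and covariance are population
    moments.  The value lies in [0, 2]: 0 for structure-preserving (e.g.
    positive affine) maps, 2 for perfect anti-correlation in every window.
    """
    w = weights or EnhanceWeights()
    tm = isinstance(x, Tensor) or isinstance(gx, Tensor)
    xb, gb = _to_batch(x), _to_batch(gx)
    if xb.data.shape != gb.data.shape:
        raise ValueError(f"shape mismatch: {xb.data.shape} vs {gb.data.shape}")
    B, _, H, W = xb.data.shape
    win = w.window
    nh, nw = H // win, W // win
    if nh < 1 or nw < 1:
        raise ValueError(f"image {H}x{W} smaller than one {win}x{win} window")
    Hc, Wc = nh * win, nw * win

    def tiles(t: Tensor) -> Tensor:
        t = t[:, :, :Hc, :Wc]
        t = t.reshape((B, nh, win, nw, win))
        t = t.transpose((0, 1, 3, 2, 4))
        return t.reshape((B, nh * nw, win * win))

    xt, gt = tiles(xb), tiles(gb)
    mx = tmean(xt, axis=2, keepdims=True)
    mg = tmean(gt, axis=2, keepdims=True)
    xc = xt - mx
    gc = gt - mg
    cov = tmean(xc * gc, axis=2)
    sx = tsqrt(relu(tmean(xc * xc, axis=2)))
    sg = tsqrt(relu(tmean(gc * gc, axis=2)))
    term = (cov + w.c) / (sx * sg + w.c)
    loss = 1.0 - term.mean()
    return _maybe_float(loss, tm)


def _lsgan(pred: Tensor, target: float) -> Tensor:
    d = pred - target
    return tmean(d * d)


def baseline_loss(x, y, models: PSGANModels, weights: BaselineWeights | None = None):
    """Generator-side baseline objective with per-term breakdown.

    Least-squares adversarial terms for both directions, plus
    lambda_cyc * image-level cycle consistency and lambda_idt * identity
    regularization (mean absolute errors).
    """
    bw = weights or BaselineWeights()
    xb, yb = _to_batch(x), _to_batch(y)
    if xb.data.shape[1:] != yb.data.shape[1:]:
        raise ValueError(
            f"domain shape mismatch: {xb.data.shape[1:]} vs {yb.data.shape[1:]}"
        )
    fx = models.g_xy(xb)  # fake Y
    fy = models.g_yx(yb)  # fake X
    adv_xy = _lsgan(models.d_y(fx), 1.0)
    adv_yx = _lsgan(models.d_x(fy), 1.0)
    cyc = tmean(tabs(models.g_yx(fx) - xb)) + tmean(tabs(models.g_xy(fy) - yb))
    idt = tmean(tabs(models.g_xy(yb) - yb)) + tmean(tabs(models.g_yx(xb) - xb))
    total = adv_xy + adv_yx + bw.lambda_cyc * cyc + bw.lambda_idt * idt
    breakdown = {
        "adv_xy": float(adv_xy.data),
        "adv_yx": float(adv_yx.data),
        "cycle": float(cyc.data),
        "identity": float(idt.data),
        "fake_x": fy,
        "fake_y": fx,
    }
    return total, breakdown


def psgan_loss(x, y, models: PSGANModels, extractor, config: PSGANConfig):
    """Full generator objective: baseline + xi*L_p + rho1*L_s + rho2*L_s."""
    w = config.weights
    total, breakdown = baseline_loss(x, y, models, config.baseline)
    if w.xi > 0:
        lp = cyclic_perceptual_loss(_to_batch(x), y, models.g_xy, models.g_yx, extractor)
        total = total + w.xi * lp
        breakdown["perceptual"] = float(lp.data)
    if w.rho1 > 0:
        ls_x = structure_loss(_to_batch(x), breakdown["fake_y"], w)
        total = total + w.rho1 * ls_x
        breakdown["structure_x"] = float(ls_x.data)
    if w.rho2 > 0:
        ls_y = structure_loss(_to_batch(y), breakdown["fake_x"], w)
        total = total + w.rho2 * ls_y
        breakdown["structure_y"] = float(ls_y.data)
    breakdown["total"] = float(total.data)
    return total, breakdown


def discriminator_loss(disc: PatchDiscriminator, real: Tensor, fake: Tensor) -> Tensor:
    """0.5 * (LSGAN real toward 1 + LSGAN fake toward 0)."""
    return 0.5 * (_lsgan(disc(real), 1.0) + _lsgan(disc(fake), 0.0))


class _ReplayBuffer:
    """Pool of past generated images for discriminator updates."""

    def __init__(self, size: int, rng: np.random.Generator):
        self.size = size
        self.rng = rng
        self.items: list[np.ndarray] = []

    def push_and_sample(self, image: np.ndarray) -> np.ndarray:
        if self.size == 0:
            return image
        if len(self.items) < self.size:
            self.items.append(image.copy())
            return image
        if self.rng.random() < 0.5:
            idx = int(self.rng.integers(0, self.size))
            out = self.items[idx].copy()
            self.items[idx] = image.copy()
            return out
        return image


# ---------------------------------------------------------------------------
# training / inference
# ---------------------------------------------------------------------------

def train_psgan(
    x_images,
    y_images,
    config: PSGANConfig,
    out_dir=None,
) -> tuple[PSGANModels, pd.DataFrame]:
    """Adversarial training over two unpaired image pools.

    ``x_images`` / ``y_images`` are sequences of 2-D arrays in [0, 1]
    (low- and high-contrast domains).  Alternates one generator update
    (full objective) and one update of each discriminator (least-squares,
    with a seeded replay buffer of past fakes) per image pair.
    """
    x_pool = [np.asarray(a, dtype=np.float64) for a in x_images]
    y_pool = [np.asarray(a, dtype=np.float64) for a in y_images]
    if not x_pool or not y_pool:
        raise ValueError("both domains must contain at least one image")
    models = build_psgan(config)
    extractor = build_extractor(
        config.extractor, seed=config.seed + 7, layers=config.weights.feature_layers
    )
    gen_params = models.g_xy.params() + models.g_yx.params()
    dis_params = models.d_x.params() + models.d_y.params()
    opt_g = nn.Adam(gen_params, lr=config.lr, betas=(0.5, 0.999))
    opt_d = nn.Adam(dis_params, lr=config.lr, betas=(0.5, 0.999))
    rng = np.random.default_rng(config.seed + 11)
    buf_x = _ReplayBuffer(config.buffer_size, np.random.default_rng(config.seed + 13))
    buf_y = _ReplayBuffer(config.buffer_size, np.random.default_rng(config.seed + 17))

    n_steps = min(len(x_pool), len(y_pool))
    records = []
    for epoch in range(config.epochs):
        lr = nn.linear_decay_lr(config.lr, epoch, config.epochs_constant, config.epochs_decay)
        opt_g.lr = lr
        opt_d.lr = lr
        xi = rng.permutation(len(x_pool))[:n_steps]
        yi = rng.permutation(len(y_pool))[:n_steps]
        sums: dict[str, float] = {}
        for i, j in zip(xi, yi):
            x = x_pool[i]
            y = y_pool[j]
            total, bd = psgan_loss(x, y, models, extractor, config)
            if not np.isfinite(total.data):
                raise RuntimeError(f"non-finite generator loss at epoch {epoch}: {bd}")
            opt_g.zero_grad()
            total.backward()
            opt_g.step()

            fake_x = buf_x.push_and_sample(bd["fake_x"].data)
            fake_y = buf_y.push_and_sample(bd["fake_y"].data)
            d_loss = discriminator_loss(
                models.d_x, _to_batch(x), Tensor(fake_x)
            ) + discriminator_loss(models.d_y, _to_batch(y), Tensor(fake_y))
            if not np.isfinite(d_loss.data):
                raise RuntimeError(f"non-finite discriminator loss at epoch {epoch}")
            opt_d.zero_grad()
            d_loss.backward()
            opt_d.step()

            bd_scalar = {k: v for k, v in bd.items() if isinstance(v, float)}
            bd_scalar["d_loss"] = float(d_loss.data)
            for k, v in bd_scalar.items():
                sums[k] = sums.get(k, 0.0) + v
        rec = {"epoch": epoch, "lr": lr}
        rec.update({k: v / n_steps for k, v in sums.items()})
        records.append(rec)
    history = pd.DataFrame(records)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_psgan(models, config, out_dir / "psgan.npz")
        history.to_csv(out_dir / "psgan_history.csv", index=False)
    return models, history


def enhance(g_xy: ResnetGenerator, image: np.ndarray) -> np.ndarray:
    """Translate one low-contrast image to the high-contrast domain.

    Odd-sized inputs are reflect-padded to even sides and cropped back;
    output is in [0, 1] by the generator's clamp.  Deterministic.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("enhance expects a single 2-D image")
    h, w = img.shape
    ph, pw = h % 2, w % 2
    if ph or pw:
        img_p = np.pad(img, ((0, ph), (0, pw)), mode="reflect")
    else:
        img_p = img
    out = g_xy(Tensor(img_p[None, None])).data[0, 0]
    return out[:h, :w]


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_psgan(models: PSGANModels, config: PSGANConfig, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = {}
    for name, model in models._asdict().items():
        for key, arr in model.state_dict().items():
            state[f"{name}.{key}"] = arr
    np.savez(path, **state)
    sidecar = {"config": config.model_dump(), "kind": "psgan"}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_psgan(path) -> tuple[PSGANModels, PSGANConfig]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    config = PSGANConfig(**sidecar["config"])
    models = build_psgan(config)
    with np.load(path) as data:
        for name, model in models._asdict().items():
            model.load_state_dict(
                {
                    k.split(".", 1)[1]: data[k]
                    for k in data.files
                    if k.startswith(f"{name}.")
                }
            )
    return models, config
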