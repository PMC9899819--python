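"""Stripe-removal network: a U-shaped noise estimator.

The de-striping stage learns a mapping from a corrupted image I_in to its
stripe-noise map N_out; the clean image is then recovered through the
residual rule C_out = max{I_in - N_out, 0}.  The network is a standard
encoder-decoder with symmetric skip connections (two 3x3 convolutions with
instance normalization per level, 2x max-pool down, nearest-upsample +
convolution up) and a final ReLU so the predicted noise is non-negative,
matching the additive bright-stripe model of the synthetic data.

Training minimizes the composite de-stripe objective
(:mod:`octaclear.destripe_losses`) with Adam and a constant-then-linear
learning-rate decay.  Everything is seeded: parameter initialization, data
order, and hence the full trajectory.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import nn
from .destripe_losses import DestripeWeights, stripe_degrade
from .metrics import psnr
from .nn.tensor import Tensor, relu, tabs, tsqrt, tsum

__all__ = [
    "SRNet",
    "SRNetConfig",
    "build_srnet",
    "compose_clean",
    "destripe",
    "load_srnet",
    "save_srnet",
    "train_srnet",
]


class SRNetConfig(BaseModel):
    """Architecture and training settings for the de-striping stage.

    ``depth`` is the number of 2x down/upsamplings, so inputs must have
    spatial sides divisible by 2**depth.  The default schedule follows the
    reference recipe (lr 2e-4, decay concluding at epoch 300, batch 16);
    the ``tiny`` profile is a CPU-sized configuration with a shorter,
    hotter schedule for desk-scale experiments.
    """

    depth: int = 4
    base_channels: int = 32
    batch_size: int = 16
    lr: float = 2e-4
    epochs_constant: int = 150
    epochs_decay: int = 150
    seed: int = 0
    final_zero_init: bool = True
    loss: DestripeWeights = Field(default_factory=DestripeWeights)

    @field_validator("depth")
    @classmethod
    def _depth(cls, v):
        if v < 2:
            raise ValueError("depth must be >= 2")
        return v

    @field_validator("base_channels")
    @classmethod
    def _base(cls, v):
        if v < 4:
            raise ValueError("base_channels must be >= 4")
        return v

    @field_validator("batch_size", "epochs_constant", "epochs_decay")
    @classmethod
    def _counts(cls, v, info):
        if v < 0 or (info.field_name == "batch_size" and v < 1):
            raise ValueError(f"{info.field_name} must be positive")
        return v

    @field_validator("lr")
    @classmethod
    def _lr(cls, v):
        if v <= 0:
            raise ValueError("lr must be > 0")
        return v

    @property
    def epochs(self) -> int:
        return self.epochs_constant + self.epochs_decay

    @classmethod
    def tiny(cls, **overrides) -> "SRNetConfig":
        base = dict(
            depth=2, base_channels=8, batch_size=16, lr=1e-3, epochs_constant=10, epochs_decay=10
        )
        base.update(overrides)
        return cls(**base)


class _Block(nn.Module):
    """conv3x3 + IN + activation, twice."""

    def __init__(self, cin, cout, rng, act="lrelu"):
        self.c1 = nn.Conv2d(cin, cout, 3, rng=rng)
        self.n1 = nn.InstanceNorm2d(cout)
        self.c2 = nn.Conv2d(cout, cout, 3, rng=rng)
        self.n2 = nn.InstanceNorm2d(cout)
        self.act = nn.LeakyReLU(0.2) if act == "lrelu" else nn.ReLU()

    def forward(self, x):
        x = self.act(self.n1(self.c1(x)))
        return self.act(self.n2(self.c2(x)))


class SRNet(nn.Module):
    def __init__(self, config: SRNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, base = config.depth, config.base_channels
        chans = [base * 2**i for i in range(d + 1)]
        self.enc = [_Block(1 if i == 0 else chans[i - 1], chans[i], rng) for i in range(d)]
        self.bottom = _Block(chans[d - 1], chans[d], rng)
        self.upconvs = [nn.Conv2d(chans[i + 1], chans[i], 3, rng=rng) for i in reversed(range(d))]
        self.dec = [_Block(2 * chans[i], chans[i], rng, act="relu") for i in reversed(range(d))]
        # near-zero init by default: an untrained model predicts an almost
        # empty noise map, so training refines the identity decomposition.
        # The small positive bias keeps the final ReLU active (a ReLU that
        # starts at exactly zero would block all gradients).
        self.out_conv = nn.Conv2d(base, 1, 3, rng=rng, zero_init=config.final_zero_init)
        if config.final_zero_init:
            self.out_conv.b.data[:] = 0.02

    def forward(self, x):
        h, w = x.shape[2], x.shape[3]
        f = 2**self.config.depth
        if h % f or w % f:
            raise ValueError(
                f"input {h}x{w} not divisible by 2^depth={f}; pad before calling"
            )
        skips = []
        for block in self.enc:
            x = block(x)
            skips.append(x)
            x = nn.maxpool2(x)
        x = self.bottom(x)
        for upconv, block, skip in zip(self.upconvs, self.dec, reversed(skips)):
            x = upconv(nn.upsample2(x))
            x = block(nn.concat([x, skip], axis=1))
        return relu(self.out_conv(x))


def build_srnet(config: SRNetConfig | None = None) -> SRNet:
    return SRNet(config or SRNetConfig())


def compose_clean(i_in, n_out):
    """C_out = max{I_in - N_out, 0} (elementwise)."""
    if isinstance(i_in, Tensor) or isinstance(n_out, Tensor):
        a, b = nn.as_tensor(i_in), nn.as_tensor(n_out)
        if a.data.shape != b.data.shape:
            raise ValueError(f"shape mismatch: {a.data.shape} vs {b.data.shape}")
        return relu(a - b)
    a = np.asarray(i_in, dtype=np.float64)
    b = np.asarray(n_out, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return np.maximum(a - b, 0.0)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _per_image_fro(x: Tensor) -> Tensor:
    return tsqrt(tsum(x * x, axis=(1, 2, 3)))


def _batch_destripe_loss(
    x: Tensor,
    n_out: Tensor,
    c_out: Tensor,
    d_ref: np.ndarray,
    atv_ref: np.ndarray,
    w: DestripeWeights,
) -> tuple[Tensor, dict[str, float]]:
    """Batched Eq-1 objective; per-image norms averaged over the batch."""
    r = x - (n_out + c_out)
    recon = (0.5 * _per_image_fro(r)).mean()
    d_out = nn.svd_shrink(n_out.reshape((n_out.shape[0], n_out.shape[2], n_out.shape[3])), w.lam)
    diff = Tensor(d_ref) - d_out
    stripe = tsqrt(tsum(diff * diff, axis=(1, 2))).mean()
    dh = c_out[:, :, :, 1:] - c_out[:, :, :, :-1]
    dv = c_out[:, :, 1:, :] - c_out[:, :, :-1, :]
    atv_out = tsum(tabs(dh), axis=(1, 2, 3)) + tsum(tabs(dv), axis=(1, 2, 3))
    atv_term = tabs(atv_out - Tensor(atv_ref)).mean()
    total = w.alpha * recon + w.beta * stripe + w.gamma * atv_term
    parts = {
        "recon": float(recon.data),
        "stripe": float(stripe.data),
        "atv": float(atv_term.data),
    }
    return total, parts


def _stack_images(arrays) -> np.ndarray:
    return np.stack(arrays)[:, None, :, :]


def train_srnet(
    manifest: pd.DataFrame,
    config: SRNetConfig,
    root,
    out_dir=None,
    val_manifest: pd.DataFrame | None = None,
) -> tuple[SRNet, pd.DataFrame]:
    """Train the noise estimator on the train split of a dataset manifest.

    Returns the trained model and a per-epoch history of the loss
    components (plus validation PSNR when ``val_manifest`` is given).
    Checkpoints and the history CSV are written under ``out_dir`` if set.
    """
    from .synthetic import load_triplet

    train_rows = manifest[manifest["split"] == "train"]
    if len(train_rows) == 0:
        raise ValueError("manifest contains no train-split triplets")

    triplets = [load_triplet(row, root) for _, row in train_rows.iterrows()]
    x_all = _stack_images([t["corrupted"] for t in triplets])
    n_ref_all = np.stack([t["noise"] for t in triplets])
    c_ref_all = np.stack([t["clean"] for t in triplets])
    w = config.loss
    d_ref_all = stripe_degrade(n_ref_all, w.lam)
    atv_ref_all = np.array(
        [
            np.abs(np.diff(c, axis=1)).sum() + np.abs(np.diff(c, axis=0)).sum()
            for c in c_ref_all
        ]
    )

    val = None
    if val_manifest is not None and len(val_manifest):
        val = [load_triplet(row, root) for _, row in val_manifest.iterrows()]

    model = build_srnet(config)
    opt = nn.Adam(model.params(), lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)
    n = x_all.shape[0]
    records = []
    for epoch in range(config.epochs):
        opt.lr = nn.linear_decay_lr(config.lr, epoch, config.epochs_constant, config.epochs_decay)
        perm = rng.permutation(n)
        sums = {"total": 0.0, "recon": 0.0, "stripe": 0.0, "atv": 0.0}
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            x = Tensor(x_all[idx])
            n_out = model(x)
            c_out = relu(x - n_out)
            total, parts = _batch_destripe_loss(
                x, n_out, c_out, d_ref_all[idx], atv_ref_all[idx], w
            )
            if not np.isfinite(total.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch starting at {start}: {parts}"
                )
            opt.zero_grad()
            total.backward()
            opt.step()
            sums["total"] += float(total.data)
            for k in ("recon", "stripe", "atv"):
                sums[k] += parts[k]
            n_batches += 1
        rec = {"epoch": epoch, "lr": opt.lr}
        rec.update({k: v / n_batches for k, v in sums.items()})
        if val is not None:
            psnrs = []
            for t in val:
                _, c_out = destripe(model, t["corrupted"])
                psnrs.append(psnr(t["clean"], c_out))
            rec["val_psnr"] = float(np.mean(psnrs))
        records.append(rec)
    history = pd.DataFrame(records)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_srnet(model, out_dir / "srnet.npz")
        history.to_csv(out_dir / "srnet_history.csv", index=False)
    return model, history


def destripe(model: SRNet, i_in: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predict the stripe-noise map and the de-striped image.

    Inputs whose sides are not divisible by 2**depth are reflect-padded,
    processed, and cropped back.  Deterministic: no stochastic layers.
    """
    img = np.asarray(i_in, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("destripe expects a single 2-D image")
    h, w = img.shape
    f = 2**model.config.depth
    ph = (-h) % f
    pw = (-w) % f
    if ph or pw:
        if h < 2 or w < 2:
            raise ValueError("image too small to pad for the network")
        img_p = np.pad(img, ((0, ph), (0, pw)), mode="reflect")
    else:
        img_p = img
    n_out = model(Tensor(img_p[None, None])).data[0, 0][:h, :w]
    n_out = np.maximum(n_out, 0.0)
    return n_out, compose_clean(img, n_out)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_srnet(model: SRNet, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    sidecar = {"config": model.config.model_dump(), "kind": "srnet"}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_srnet(path) -> SRNet:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    config = SRNetConfig(**sidecar["config"])
    model = build_srnet(config)
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
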