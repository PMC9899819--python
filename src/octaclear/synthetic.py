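"""Synthetic vessel phantoms and additive stripe-noise corruption.

Clinical en-face angiograms with paired clean/corrupted versions are not
publicly available, so every stage of the pipeline is exercised on
phantoms: smooth curvilinear bright vessels on a speckled dark background,
corrupted by additive bright stripe fields.  Two properties of the real
artifact are guaranteed by construction, because the de-striping objective
relies on them:

* additivity — a corruption triplet satisfies corrupted = clean + noise
  exactly, elementwise (noise is recomputed after clipping);
* low rank — a stripe field is a sum of per-stripe rank-1 bands, so its
  matrix rank is bounded by the number of stripes drawn.

The corruption *level* i of an image is the number of independently drawn
stripe fields added to it; higher levels give stronger corruption.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, field_validator, model_validator
from scipy.interpolate import splev, splprep
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from scipy.spatial import cKDTree

from .image_io import read_image, write_image

__all__ = [
    "CorruptionTriplet",
    "StripeFieldParams",
    "VesselPhantomParams",
    "corrupt_image",
    "generate_stripe_field",
    "generate_vessel_phantom",
    "load_triplet",
    "make_dataset",
    "read_manifest",
    "reduce_contrast",
]

MIN_SIZE = 16


class VesselPhantomParams(BaseModel):
    """Parameters of the clean vessel phantom.

    Vessels are bright on a dark textured background; ``intensity_range``
    must therefore lie entirely above ``background_level``.  Widths are in
    pixels (full vessel thickness), ``texture_sd`` is the standard
    deviation of the background speckle and ``blur_sigma`` the final
    Gaussian smoothing in pixels.
    """

    n_vessels: int = 6
    width_range: tuple[float, float] = (1.5, 3.0)
    intensity_range: tuple[float, float] = (0.55, 0.95)
    background_level: float = 0.15
    texture_sd: float = 0.05
    blur_sigma: float = 0.7

    @field_validator("n_vessels")
    @classmethod
    def _nv(cls, v):
        if v < 0:
            raise ValueError("n_vessels must be >= 0")
        return v

    @field_validator("width_range")
    @classmethod
    def _wr(cls, v):
        if not (0 < v[0] <= v[1]):
            raise ValueError("width_range must be a non-empty positive range")
        return v

    @field_validator("intensity_range")
    @classmethod
    def _ir(cls, v):
        if not (0 <= v[0] <= v[1] <= 1):
            raise ValueError("intensity_range must be a non-empty range within [0, 1]")
        return v

    @field_validator("background_level")
    @classmethod
    def _bg(cls, v):
        if not 0 <= v <= 1:
            raise ValueError("background_level must be in [0, 1]")
        return v

    @field_validator("texture_sd", "blur_sigma")
    @classmethod
    def _sd(cls, v, info):
        if v < 0:
            raise ValueError(f"{info.field_name} must be >= 0")
        return v

    @model_validator(mode="after")
    def _bright_on_dark(self):
        if self.intensity_range[0] <= self.background_level:
            raise ValueError(
                "intensity_range must lie entirely above background_level "
                "(vessels are bright on a dark background)"
            )
        return self


class StripeFieldParams(BaseModel):
    """Parameters of one additive stripe-noise field.

    A field holds a Poisson(``n_stripes_mean``) number of parallel bands of
    the configured orientation.  Each band has its own thickness (pixels),
    amplitude (additive intensity) and position; with probability
    ``full_span_prob`` it spans the full row/column, otherwise it covers a
    random fraction of at least ``min_fraction`` of it.
    """

    orientation: Literal["horizontal", "vertical"] = "horizontal"
    n_stripes_mean: float = 3.0
    thickness_range: tuple[int, int] = (1, 4)
    amplitude_range: tuple[float, float] = (0.1, 0.5)
    full_span_prob: float = 0.7
    min_fraction: float = 0.3

    @field_validator("n_stripes_mean")
    @classmethod
    def _nm(cls, v):
        if v < 0:
            raise ValueError("n_stripes_mean must be >= 0")
        return v

    @field_validator("thickness_range")
    @classmethod
    def _tr(cls, v):
        if not (1 <= v[0] <= v[1]):
            raise ValueError("thickness_range must be a non-empty range of >= 1 pixels")
        return v

    @field_validator("amplitude_range")
    @classmethod
    def _ar(cls, v):
        if not (0 < v[0] <= v[1] <= 1):
            raise ValueError("amplitude_range must be a non-empty range within (0, 1]")
        return v

    @field_validator("full_span_prob")
    @classmethod
    def _fsp(cls, v):
        if not 0 <= v <= 1:
            raise ValueError("full_span_prob must be in [0, 1]")
        return v

    @field_validator("min_fraction")
    @classmethod
    def _mf(cls, v):
        if not 0 < v <= 1:
            raise ValueError("min_fraction must be in (0, 1]")
        return v


@dataclass(frozen=True)
class CorruptionTriplet:
    """(clean, noise, corrupted) with corrupted = clean + noise exactly."""

    clean: np.ndarray
    noise: np.ndarray
    corrupted: np.ndarray
    level: int


def _check_dims(height: int, width: int) -> None:
    if height < MIN_SIZE or width < MIN_SIZE:
        raise ValueError(f"height and width must be >= {MIN_SIZE}, got {height}x{width}")


# ---------------------------------------------------------------------------
# phantom generation
# ---------------------------------------------------------------------------

def _random_vessel_curve(rng: np.random.Generator, height: int, width: int) -> np.ndarray:
    """Dense samples of a smooth random curve crossing the image."""
    # endpoints on opposite borders plus interior waypoints
    if rng.random() < 0.5:  # roughly left-right
        xs = np.array([0.0, width - 1.0])
        ys = rng.uniform(0, height - 1, size=2)
    else:
        ys = np.array([0.0, height - 1.0])
        xs = rng.uniform(0, width - 1, size=2)
    n_mid = int(rng.integers(2, 4))
    t_mid = np.sort(rng.uniform(0.2, 0.8, size=n_mid))
    mx = xs[0] + t_mid * (xs[1] - xs[0]) + rng.normal(0, 0.12 * width, size=n_mid)
    my = ys[0] + t_mid * (ys[1] - ys[0]) + rng.normal(0, 0.12 * height, size=n_mid)
    px = np.concatenate([[xs[0]], mx, [xs[1]]])
    py = np.concatenate([[ys[0]], my, [ys[1]]])
    tck, _ = splprep([px, py], s=0, k=min(3, len(px) - 1))
    t = np.linspace(0, 1, 4 * max(height, width))
    cx, cy = splev(t, tck)
    return np.column_stack([cx, cy])


def generate_vessel_phantom(
    seed: int,
    height: int,
    width: int,
    params: VesselPhantomParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a clean vessel phantom and its exact binary vessel mask.

    Returns ``(image, mask)``: ``image`` is float64 in [0, 1], ``mask`` is
    boolean, True exactly on pixels within half a vessel width of a vessel
    centreline.  Deterministic for a fixed seed.
    """
    params = params or VesselPhantomParams()
    _check_dims(height, width)
    rng = np.random.default_rng(seed)

    texture = gaussian_filter(rng.standard_normal((height, width)), 1.2)
    sd = texture.std()
    if sd > 0:
        texture /= sd
    img = params.background_level + params.texture_sd * texture
    mask = np.zeros((height, width), dtype=bool)

    yy, xx = np.mgrid[0:height, 0:width]
    grid = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)

    for _ in range(params.n_vessels):
        curve = _random_vessel_curve(rng, height, width)
        w = rng.uniform(*params.width_range)
        a = rng.uniform(*params.intensity_range)
        r = w / 2.0
        dist = cKDTree(curve).query(grid, workers=1)[0].reshape(height, width)
        mask |= dist <= r
        profile = a * np.exp(-0.5 * (dist / max(r, 0.5)) ** 2)
        img = np.maximum(img, profile)

    img = gaussian_filter(img, params.blur_sigma) if params.blur_sigma > 0 else img
    return np.clip(img, 0.0, 1.0), mask


def reduce_contrast(image: np.ndarray, factor: float, pivot: float = 0.15) -> np.ndarray:
    """Compress intensities toward ``pivot``: pivot + factor*(image - pivot)."""
    if not 0 < factor <= 1:
        raise ValueError("factor must be in (0, 1]")
    return np.clip(pivot + factor * (np.asarray(image, dtype=np.float64) - pivot), 0.0, 1.0)


# ---------------------------------------------------------------------------
# stripe fields and corruption
# ---------------------------------------------------------------------------

def generate_stripe_field(
    seed: int,
    height: int,
    width: int,
    params: StripeFieldParams | None = None,
    return_specs: bool = False,
):
    """Draw one additive stripe-noise field.

    The field is non-negative and is a sum of per-stripe rank-1 bands; the
    1-pixel Gaussian smoothing applied along each stripe's short axis keeps
    the per-stripe rank at one, so the matrix rank of the whole field never
    exceeds the number of stripes drawn.
    """
    params = params or StripeFieldParams()
    _check_dims(height, width)
    rng = np.random.default_rng(seed)
    field = np.zeros((height, width))
    k = int(rng.poisson(params.n_stripes_mean))
    specs = []
    long_len = width if params.orientation == "horizontal" else height
    short_len = height if params.orientation == "horizontal" else width
    for _ in range(k):
        thick = int(rng.integers(params.thickness_range[0], params.thickness_range[1] + 1))
        amp = rng.uniform(*params.amplitude_range)
        pos = int(rng.integers(0, max(short_len - thick, 0) + 1))
        if rng.random() < params.full_span_prob:
            start, stop = 0, long_len
        else:
            frac = rng.uniform(params.min_fraction, 1.0)
            length = max(1, int(round(frac * long_len)))
            start = int(rng.integers(0, long_len - length + 1))
            stop = start + length
        band = np.zeros((height, width))
        if params.orientation == "horizontal":
            band[pos : pos + thick, start:stop] = amp
            band = gaussian_filter1d(band, 1.0, axis=0)
        else:
            band[start:stop, pos : pos + thick] = amp
            band = gaussian_filter1d(band, 1.0, axis=1)
        field += band
        specs.append({"pos": pos, "thickness": thick, "amplitude": amp, "span": (start, stop)})
    if return_specs:
        return field, specs
    return field


def corrupt_image(
    clean: np.ndarray,
    level: int,
    seed: int,
    params: StripeFieldParams | None = None,
) -> CorruptionTriplet:
    """Add ``level`` independent stripe fields to a clean image.

    The sum is clipped to [0, 1] and the stored noise is recomputed as
    corrupted - clean so that the additive identity holds exactly even
    where clipping was active.
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    clean = np.asarray(clean, dtype=np.float64)
    if clean.ndim != 2:
        raise ValueError("clean must be a 2-D image")
    h, w = clean.shape
    rng_seeds = np.random.SeedSequence(seed).spawn(level)
    total = np.zeros_like(clean)
    for ss in rng_seeds:
        child_seed = int(ss.generate_state(1)[0] % (2**31))
        total += generate_stripe_field(child_seed, h, w, params)
    corrupted = np.clip(clean + total, 0.0, 1.0)
    noise = corrupted - clean
    return CorruptionTriplet(clean=clean, noise=noise, corrupted=corrupted, level=level)


# ---------------------------------------------------------------------------
# dataset writer
# ---------------------------------------------------------------------------

def make_dataset(
    n_images: int,
    levels: Sequence[int],
    seed: int,
    out_dir: str | Path,
    size: int = 64,
    phantom_params: VesselPhantomParams | None = None,
    stripe_params: StripeFieldParams | None = None,
    train_fraction: float = 0.8,
) -> pd.DataFrame:
    """Write a reproducible corruption dataset and its manifest.

    For each of ``n_images`` phantoms and each level in ``levels`` a
    triplet (clean, noise, corrupted, 16-bit PNG) plus the vessel mask
    (8-bit PNG) is written under ``out_dir``.  The manifest (TSV) records
    id, level, split, the exact seeds used and all file paths, and is
    sufficient to regenerate the arrays bit for bit.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    levels = list(levels)
    if not levels or any(lv < 1 for lv in levels):
        raise ValueError("levels must be a non-empty list of positive integers")
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)

    n_train = int(round(train_fraction * n_images))
    rows = []
    for i in range(n_images):
        phantom_seed = (seed * 100003 + i) % (2**31)
        clean, mask = generate_vessel_phantom(phantom_seed, size, size, phantom_params)
        split = "train" if i < n_train else "test"
        mask_path = f"images/{i:04d}_mask.png"
        write_image(mask.astype(np.float64), out / mask_path, bit_depth=8)
        clean_path = f"images/{i:04d}_clean.png"
        write_image(clean, out / clean_path, bit_depth=16)
        for lv in levels:
            corrupt_seed = (seed * 1000003 + i * 101 + lv) % (2**31)
            triplet = corrupt_image(clean, lv, corrupt_seed, stripe_params)
            base = f"images/{i:04d}_l{lv}"
            write_image(triplet.noise, out / f"{base}_noise.png", bit_depth=16)
            write_image(triplet.corrupted, out / f"{base}_corrupted.png", bit_depth=16)
            rows.append(
                {
                    "id": f"{i:04d}_l{lv}",
                    "image": i,
                    "level": lv,
                    "split": split,
                    "phantom_seed": phantom_seed,
                    "corrupt_seed": corrupt_seed,
                    "clean": clean_path,
                    "mask": mask_path,
                    "noise": f"{base}_noise.png",
                    "corrupted": f"{base}_corrupted.png",
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return manifest


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.is_dir():
        path = path / "manifest.tsv"
    return pd.read_csv(path, sep="\t")


def load_triplet(row: pd.Series, root: str | Path) -> dict[str, np.ndarray]:
    """Read the four arrays of one manifest row back from disk."""
    root = Path(root)
    return {
        "clean": read_image(root / row["clean"]),
        "noise": read_image(root / row["noise"]),
        "corrupted": read_image(root / row["corrupted"]),
        "mask": read_image(root / row["mask"]) > 0.5,
    }


def manifest_checksum(out_dir: str | Path) -> str:
    """SHA-256 over the manifest plus every referenced file (determinism aid)."""
    out = Path(out_dir)
    h = hashlib.sha256()
    h.update((out / "manifest.tsv").read_bytes())
    manifest = read_manifest(out)
    paths = set()
    for col in ("clean", "mask", "noise", "corrupted"):
        paths.update(manifest[col])
    for p in sorted(paths):
        h.update((out / p).read_bytes())
    return h.hexdigest()
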