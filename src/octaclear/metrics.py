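"""Image-fidelity and segmentation-based evaluation.

Two validation routes are provided, matching how de-striping and
enhancement results are judged in this field:

1. fidelity against a known clean reference — PSNR and SSIM;
2. vessel-segmentation overlap — a simple deterministic baseline
   segmenter produces a binary mask that is compared with the ground-truth
   vessel mask through Dice, sensitivity, specificity and G-mean.

Note on specificity: one published formulation of the G-mean writes
``Spe = FP/(FP+TN)``, which is the false-positive rate and would make the
G-mean *fall* as a classifier improves.  This module uses the standard
``Spe = TN/(TN+FP)``; the geometric mean of sensitivity and specificity
then behaves as a larger-is-better score.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.filters import threshold_otsu

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "baseline_segment",
    "confusion_counts",
    "dice",
    "evaluate",
    "gmean",
    "psnr",
    "sensitivity",
    "specificity",
    "ssim",
]


# ---------------------------------------------------------------------------
# fidelity metrics
# ---------------------------------------------------------------------------

def psnr(reference: np.ndarray, test: np.ndarray, max_val: float = 1.0) -> float:
    """10*log10(max_val^2 / MSE); returns +inf for identical images."""
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if reference.shape != test.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {test.shape}")
    if max_val <= 0:
        raise ValueError("max_val must be > 0")
    mse = float(np.mean((reference - test) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(max_val**2 / mse)


def ssim(
    reference: np.ndarray,
    test: np.ndarray,
    max_val: float = 1.0,
    sigma: float = 1.5,
    k1: float = 0.01,
    k2: float = 0.03,
) -> float:
    """Mean local SSIM with a Gaussian 11x11 (sigma=1.5) window.

    Standard luminance/contrast/structure form with population
    (weighted-window) moments; an edge strip of the filter radius is
    excluded from the mean to avoid boundary effects.
    """
    x = np.asarray(reference, dtype=np.float64)
    y = np.asarray(test, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    truncate = 3.5
    r = int(truncate * sigma + 0.5)
    win = 2 * r + 1
    if min(x.shape) < win:
        raise ValueError(f"image smaller than the {win}x{win} SSIM window")

    def filt(a):
        return gaussian_filter(a, sigma=sigma, truncate=truncate, mode="reflect")

    ux, uy = filt(x), filt(y)
    vx = filt(x * x) - ux * ux
    vy = filt(y * y) - uy * uy
    vxy = filt(x * y) - ux * uy
    c1 = (k1 * max_val) ** 2
    c2 = (k2 * max_val) ** 2
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / ((ux**2 + uy**2 + c1) * (vx + vy + c2))
    pad = (win - 1) // 2
    return float(s[pad:-pad, pad:-pad].mean())


# ---------------------------------------------------------------------------
# segmentation metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _as_binary(mask: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.dtype == bool:
        return arr
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"{name} must be binary (bool or 0/1)")
    return arr.astype(bool)


def confusion_counts(predicted: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    pred = _as_binary(predicted, "predicted")
    true = _as_binary(truth, "truth")
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {true.shape}")
    tp = int(np.sum(pred & true))
    tn = int(np.sum(~pred & ~true))
    fp = int(np.sum(pred & ~true))
    fn = int(np.sum(~pred & true))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: zero denominator, returning NaN sentinel", stacklevel=3)
        return math.nan
    return num / den


def dice(counts: ConfusionCounts) -> float:
    """2TP / (2TP + FP + FN)."""
    return _safe_ratio(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn, "dice")


def sensitivity(counts: ConfusionCounts) -> float:
    """TP / (TP + FN) (recall on vessel pixels)."""
    return _safe_ratio(counts.tp, counts.tp + counts.fn, "sensitivity")


def specificity(counts: ConfusionCounts) -> float:
    """TN / (TN + FP)."""
    return _safe_ratio(counts.tn, counts.tn + counts.fp, "specificity")


def gmean(counts: ConfusionCounts) -> float:
    """sqrt(sensitivity * specificity)."""
    sen = sensitivity(counts)
    spe = specificity(counts)
    if math.isnan(sen) or math.isnan(spe):
        return math.nan
    return math.sqrt(sen * spe)


# ---------------------------------------------------------------------------
# baseline vessel segmentation
# ---------------------------------------------------------------------------

def baseline_segment(
    image: np.ndarray,
    method: str = "percentile",
    percentile: float = 75.0,
    highpass_sigma: float = 8.0,
) -> np.ndarray:
    """Deterministic global-threshold vessel segmentation.

    The slowly varying background is removed with a Gaussian high-pass
    (image minus a ``highpass_sigma`` blur), then a global threshold is
    applied: the given intensity percentile, or Otsu's method.  A constant
    image yields an empty mask with a warning.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("baseline_segment expects a 2-D image")
    if img.max() == img.min():
        warnings.warn("constant image: returning an empty mask", stacklevel=2)
        return np.zeros_like(img, dtype=bool)
    hp = img - gaussian_filter(img, highpass_sigma) if highpass_sigma > 0 else img
    if method == "percentile":
        thr = np.percentile(hp, percentile)
    elif method == "otsu":
        thr = threshold_otsu(hp)
    else:
        raise ValueError(f"unknown segmentation method: {method!r}")
    return hp > thr


# ---------------------------------------------------------------------------
# evaluation harness
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    """Per-image metric table plus mean +/- sd aggregates."""

    per_image: pd.DataFrame
    aggregate: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def write(self, out_prefix) -> None:
        from pathlib import Path

        out_prefix = Path(out_prefix)
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
        self.per_image.to_csv(f"{out_prefix}_per_image.csv", index=False)
        payload = {
            "provenance": self.provenance,
            "aggregate": self.aggregate.to_dict(orient="records"),
        }
        import json

        with open(f"{out_prefix}_aggregate.json", "w") as fh:
            json.dump(payload, fh, indent=2, default=float)


_FIDELITY = ("psnr", "ssim")
_SEGMENT = ("dice", "sen", "spe", "gmean")


def metrics_for_pair(
    clean: np.ndarray,
    test: np.ndarray,
    mask: np.ndarray | None = None,
    metrics: tuple[str, ...] = _FIDELITY + _SEGMENT,
    border: int = 2,
    segment_kwargs: dict | None = None,
) -> dict[str, float]:
    """Compute the requested metrics for one (reference, test) image pair."""
    out: dict[str, float] = {}
    if "psnr" in metrics:
        out["psnr"] = psnr(clean, test)
    if "ssim" in metrics:
        out["ssim"] = ssim(clean, test)
    seg_wanted = [m for m in metrics if m in _SEGMENT]
    if seg_wanted:
        if mask is None:
            raise ValueError("segmentation metrics requested but no ground-truth mask given")
        pred = baseline_segment(test, **(segment_kwargs or {}))
        if border > 0:
            sl = (slice(border, -border), slice(border, -border))
            counts = confusion_counts(pred[sl], np.asarray(mask, bool)[sl])
        else:
            counts = confusion_counts(pred, mask)
        fns = {"dice": dice, "sen": sensitivity, "spe": specificity, "gmean": gmean}
        for m in seg_wanted:
            out[m] = fns[m](counts)
    return out


def evaluate(
    manifest: pd.DataFrame,
    root,
    conditions: dict,
    metrics: tuple[str, ...] = _FIDELITY + _SEGMENT,
    border: int = 2,
    segment_kwargs: dict | None = None,
    provenance: dict | None = None,
) -> MetricReport:
    """Evaluate one or more processing conditions over a dataset manifest.

    ``conditions`` maps a condition name (e.g. ``corrupted``, ``destriped``,
    ``enhanced``) to a callable ``row_arrays -> image`` producing the image
    to score for that manifest row; ``row_arrays`` is the dict returned by
    :func:`octaclear.synthetic.load_triplet`.  Aggregates (mean, sd) are
    reported per condition and noise level.
    """
    from .synthetic import load_triplet

    rows = []
    for _, row in manifest.iterrows():
        arrays = load_triplet(row, root)
        for cond, producer in conditions.items():
            img = producer(arrays)
            vals = metrics_for_pair(
                arrays["clean"], img, arrays["mask"], metrics, border, segment_kwargs
            )
            rows.append({"id": row["id"], "level": row["level"], "condition": cond, **vals})
    per_image = pd.DataFrame(rows)
    value_cols = [c for c in per_image.columns if c not in ("id", "level", "condition")]
    agg = (
        per_image.replace([np.inf, -np.inf], np.nan)
        .groupby(["condition", "level"])[value_cols]
        .agg(["mean", "std"])
    )
    agg.columns = ["_".join(c) for c in agg.columns]
    aggregate = agg.reset_index()
    return MetricReport(per_image=per_image, aggregate=aggregate, provenance=provenance or {})
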