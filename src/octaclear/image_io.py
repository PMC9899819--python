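"""Reading and writing grayscale images normalized to [0, 1].

PNG files are handled through Pillow, TIFF through tifffile.  On read,
integer images are divided by the container maximum (255 or 65535); RGB
input is coerced to grayscale by the Rec. 601 luminance with a logged
warning.  On write, values are quantized with round-half-up so a
read-after-write round trip is exact to within one quantization step.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

logger = logging.getLogger(__name__)

__all__ = ["read_image", "write_image"]

_LUMA = np.array([0.299, 0.587, 0.114])


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image as float64 in [0, 1]."""
    path = Path(path)
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        elif suffix == ".png":
            with Image.open(path) as im:
                arr = np.asarray(im)
        else:
            raise OSError(f"unsupported image format: {path}")
    except FileNotFoundError:
        raise
    except OSError as exc:
        raise OSError(f"could not read image {path}: {exc}") from exc
    if arr.ndim == 3:
        logger.warning("converting RGB image %s to grayscale by luminance", path)
        arr = arr[..., :3].astype(np.float64) @ _LUMA
        # luminance of 8/16-bit channels keeps the original scale
        scale = 255.0 if arr.max() <= 255.0 else 65535.0
        return np.clip(arr / scale, 0.0, 1.0)
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    if np.issubdtype(arr.dtype, np.floating):
        return np.clip(arr.astype(np.float64), 0.0, 1.0)
    raise OSError(f"unsupported pixel type {arr.dtype} in {path}")


def write_image(image: np.ndarray, path: str | Path, bit_depth: int = 16) -> None:
    """Write a [0, 1] image quantized to 8 or 16 bits (round-half-up)."""
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("write_image expects a 2-D image")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    maxv = 2**bit_depth - 1
    q = np.floor(np.clip(image, 0.0, 1.0) * maxv + 0.5)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, q.astype(np.uint8 if bit_depth == 8 else np.uint16))
        return
    if suffix != ".png":
        raise OSError(f"unsupported image format: {path}")
    if bit_depth == 8:
        Image.fromarray(q.astype(np.uint8)).save(path)
    else:
        Image.fromarray(q.astype(np.uint16)).save(path)
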