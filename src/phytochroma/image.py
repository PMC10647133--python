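"""8-bit sRGB raster handling shared by the pipeline stages.

Images are plain ``numpy`` arrays of shape (H, W, 3), dtype ``uint8``,
sRGB-encoded. PNG and JPEG round-trip through Pillow.
"""

from __future__ import annotations

import os

import numpy as np
from PIL import Image


class PhytochromaError(Exception):
    """Base class for pipeline errors."""


class ShapeError(PhytochromaError):
    """Image dimensions do not satisfy an operation's contract."""


def validate_image(pixels: np.ndarray) -> np.ndarray:
    """Check that ``pixels`` is an H×W×3 raster with channels in [0, 255].

    Returns the array as ``uint8`` (copying only if a cast is needed).
    """
    arr = np.asarray(pixels)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ShapeError(f"expected an H×W×3 RGB raster, got shape {arr.shape}")
    if arr.size and (arr.min() < 0 or arr.max() > 255):
        raise ValueError("channel values must lie in [0, 255]")
    return arr.astype(np.uint8, copy=False)


def clip_round(values: np.ndarray) -> np.ndarray:
    """Clip to [0, 255] and round half-up to 8-bit integers."""
    clipped = np.clip(np.asarray(values, dtype=np.float64), 0.0, 255.0)
    return np.floor(clipped + 0.5).clip(0, 255).astype(np.uint8)


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG/JPEG file as an 8-bit RGB array (alpha discarded)."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def save_image(pixels: np.ndarray, path: str | os.PathLike) -> None:
    """Write an 8-bit RGB array to PNG or JPEG, inferred from the suffix."""
    Image.fromarray(validate_image(pixels), mode="RGB").save(path)
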