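"""Physical size calibration and per-object colour extraction.

Sizes are converted from pixels to physical units via a reference object
of known dimensions captured in the same photograph (the left-most object
by convention).  Mean object colour is reported in three colour spaces:
sRGB (as captured), YUV (BT.601 full-range, +128 chroma offset) and
CIELAB under illuminant D65 and the 2° standard observer.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass

import numpy as np

from .image import PhytochromaError, validate_image
from .segmentation import DetectedObject


class DegenerateObjectError(PhytochromaError):
    """An object has no pixels to measure."""


@dataclass(frozen=True)
class SizeCalibration:
    """Physical units per pixel along each image axis."""

    scale_x: float
    scale_y: float
    unit_name: str = "mm"

    def __post_init__(self):
        if self.scale_x <= 0 or self.scale_y <= 0:
            raise ValueError("scales must be positive")


@dataclass(frozen=True)
class ObjectMeasurement:
    """Per-object physical size and mean colour in RGB, YUV and CIELAB."""

    label: str
    width: float
    height: float
    area: float
    mean_rgb: tuple[float, float, float]
    mean_yuv: tuple[float, float, float]
    mean_lab: tuple[float, float, float]


def calibrate_scale(
    reference: DetectedObject, known_width: float, known_height: float,
    unit_name: str = "mm",
) -> SizeCalibration:
    """Derive per-axis scales from the known-size reference object."""
    if known_width <= 0 or known_height <= 0:
        raise ValueError("known reference dimensions must be positive")
    bb = reference.bounding_box
    if bb.width < 1 or bb.height < 1 or reference.pixel_count == 0:
        raise DegenerateObjectError("reference object has zero pixel extent")
    return SizeCalibration(
        scale_x=known_width / bb.width,
        scale_y=known_height / bb.height,
        unit_name=unit_name,
    )


def mean_object_colour(image: np.ndarray, obj: DetectedObject) -> tuple[float, float, float]:
    """Arithmetic mean RGB over the object's mask pixels only."""
    img = validate_image(image)
    if obj.pixel_count == 0:
        raise DegenerateObjectError(f"object {obj.label!r} has an empty mask")
    vals = img[obj.mask].astype(np.float64)
    return tuple(vals.mean(axis=0))


def measure_object(
    obj: DetectedObject, cal: SizeCalibration, image: np.ndarray | None = None
) -> ObjectMeasurement:
    """Axis-aligned physical extents, calibrated area and mean colours.

    Width and height are the mask's maximum x/y extents scaled per axis;
    area is the mask pixel count times the pixel's physical footprint.
    """
    if obj.pixel_count == 0:
        raise DegenerateObjectError(f"object {obj.label!r} has an empty mask")
    ys, xs = np.nonzero(obj.mask)
    px_w = int(xs.max() - xs.min() + 1)
    px_h = int(ys.max() - ys.min() + 1)
    if image is not None:
        rgb = mean_object_colour(image, obj)
    else:
        rgb = (0.0, 0.0, 0.0)
    return ObjectMeasurement(
        label=obj.label,
        width=px_w * cal.scale_x,
        height=px_h * cal.scale_y,
        area=obj.pixel_count * cal.scale_x * cal.scale_y,
        mean_rgb=rgb,
        mean_yuv=tuple(rgb_to_yuv(rgb)),
        mean_lab=tuple(rgb_to_lab(rgb)),
    )


# ---------------------------------------------------------------------------
# Colour-space conversions
# ---------------------------------------------------------------------------

# BT.601 full-range luma/chroma matrix
_YUV_MATRIX = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.168736, -0.331264, 0.5],
        [0.5, -0.418688, -0.081312],
    ]
)

# sRGB primaries → CIE XYZ (D65), IEC 61966-2-1
_RGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)

# D65 white point, 2° observer
_WHITE_D65 = np.array([0.95047, 1.00000, 1.08883])


def rgb_to_yuv(rgb) -> np.ndarray:
    """8-bit RGB → BT.601 full-range YUV with +128 chroma offset."""
    x = np.asarray(rgb, dtype=np.float64)
    yuv = x @ _YUV_MATRIX.T
    yuv[..., 1:] += 128.0
    return yuv


def _srgb_decode(u: np.ndarray) -> np.ndarray:
    """Inverse sRGB transfer function: display-referred [0,1] → linear light."""
    return np.where(u <= 0.04045, u / 12.92, ((u + 0.055) / 1.055) ** 2.4)


def rgb_to_lab(rgb) -> np.ndarray:
    """8-bit sRGB → CIELAB (D65, 2° observer).

    Gamma-decode to linear light, project to XYZ, then apply the CIELAB
    forward function with its cube-root / linear-piecewise split.
    """
    x = np.asarray(rgb, dtype=np.float64) / 255.0
    xyz = _srgb_decode(x) @ _RGB_TO_XYZ.T
    t = xyz / _WHITE_D65
    delta = 6.0 / 29.0
    f = np.where(t > delta**3, np.cbrt(t), t / (3 * delta**2) + 4.0 / 29.0)
    fx, fy, fz = f[..., 0], f[..., 1], f[..., 2]
    return np.stack([116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)], axis=-1)


# ---------------------------------------------------------------------------
# Results export
# ---------------------------------------------------------------------------

RESULTS_HEADER = ["object", "width", "height", "area", "R", "G", "B", "Y", "U", "V", "L", "a", "b"]


def write_results_csv(
    measurements: list[ObjectMeasurement], path: str | os.PathLike,
    unit_name: str | None = None,
) -> None:
    """Write one row per object (floats at 3 d.p.); unit metadata in a sidecar JSON."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(RESULTS_HEADER)
        for m in measurements:
            row = [m.label] + [
                f"{v:.3f}"
                for v in (m.width, m.height, m.area, *m.mean_rgb, *m.mean_yuv, *m.mean_lab)
            ]
            writer.writerow(row)
    if unit_name is not None:
        sidecar = os.fspath(path) + ".meta.json"
        with open(sidecar, "w") as fh:
            json.dump({"unit": unit_name, "columns": RESULTS_HEADER}, fh, indent=2)
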