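"""White-background removal and object separation.

Plant material is photographed on a white background; background pixels
are identified by colour thresholding (near-white: every channel at or
above the threshold), the foreground mask is cleaned by morphological
opening then closing, and individual objects are extracted from a Canny
edge map via connected external contours, sorted left-to-right.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import feature, morphology

from .image import PhytochromaError, clip_round, validate_image

WHITE = np.array([255, 255, 255], dtype=np.uint8)


def _drop_small_components(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Remove connected components with fewer than ``min_area`` pixels."""
    lab, n = ndimage.label(mask)
    if n == 0:
        return mask
    counts = np.bincount(lab.ravel())
    keep = counts >= min_area
    keep[0] = False
    return keep[lab]


class BoundsError(PhytochromaError):
    """A region of interest does not lie within the host image."""


@dataclass(frozen=True)
class RegionOfInterest:
    """Axis-aligned crop window: 0-based top-left origin, half-open extent."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self):
        if self.width < 1 or self.height < 1:
            raise ValueError("ROI width and height must be >= 1")
        if self.x0 < 0 or self.y0 < 0:
            raise BoundsError("ROI origin must be non-negative")


@dataclass(frozen=True)
class DetectedObject:
    """A single segmented object: binary mask, tight bounding box, label."""

    mask: np.ndarray                # full-image boolean raster
    bounding_box: RegionOfInterest
    label: str
    pixel_count: int = field(init=False)

    def __post_init__(self):
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "pixel_count", int(mask.sum()))

    def extract(self, image: np.ndarray) -> np.ndarray:
        """The object's bounding-box sub-image on a pure white background."""
        img = validate_image(image)
        bb = self.bounding_box
        sub = img[bb.y0 : bb.y0 + bb.height, bb.x0 : bb.x0 + bb.width].copy()
        submask = self.mask[bb.y0 : bb.y0 + bb.height, bb.x0 : bb.x0 + bb.width]
        sub[~submask] = WHITE
        return sub


def crop_roi(image: np.ndarray, roi: RegionOfInterest) -> np.ndarray:
    """Cut the ROI out of the image; the ROI must lie fully inside it."""
    img = validate_image(image)
    h, w = img.shape[:2]
    if roi.x0 + roi.width > w or roi.y0 + roi.height > h:
        raise BoundsError(
            f"ROI {roi} exceeds image bounds {w}×{h}"
        )
    return img[roi.y0 : roi.y0 + roi.height, roi.x0 : roi.x0 + roi.width].copy()


def remove_background(
    image: np.ndarray,
    threshold: int = 150,
    min_object_area: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Replace the near-white background with pure white.

    A pixel is background when all three channels are >= ``threshold``
    (150 is a good starting value for a lightbox scene).  The foreground
    mask is cleaned by morphological opening then closing with a 5×5
    elliptical structuring element, and connected components smaller than
    ``min_object_area`` pixels are discarded.

    Returns ``(cleaned image, foreground mask)``.
    """
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must lie in [0, 255], got {threshold}")
    img = validate_image(image)
    foreground = ~(img >= threshold).all(axis=2)
    selem = morphology.disk(2)  # 5×5 ellipse
    cleaned = morphology.closing(morphology.opening(foreground, selem), selem)
    if min_object_area > 0:
        cleaned = _drop_small_components(cleaned, min_object_area)
    out = img.copy()
    out[~cleaned] = WHITE
    return out, cleaned


def separate_objects(
    image: np.ndarray,
    labels: list[str] | None = None,
    min_object_area: int = 500,
    canny_low: float = 50.0,
    canny_high: float = 150.0,
) -> list[DetectedObject]:
    """Split a white-background image into individual objects.

    Canny edges are extracted, closed into external contours, filled, and
    each connected region of at least ``min_object_area`` pixels becomes a
    ``DetectedObject``.  Objects are sorted left-to-right by bounding-box
    x0 (ties broken by y0); touching objects merge into one (documented
    limitation).  ``labels`` are assigned in sorted order; missing labels
    are auto-generated (``obj_001`` …).
    """
    img = validate_image(image)
    gray = img.astype(np.float64).mean(axis=2) / 255.0
    edges = feature.canny(
        gray, sigma=1.0, low_threshold=canny_low / 255.0, high_threshold=canny_high / 255.0
    )
    closed = morphology.closing(edges, morphology.disk(2))
    filled = ndimage.binary_fill_holes(closed)
    # the closed contour overshoots the object by ~1 px; the background is
    # pure white by contract, so intersecting restores the exact extent
    non_white = ~(img == 255).all(axis=2)
    lab, n = ndimage.label(filled)
    objects = []
    for i in range(1, n + 1):
        mask = (lab == i) & non_white
        if mask.sum() < min_object_area:
            continue
        ys, xs = np.nonzero(mask)
        bb = RegionOfInterest(
            x0=int(xs.min()), y0=int(ys.min()),
            width=int(xs.max() - xs.min() + 1), height=int(ys.max() - ys.min() + 1),
        )
        objects.append((bb.x0, bb.y0, mask, bb))
    objects.sort(key=lambda t: (t[0], t[1]))
    result = []
    for idx, (_, _, mask, bb) in enumerate(objects):
        if labels is not None and idx < len(labels):
            name = labels[idx]
        else:
            name = f"obj_{idx + 1:03d}"
        result.append(DetectedObject(mask=mask, bounding_box=bb, label=name))
    return result
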