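"""Flat-field background correction and checker-based colour correction.

The colour-accuracy machinery works on a 24-swatch checker card: the card
is located in the photograph, the mean RGB of each swatch is sampled, and a
per-channel third-order polynomial regression maps observed colours onto
the card's known reference sRGB values.  The fitted transform is then
applied to every pixel of the photograph.  Colour accuracy is scored as the
Euclidean distance in RGB space (ΔRGB) between observed and reference
swatches, averaged over the 24 patches.

Swatch ordering convention
--------------------------
Reference CSVs and sampled grids use a single column-major convention in
the card's logical landscape frame (4 rows × 6 columns): entry ``i`` is the
swatch at row ``i % 4``, column ``i // 4``, rows top-to-bottom and columns
left-to-right.  The anchor swatch — the light-blue patch on the shipped
default card — sits at the logical top-right (index 20) and is used to
resolve the card's orientation in the photograph.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import PhytochromaError, ShapeError, clip_round, validate_image

N_SWATCHES = 24
GRID_ROWS = 4
GRID_COLS = 6
ANCHOR_INDEX = 20  # logical top-right in the column-major convention
ORDER_CONVENTION = "column-major-4x6-anchor-top-right"

# Default 24-patch reference (sRGB), column-major per the convention above.
# Column 0 is the neutral ramp; index 20 is the light-blue anchor patch.
_DEFAULT_REFERENCE = [
    (249, 242, 238), (202, 198, 195), (161, 157, 154), (122, 118, 116),
    (80, 80, 78), (43, 41, 43), (0, 127, 159), (192, 75, 145),
    (245, 205, 0), (186, 26, 51), (57, 146, 64), (25, 55, 135),
    (222, 118, 32), (58, 88, 159), (195, 79, 95), (83, 58, 106),
    (157, 188, 54), (238, 158, 25), (112, 76, 60), (126, 125, 174),
    (98, 187, 166), (197, 145, 125), (87, 120, 155), (82, 106, 60),
]


class FormatError(PhytochromaError):
    """A file does not follow the documented dialect."""


class DetectionError(PhytochromaError):
    """No usable checker card could be located."""


class FitError(PhytochromaError):
    """The correction regression is not identifiable."""


@dataclass(frozen=True)
class SwatchSet:
    """24 reference sRGB triples in the documented order."""

    reference_rgb: np.ndarray  # (24, 3) float64
    order_convention: str = ORDER_CONVENTION

    def __post_init__(self):
        arr = np.asarray(self.reference_rgb, dtype=np.float64)
        if arr.shape != (N_SWATCHES, 3):
            raise FormatError(
                f"a swatch set needs exactly {N_SWATCHES} RGB triples, got shape {arr.shape}"
            )
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("swatch values must lie in [0, 255]")
        if len({tuple(row) for row in arr.tolist()}) != N_SWATCHES:
            raise ValueError("swatch triples must be distinct")
        object.__setattr__(self, "reference_rgb", arr)


@dataclass(frozen=True)
class SwatchGrid:
    """Observed mean colours of the 24 swatches plus their image geometry."""

    observed_rgb: np.ndarray        # (24, 3) float64, ordered per convention
    cell_polygons: np.ndarray       # (24, 4, 2) pixel coords (x, y), tl,tr,br,bl
    orientation: str = "rot0"       # rotation applied to reach the logical frame

    def __post_init__(self):
        obs = np.asarray(self.observed_rgb, dtype=np.float64)
        if obs.shape != (N_SWATCHES, 3):
            raise FormatError(f"expected {N_SWATCHES} observed swatches, got {obs.shape}")
        object.__setattr__(self, "observed_rgb", obs)
        object.__setattr__(
            self, "cell_polygons", np.asarray(self.cell_polygons, dtype=np.float64)
        )


@dataclass(frozen=True)
class CorrectionModel:
    """Per-channel 9-term cubic regression coefficients.

    The basis is (R, G, B, R², G², B², R³, G³, B³) with no intercept,
    evaluated on unit-normalised channels (raw values divided by 255).
    ``coefficients[c]`` are the nine terms for output channel ``c``.
    """

    coefficients: np.ndarray        # (3, 9)
    r2_per_channel: np.ndarray      # (3,)
    input_scale: str = "unit"

    def __post_init__(self):
        coef = np.asarray(self.coefficients, dtype=np.float64)
        r2 = np.asarray(self.r2_per_channel, dtype=np.float64)
        if coef.shape != (3, 9):
            raise ValueError(f"expected 3×9 coefficients, got {coef.shape}")
        object.__setattr__(self, "coefficients", coef)
        object.__setattr__(self, "r2_per_channel", r2)

    @classmethod
    def identity(cls) -> "CorrectionModel":
        coef = np.zeros((3, 9))
        coef[0, 0] = coef[1, 1] = coef[2, 2] = 1.0
        return cls(coef, np.ones(3))


def load_reference_swatches(path: str | os.PathLike) -> SwatchSet:
    """Read a 24-row reference CSV with header ``R,G,B``."""
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip().upper() for h in header[:3]] != ["R", "G", "B"]:
            raise FormatError(f"{path}: expected header 'R,G,B'")
        for idx, row in enumerate(reader):
            if not row or not any(cell.strip() for cell in row):
                continue
            try:
                triple = tuple(float(cell) for cell in row[:3])
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric value in data row {idx}") from exc
            for v in triple:
                if not 0 <= v <= 255:
                    raise ValueError(
                        f"{path}: value {v:g} outside [0, 255] in data row {idx}"
                    )
            rows.append(triple)
    if len(rows) != N_SWATCHES:
        raise FormatError(f"{path}: expected {N_SWATCHES} data rows, found {len(rows)} rows")
    return SwatchSet(np.asarray(rows))


def default_reference_swatches() -> SwatchSet:
    """The packaged default 24-patch reference card."""
    return SwatchSet(np.asarray(_DEFAULT_REFERENCE, dtype=np.float64))


def write_reference_swatches(swatches: SwatchSet, path: str | os.PathLike) -> None:
    """Write a swatch set in the same CSV dialect ``load_reference_swatches`` reads."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["R", "G", "B"])
        for r, g, b in swatches.reference_rgb:
            writer.writerow([f"{r:.3f}", f"{g:.3f}", f"{b:.3f}"])


# ---------------------------------------------------------------------------
# Flat-field correction
# ---------------------------------------------------------------------------

def background_correct(image: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Divide an image by its normalised flat-field background.

    The background photograph (empty, evenly lit scene) is box-blurred with
    a 5×5 kernel and divided per channel by that channel's maximum so the
    field lies in (0, 1].  The experimental image is divided elementwise by
    the field, which flattens vignetting and lighting non-uniformity, then
    clipped to [0, 255] and rounded.
    """
    img = validate_image(image).astype(np.float64)
    bg = validate_image(background).astype(np.float64)
    if img.shape != bg.shape:
        raise ShapeError(
            f"image {img.shape[:2]} and background {bg.shape[:2]} dimensions differ"
        )
    blurred = ndimage.uniform_filter(bg, size=(5, 5, 1), mode="nearest")
    peak = blurred.reshape(-1, 3).max(axis=0)
    if np.any(peak <= 0):
        raise ValueError("degenerate background: a channel maximum is 0")
    field = blurred / peak
    field = np.maximum(field, 1.0 / 255.0)  # guard divisions by ~0
    return clip_round(img / field)


# ---------------------------------------------------------------------------
# Checker sampling
# ---------------------------------------------------------------------------

def _locate_card(gray: np.ndarray, dark_threshold: float) -> tuple[int, int, int, int]:
    """Bounding box (x0, y0, x1, y1; half-open) of the dark-bordered card."""
    dark = gray < dark_threshold
    if not dark.any():
        raise DetectionError(
            "no checker card found: no dark card border in the image; "
            "crop or rotate so the card is upright and visible"
        )
    labels, n = ndimage.label(dark)
    best = None
    for sl in ndimage.find_objects(labels):
        if sl is None:
            continue
        ys, xs = sl
        h, w = ys.stop - ys.start, xs.stop - xs.start
        if h < 8 or w < 8:
            continue
        aspect = w / h
        if not (0.45 < aspect < 2.2):  # near 6:4 or 4:6
            continue
        # the card border must trace the bounding-box perimeter; a rotated
        # card or a blob-shaped object leaves the perimeter mostly light
        comp = dark[sl]
        perim = np.concatenate([comp[0, :], comp[-1, :], comp[:, 0], comp[:, -1]])
        if perim.mean() < 0.8:
            continue
        area = h * w
        if best is None or area > best[0]:
            best = (area, xs.start, ys.start, xs.stop, ys.stop)
    if best is None:
        raise DetectionError(
            "no upright checker card found: crop and rotate the photograph so "
            "the card is square to the image axes, or pass corner coordinates"
        )
    return best[1:]


def _border_inset(card_dark: np.ndarray) -> int:
    """Thickness of the dark border along the left edge of the card mask.

    Dark swatches can sit next to the border, so the thickness is the
    minimum dark run over the central rows — at least one row meets a
    light swatch straight after the border.
    """
    h = card_dark.shape[0]
    central = card_dark[h // 10 : max(h - h // 10, h // 10 + 1)]
    runs = [int(np.argmin(row)) for row in central if not row.all()]
    return max(min(runs), 1) if runs else 1


def sample_checker(
    image: np.ndarray,
    hint: np.ndarray | list | None = None,
    reference: SwatchSet | None = None,
    dark_threshold: float = 90.0,
) -> SwatchGrid:
    """Locate the 4×6 checker card and sample its 24 swatch means.

    The card is found as the largest near-rectangular dark-bordered region
    (or taken from ``hint``, four (x, y) corner coordinates of an
    axis-aligned card).  Its interior is split into a 4×6 grid; the mean
    RGB of the central 50 % of each cell is sampled; cells are ordered by
    the documented column-major convention after resolving orientation by
    matching the anchor swatch against ``reference`` (the packaged default
    card when omitted).
    """
    img = validate_image(image).astype(np.float64)
    gray = img.mean(axis=2)
    if hint is not None:
        corners = np.asarray(hint, dtype=np.float64).reshape(4, 2)
        x0, y0 = np.floor(corners.min(axis=0)).astype(int)
        x1, y1 = np.ceil(corners.max(axis=0)).astype(int)
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, img.shape[1]), min(y1, img.shape[0])
        if x1 - x0 < 8 or y1 - y0 < 8:
            raise DetectionError("hint region is too small to hold a checker card")
    else:
        x0, y0, x1, y1 = _locate_card(gray, dark_threshold)

    card_dark = gray[y0:y1, x0:x1] < dark_threshold
    # self-calibrating border estimate: scan along the centre of the first
    # swatch row/column, where the only dark run is the card border
    left = _border_inset(card_dark)
    right = _border_inset(card_dark[:, ::-1])
    top = _border_inset(card_dark.T)
    bottom = _border_inset(card_dark.T[:, ::-1])
    ix0, ix1 = x0 + left, x1 - right
    iy0, iy1 = y0 + top, y1 - bottom
    if ix1 - ix0 < GRID_COLS or iy1 - iy0 < GRID_COLS:
        raise DetectionError("checker card interior is degenerate")

    landscape = (ix1 - ix0) >= (iy1 - iy0)
    nrows, ncols = (GRID_ROWS, GRID_COLS) if landscape else (GRID_COLS, GRID_ROWS)
    xs = np.linspace(ix0, ix1, ncols + 1)
    ys = np.linspace(iy0, iy1, nrows + 1)
    means = np.empty((nrows, ncols, 3))
    polys = np.empty((nrows, ncols, 4, 2))
    for r in range(nrows):
        for c in range(ncols):
            cx0, cx1, cy0, cy1 = xs[c], xs[c + 1], ys[r], ys[r + 1]
            qx, qy = (cx1 - cx0) / 4.0, (cy1 - cy0) / 4.0
            sx0, sx1 = int(round(cx0 + qx)), int(round(cx1 - qx))
            sy0, sy1 = int(round(cy0 + qy)), int(round(cy1 - qy))
            means[r, c] = img[sy0:sy1, sx0:sx1].reshape(-1, 3).mean(axis=0)
            polys[r, c] = [(cx0, cy0), (cx1, cy0), (cx1, cy1), (cx0, cy1)]

    ref = (reference or default_reference_swatches()).reference_rgb
    anchor_ref = ref[ANCHOR_INDEX]
    # candidate rotations mapping the image-frame grid onto the 4×6 logical
    # landscape frame; pick the one whose logical top-right cell best
    # matches the anchor swatch
    if landscape:
        candidates = {"rot0": (means, polys), "rot180": (means[::-1, ::-1], polys[::-1, ::-1])}
    else:
        candidates = {
            "rot90": (means.transpose(1, 0, 2)[:, ::-1], polys.transpose(1, 0, 2, 3)[:, ::-1]),
            "rot270": (means.transpose(1, 0, 2)[::-1, :], polys.transpose(1, 0, 2, 3)[::-1, :]),
        }
    best_name, best_dist = None, np.inf
    for name, (m, _) in candidates.items():
        dist = float(np.linalg.norm(m[0, GRID_COLS - 1] - anchor_ref))
        if dist < best_dist:
            best_name, best_dist = name, dist
    means_l, polys_l = candidates[best_name]
    order = means_l.transpose(1, 0, 2).reshape(N_SWATCHES, 3)          # column-major
    polys_o = polys_l.transpose(1, 0, 2, 3).reshape(N_SWATCHES, 4, 2)
    return SwatchGrid(order, polys_o, orientation=best_name)


# ---------------------------------------------------------------------------
# Polynomial colour correction
# ---------------------------------------------------------------------------

def _design_matrix(rgb: np.ndarray) -> np.ndarray:
    """9-term cubic basis (R, G, B, R², G², B², R³, G³, B³), no intercept.

    ``rgb`` is on the unit scale (raw / 255).
    """
    x = np.asarray(rgb, dtype=np.float64)
    return np.concatenate([x, x**2, x**3], axis=-1)


def fit_colour_correction(observed: SwatchGrid, reference: SwatchSet) -> CorrectionModel:
    """Ordinary-least-squares fit of the 9-term cubic correction per channel.

    Maps observed swatch means onto the reference sRGB values.  r² per
    channel is 1 − SSR/SST with SST about the reference-channel mean.
    """
    obs = observed.observed_rgb / 255.0
    ref = reference.reference_rgb / 255.0
    X = _design_matrix(obs)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError(
            "correction regression is not identifiable: observed swatch "
            "colours do not span the cubic basis (rank-deficient design matrix)"
        )
    coef, *_ = np.linalg.lstsq(X, ref, rcond=None)
    pred = X @ coef
    ssr = ((ref - pred) ** 2).sum(axis=0)
    sst = ((ref - ref.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(sst > 0, 1.0 - ssr / sst, 1.0)
    return CorrectionModel(coef.T, r2)


def correct_colours(rgb: np.ndarray, model: CorrectionModel) -> np.ndarray:
    """Apply the fitted transform to float RGB triples (no rounding)."""
    x = np.asarray(rgb, dtype=np.float64) / 255.0
    out = _design_matrix(x) @ model.coefficients.T
    return out * 255.0


def apply_colour_correction(image: np.ndarray, model: CorrectionModel) -> np.ndarray:
    """Transform every pixel by the correction model; clip and round to 8 bit."""
    img = validate_image(image)
    flat = correct_colours(img.reshape(-1, 3), model)
    return clip_round(flat).reshape(img.shape)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def delta_rgb(observed, reference) -> float:
    """Euclidean distance between two RGB triples (ΔRGB)."""
    a = np.asarray(observed, dtype=np.float64)
    b = np.asarray(reference, dtype=np.float64)
    return float(np.linalg.norm(a - b))


def mean_swatch_error(observed: SwatchGrid | np.ndarray, reference: SwatchSet) -> float:
    """Mean ΔRGB over the 24 swatches."""
    obs = observed.observed_rgb if isinstance(observed, SwatchGrid) else np.asarray(observed)
    diffs = obs.astype(np.float64) - reference.reference_rgb
    return float(np.linalg.norm(diffs, axis=1).mean())


def check_white_saturation(corrected_white_swatch) -> tuple[bool, tuple[float, float, float]]:
    """Flag a corrected white swatch whose channel hit the 255 ceiling."""
    triple = tuple(float(v) for v in corrected_white_swatch)
    if any(not 0 <= v <= 255 for v in triple):
        raise ValueError("white swatch values must lie in [0, 255]")
    return any(v >= 255.0 for v in triple), triple
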