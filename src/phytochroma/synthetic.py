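"""Deterministic synthetic scene rendering and dataset simulation.

Renders the capture layout the pipeline expects — a white lightbox
background holding a dark-bordered 4×6 checker card, a known-size
reference object and plant-like objects — together with a ground-truth
manifest, and distorts it with a parametric camera model (radial
vignette, channelwise cubic colour cast, additive Gaussian noise).
Rendering is hard-edged (no anti-aliasing) so mask pixel counts are exact
ground truth.  Every stochastic operation takes an explicit seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .correction import (
    ANCHOR_INDEX,
    GRID_COLS,
    GRID_ROWS,
    N_SWATCHES,
    SwatchSet,
    default_reference_swatches,
)
from .image import clip_round, validate_image

CARD_DARK = (30, 30, 30)
_BORDER_FRAC = 0.05   # card border as a fraction of the card's short side
_GAP_FRAC = 0.08      # swatch inset inside its grid cell, per side

# moderate warm colour cast, channelwise cubic on unit-scale channels;
# mild and monotone so a successful correction is achievable
DEFAULT_CAST = (
    (1.08, -0.12, 0.02),   # R
    (0.95, 0.03, 0.00),    # G
    (0.88, 0.05, 0.03),    # B
)


class SceneSpecError(ValueError):
    """The scene specification is geometrically invalid."""


@dataclass(frozen=True)
class ObjectSpec:
    """One rendered object: a hard-edged disc or axis-aligned rectangle."""

    shape: str                       # "disc" | "rect"
    position: tuple[int, int]        # disc centre / rect top-left (x, y)
    size: tuple[int, int]            # disc: (radius, radius); rect: (w, h)
    colour: tuple[int, int, int]
    label: str = ""


@dataclass(frozen=True)
class SceneSpec:
    """Layout of a synthetic capture: checker card, reference, objects."""

    width: int = 640
    height: int = 480
    card_origin: tuple[int, int] = (40, 30)
    card_width: int = 306
    swatches: SwatchSet = field(default_factory=default_reference_swatches)
    reference_object: ObjectSpec | None = None
    reference_physical_size: tuple[float, float] = (10.0, 10.0)  # e.g. mm
    objects: tuple[ObjectSpec, ...] = ()
    allow_overlap: bool = False
    seed: int = 0


@dataclass(frozen=True)
class ObjectTruth:
    """Ground truth for one rendered object."""

    label: str
    colour: tuple[int, int, int]
    pixel_count: int
    bbox: tuple[int, int, int, int]          # x0, y0, width, height
    physical_width: float
    physical_height: float
    physical_area: float


@dataclass(frozen=True)
class SceneTruth:
    """Manifest consistent with the rendered image by construction."""

    swatch_rgb: np.ndarray                    # (24, 3) in the ordering convention
    card_corners: np.ndarray                  # (4, 2) tl, tr, br, bl (x, y)
    reference: ObjectTruth | None
    objects: tuple[ObjectTruth, ...]
    scale_x: float
    scale_y: float
    distortion: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = asdict(self)
        payload["swatch_rgb"] = self.swatch_rgb.tolist()
        payload["card_corners"] = self.card_corners.tolist()
        return json.dumps(payload, indent=2)


def _paint_object(canvas: np.ndarray, spec: ObjectSpec) -> np.ndarray:
    """Draw a hard-edged object; returns its boolean mask."""
    h, w = canvas.shape[:2]
    if spec.shape == "disc":
        cx, cy = spec.position
        r = spec.size[0]
        if cx - r < 0 or cy - r < 0 or cx + r >= w or cy + r >= h:
            raise SceneSpecError(f"object {spec.label!r} extends outside the image")
        yy, xx = np.mgrid[0:h, 0:w]
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    elif spec.shape == "rect":
        x0, y0 = spec.position
        rw, rh = spec.size
        if x0 < 0 or y0 < 0 or x0 + rw > w or y0 + rh > h:
            raise SceneSpecError(f"object {spec.label!r} extends outside the image")
        mask = np.zeros((h, w), dtype=bool)
        mask[y0 : y0 + rh, x0 : x0 + rw] = True
    else:
        raise SceneSpecError(f"unknown object shape {spec.shape!r}")
    if not mask.any():
        raise SceneSpecError(f"object {spec.label!r} is empty")
    canvas[mask] = spec.colour
    return mask


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, SceneTruth]:
    """Render the scene and return the image plus its truth manifest.

    The checker card is drawn dark-bordered with the anchor swatch at the
    logical top-right; swatch cells sampled from the rendered image equal
    the specified colours exactly (hard edges, uniform fills).
    """
    img = np.full((spec.height, spec.width, 3), 255, dtype=np.uint8)

    # checker card: dark plate, 4×6 swatch grid, column-major convention
    card_w = spec.card_width
    border = max(2, round(_BORDER_FRAC * card_w))
    cell = (card_w - 2 * border) / GRID_COLS
    card_h = round(GRID_ROWS * cell + 2 * border)
    cx0, cy0 = spec.card_origin
    if cx0 < 0 or cy0 < 0 or cx0 + card_w > spec.width or cy0 + card_h > spec.height:
        raise SceneSpecError("checker card extends outside the image")
    img[cy0 : cy0 + card_h, cx0 : cx0 + card_w] = CARD_DARK
    ix0, iy0 = cx0 + border, cy0 + border
    ix1, iy1 = cx0 + card_w - border, cy0 + card_h - border
    xs = np.linspace(ix0, ix1, GRID_COLS + 1)
    ys = np.linspace(iy0, iy1, GRID_ROWS + 1)
    ref_swatches = spec.swatches.reference_rgb
    for c in range(GRID_COLS):
        for r in range(GRID_ROWS):
            colour = ref_swatches[c * GRID_ROWS + r]
            gx = (xs[c + 1] - xs[c]) * _GAP_FRAC
            gy = (ys[r + 1] - ys[r]) * _GAP_FRAC
            sx0, sx1 = int(round(xs[c] + gx)), int(round(xs[c + 1] - gx))
            sy0, sy1 = int(round(ys[r] + gy)), int(round(ys[r + 1] - gy))
            img[sy0:sy1, sx0:sx1] = clip_round(colour)

    card_corners = np.array(
        [(cx0, cy0), (cx0 + card_w, cy0), (cx0 + card_w, cy0 + card_h), (cx0, cy0 + card_h)],
        dtype=float,
    )

    painted = np.zeros((spec.height, spec.width), dtype=bool)
    painted[cy0 : cy0 + card_h, cx0 : cx0 + card_w] = True

    def place(obj: ObjectSpec) -> np.ndarray:
        mask = _paint_object(img, obj)
        if not spec.allow_overlap and (mask & painted).any():
            raise SceneSpecError(f"object {obj.label!r} overlaps existing geometry")
        painted[:] |= mask
        return mask

    scale_x = scale_y = float("nan")
    ref_truth = None
    if spec.reference_object is not None:
        mask = place(spec.reference_object)
        ys_, xs_ = np.nonzero(mask)
        bw = int(xs_.max() - xs_.min() + 1)
        bh = int(ys_.max() - ys_.min() + 1)
        scale_x = spec.reference_physical_size[0] / bw
        scale_y = spec.reference_physical_size[1] / bh
        ref_truth = ObjectTruth(
            label=spec.reference_object.label or "reference",
            colour=spec.reference_object.colour,
            pixel_count=int(mask.sum()),
            bbox=(int(xs_.min()), int(ys_.min()), bw, bh),
            physical_width=spec.reference_physical_size[0],
            physical_height=spec.reference_physical_size[1],
            physical_area=float(mask.sum()) * scale_x * scale_y,
        )

    obj_truths = []
    for obj in spec.objects:
        mask = place(obj)
        ys_, xs_ = np.nonzero(mask)
        bw = int(xs_.max() - xs_.min() + 1)
        bh = int(ys_.max() - ys_.min() + 1)
        obj_truths.append(
            ObjectTruth(
                label=obj.label,
                colour=obj.colour,
                pixel_count=int(mask.sum()),
                bbox=(int(xs_.min()), int(ys_.min()), bw, bh),
                physical_width=bw * scale_x,
                physical_height=bh * scale_y,
                physical_area=float(mask.sum()) * scale_x * scale_y,
            )
        )

    truth = SceneTruth(
        swatch_rgb=np.asarray(ref_swatches, dtype=float),
        card_corners=card_corners,
        reference=ref_truth,
        objects=tuple(obj_truths),
        scale_x=scale_x,
        scale_y=scale_y,
    )
    return img, truth


def default_scene(seed: int = 0) -> SceneSpec:
    """A standard test capture: card, 10 mm square reference, three discs."""
    return SceneSpec(
        reference_object=ObjectSpec("rect", (60, 330), (60, 60), (120, 120, 125), "ref"),
        reference_physical_size=(10.0, 10.0),
        objects=(
            ObjectSpec("disc", (260, 380), (45, 45), (186, 40, 45), "tomato_1"),
            ObjectSpec("disc", (400, 380), (45, 45), (70, 140, 60), "leaf_1"),
            ObjectSpec("disc", (540, 380), (45, 45), (220, 130, 40), "tomato_2"),
        ),
        seed=seed,
    )


def vignette_field(height: int, width: int, strength: float) -> np.ndarray:
    """Radial multiplicative field: 1 at centre, 1−strength at the farthest corner."""
    if not 0 <= strength < 1:
        raise ValueError("vignette strength must lie in [0, 1)")
    yy, xx = np.mgrid[0:height, 0:width].astype(np.float64)
    cx, cy = (width - 1) / 2.0, (height - 1) / 2.0
    r2 = (xx - cx) ** 2 + (yy - cy) ** 2
    rmax2 = cx**2 + cy**2
    return 1.0 - strength * (r2 / rmax2 if rmax2 > 0 else 0.0)


def apply_cast(rgb: np.ndarray, cast) -> np.ndarray:
    """Channelwise cubic cast on unit-scale channels (float output, 0–255)."""
    x = np.asarray(rgb, dtype=np.float64) / 255.0
    coefs = np.asarray(cast, dtype=np.float64)  # (3, 3): linear, quadratic, cubic
    out = coefs[:, 0] * x + coefs[:, 1] * x**2 + coefs[:, 2] * x**3
    return out * 255.0


def apply_camera_distortion(
    image: np.ndarray,
    cast=None,
    vignette_strength: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Distort a rendered scene: vignette, then colour cast, then noise.

    The vignette multiplies each pixel by a radial field, the cast applies
    a per-channel cubic on unit-scale channels, and Gaussian noise of the
    given SD (8-bit units) is added with the given seed before clipping.
    """
    if noise_sd < 0:
        raise ValueError("noise SD must be non-negative")
    img = validate_image(image).astype(np.float64)
    if vignette_strength:
        img = img * vignette_field(img.shape[0], img.shape[1], vignette_strength)[..., None]
    if cast is not None:
        img = apply_cast(img, cast)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return clip_round(img)


def simulate_pigment_dataset(model, n: int, x_range, noise_sd: float, seed: int):
    """Draw a calibration dataset from a fitted pigment model.

    Predictors are uniform over ``x_range`` (a (lo, hi) pair for the
    lycopene model's a*/b*, or three per-channel pairs for the chlorophyll
    model's RGB); responses are model predictions plus Gaussian noise.
    Returns rows in the training-CSV dialect as a list of dicts.
    """
    from .pigment_models import ChlorophyllModel, LycopeneModel

    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    if isinstance(model, LycopeneModel):
        lo, hi = x_range
        x = rng.uniform(lo, hi, size=n)
        y = model.beta1 * np.exp(model.beta2 * x) + model.beta3
        y = y + rng.normal(0.0, noise_sd, size=n)
        for i in range(n):
            rows.append({"id": f"s{i + 1:03d}", "a_over_b": float(x[i]), "lycopene": float(y[i])})
    elif isinstance(model, ChlorophyllModel):
        ranges = np.asarray(x_range, dtype=np.float64).reshape(3, 2)
        rgb = np.column_stack([rng.uniform(lo, hi, size=n) for lo, hi in ranges])
        ct = np.exp(rgb @ np.array([model.beta1, model.beta2, model.beta3]) + model.beta4)
        ct = ct + rng.normal(0.0, noise_sd, size=n)
        for i in range(n):
            rows.append(
                {
                    "id": f"s{i + 1:03d}",
                    "R": float(rgb[i, 0]), "G": float(rgb[i, 1]), "B": float(rgb[i, 2]),
                    "chlorophyll": float(ct[i]),
                }
            )
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    return rows
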