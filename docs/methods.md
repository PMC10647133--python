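# Methods

This note documents the models, conventions and numerical choices behind
`phytochroma`, and what the synthetic test scenes do and do not show about
real photographs.

## Flat-field (background) correction

A photograph of the empty, evenly lit scene is box-blurred with a 5×5
arithmetic-mean kernel and divided, per channel, by that channel's maximum,
yielding a multiplicative illumination field in (0, 1]. The experimental
image is divided elementwise by the field, then clipped to [0, 255] and
rounded. Choices:

* **Box blur, not Gaussian** — the minimal reading of "5×5"; the blur only
  suppresses sensor noise in the flat-field estimate, so the kernel shape
  is immaterial at this scale.
* **Per-channel normalisation** preserves the white balance of the flat
  field; a global maximum would tint the corrected image.
* Field values are floored at 1/255 before division so dead-black
  background pixels cannot produce unbounded quotients.
* Rounding is half-up after clipping, here and everywhere an 8-bit image
  is produced.

## Checker detection and swatch sampling

The 24-patch card is modelled as an axis-aligned, dark-bordered 4×6 grid.
Detection finds connected dark regions (mean channel value below 90 by
default), keeps those whose bounding-box aspect ratio is near 6:4 or 4:6
**and** whose bounding-box perimeter is predominantly dark — a rotated
card or a dark blob fails the perimeter test — and takes the largest.
A four-corner hint bypasses detection entirely (the supported remedy for
tilted cards is to crop/rotate the photograph or pass corners). The border
thickness is estimated per side as the minimum dark run over the central
rows, which is robust to dark swatches abutting the border. The interior
is split into a uniform 4×6 grid and the mean RGB of the central 50 % of
each cell is sampled, keeping clear of cell borders and printing gaps.

**Ordering convention.** Swatches are ordered column-major in the card's
logical landscape frame: index `i` is row `i % 4`, column `i // 4`
(rows top-to-bottom, columns left-to-right). The *anchor* swatch — the
light-blue patch on the packaged default card — sits at the logical
top-right (index 20). Orientation (0°/90°/180°/270°) is resolved by
sampling the grid under each admissible rotation and keeping the one whose
logical top-right cell is nearest the reference anchor colour; the match
is relative across at most four candidates, so it tolerates strong colour
casts. Reference CSVs (header `R,G,B`, 24 rows) must follow the same
convention.

## Polynomial colour correction

Each output channel is an ordinary-least-squares fit of the 9-term basis
(R, G, B, R², G², B², R³, G³, B³) — no intercept — mapping the 24 observed
swatch means onto the reference sRGB values. Channels are divided by 255
before the powers are formed: this conditions the cubic design matrix, and
the coefficient scale (recorded in `CorrectionModel.input_scale`) has no
effect on predictions. Per-channel goodness of fit is r² = 1 − SSR/SST
with SST about the reference-channel mean; a fit is deemed successful when
all three exceed 0.95. Because the basis contains the identity map, the
fitted transform can never increase the summed squared swatch error; the
mean ΔRGB (a mean of Euclidean norms, not of squares) decreases in every
scenario we generate, though it is not mathematically guaranteed to for
adversarial inputs. The corrected white swatch is checked for channels at
the 255 ceiling, which would indicate clipped highlights.

Note the fitted transform approximates the *inverse* of the camera's cast;
even when the cast itself is channelwise-cubic the inverse is only
approximately in the basis span, so residuals are small but nonzero, and a
spatially varying distortion (vignette) cannot be removed by this global
map — that is the flat-field step's job, which is why the pipeline orders
background correction before colour correction.

## Segmentation and measurement

Background pixels are those with **all three** channels ≥ threshold
(default 150), i.e. near-white; the foreground mask is cleaned by
morphological opening then closing with a 5×5 elliptical structuring
element (one iteration each) and components under `min_object_area`
(default 500 px) are dropped. Object separation runs Canny edge detection
(defaults 50/150 on the 0–255 scale, σ = 1), closes the edge map, fills
external contours, and intersects each filled component with the non-white
pixels — the closing dilates contours by roughly one pixel, and the
intersection restores the exact extent since the background is pure white
by contract. Touching objects merge into a single detection (a documented
limitation; the capture protocol separates objects). Objects are sorted
left-to-right by bounding-box x0, ties by y0, giving a deterministic total
order; the left-most object is by convention the known-size reference.

Width and height are axis-aligned mask extents scaled by per-axis
calibration factors (physical size of the reference divided by its pixel
extent, kept separate per axis rather than averaged); area is the mask
pixel count times the pixel footprint. Mean colour is averaged over mask
pixels only, in sRGB-encoded values (no linear-light averaging — the
calibration models are trained on the same convention, so consistency
matters more than photometric linearity).

## Colour spaces

* **YUV**: BT.601 full-range matrix with +128 chroma offset, so white is
  (255, 128, 128) and achromatic inputs have U = V = 128. The dialect is
  fixed because different YUV variants differ by several units.
* **CIELAB**: sRGB gamma decode (IEC 61966-2-1), linear RGB → XYZ with the
  D65 matrix, CIELAB forward function with the standard cube-root /
  linear-piecewise split at (6/29)³, 2° observer. The transform is
  implemented in-package (a dozen lines) and is cross-checked in the test
  suite against scikit-image's independent implementation to < 0.05 on a
  1,000-point lattice.

## Pigment models

`lycopene_from_absorbance` recomputes its coefficient from the physical
constants (ε = 17.2 × 10⁴ M⁻¹cm⁻¹ in hexane, M = 536.9 g/mol, 10 ml
hexane, ml→l, g→mg and g→kg conversions) and asserts it equals 31.2 at
three significant figures. Chlorophyll a/b come from the standard
two-wavelength equations for 80 % acetone extracts; total chlorophyll is
their sum by construction.

**Lycopene calibration** `L = β₁·exp(β₂·x) + β₃`, x = a\*/b\*, is fitted
by Levenberg–Marquardt nonlinear least squares (relative tolerance 1e-10,
10,000 evaluation cap). Initialisation: β₃ ← min(y); β₂ and β₁ from a
log-linear regression of (y − β₃ + ε) on x with ε = 1e-9 guarding the
point where y = β₃. At least four points are required; a constant
response is rejected as non-identifiable (β₂ is unconstrained).

**Chlorophyll calibration** `Ct = exp(β₁R + β₂G + β₃B + β₄)` is exactly
linear in log space, so it is fitted by OLS of ln(Ct) on (R, G, B, 1)
rather than direct NLS. This is a deliberate design choice: it is exact on
noiseless data and globally optimal, at the cost of implying a
multiplicative (log-normal) noise model rather than additive noise on Ct.
Diagnostics (r², RMSE) are reported on the original Ct scale. All Ct must
be positive; a constant colour channel makes the design rank-deficient.

Both fitted models record their training range and flag predictions
outside it as **extrapolations**: exponential calibrations with strong
curvature are only trustworthy inside the colour range they were trained
on, so calibration sets should span the full expected colour range.

`validate_model` reports RMSE, standardised residuals, and two r²
flavours — the predicted-on-observed regression r² and an identity-line
r² (1 − Σ(pred−obs)²/Σ(obs−mean)²) — plus the F statistic, degrees of
freedom (1, n−2) and p value of the regression slope, since conventions
differ on which r² a validation plot reports.

## Synthetic scenes

The generator renders the capture layout the protocol prescribes: white
background, dark-bordered 4×6 checker with the anchor swatch at the
logical top-right, a known-size reference as the left-most object, and
non-touching plant-like objects. Rendering is hard-edged (no
anti-aliasing) so ground-truth areas are exact pixel counts — slightly
unrealistic, but it makes exact assertions possible. The camera model
applies, in fixed order, (1) a radial quadratic vignette (1 at centre,
1 − strength at the farthest corner), (2) a channelwise cubic colour cast
on unit-scale channels, (3) additive Gaussian noise, then clips to 8 bits.
The default study condition used across the tests is the moderate warm
cast `DEFAULT_CAST`, vignette strength 0.2 and noise SD 2 — a distortion
comparable in ΔRGB magnitude to consumer-camera colour error under
non-ideal lighting (≈ 19 units before correction on the default card).
Pigment datasets are simulated by drawing predictors uniformly over a
stated range and adding Gaussian noise to the model response; the
parameter-recovery study uses n = 20 points on a fixed evenly spaced
a\*/b\* grid over [−0.5, 1.2] with noise SD equal to 5 % of the response
range, replicating the noise 200 times — replicating the design too would
confound estimator bias with design-leverage skew.

What the synthetic scenes do **not** emulate: anti-aliased and textured
object boundaries, shadows, specular highlights, JPEG compression,
spatially varying casts beyond the vignette, and perspective distortion of
the card. Passing tests therefore demonstrate the algorithmic correctness
of the pipeline, not its robustness to every real capture artefact; the
capture protocol (lightbox, centred objects, shadow-free lighting) is what
controls those artefacts in practice.

## Problem sizes and determinism

Test scenes are 640×480 with a 306-px card, which keeps every swatch cell
above 500 samples after central-50 % sampling; the error-reduction study
uses 20 seeded scenes and the recovery study 200 noise replicates. All
stochastic steps take explicit seeds and the pipeline contains no other
randomness, so every CSV and statistic is bit-reproducible.

## Known limitations

* Checker detection assumes an upright (axis-aligned) card; tilted cards
  need the corner hint or a pre-rotated image. Perspective distortion is
  out of scope.
* Touching objects are not split (no watershed); ΔRGB is a device-space
  error measure, not a perceptual one (no ΔE).
* Calibration model parameters are camera- and lighting-specific and must
  be refitted per setup; predictions outside the training range are
  flagged rather than trusted.
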