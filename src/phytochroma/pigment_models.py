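"""Spectrophotometric pigment formulas and colour-to-pigment calibration.

Two wet-lab formulas convert UV/vis absorbances into pigment content:
lycopene from the absorbance of a hexane extract at 503 nm, and
chlorophyll a/b from the absorbances of an 80 % acetone extract at 663 and
646 nm.  Two exponential calibration models then link image colour to
pigment content:

* lycopene:    L = β₁ · exp(β₂ · a*/b*) + β₃, with a*/b* from CIELAB —
  the ratio grows as fruit ripens from green to red;
* chlorophyll: Ct = exp(β₁R + β₂G + β₃B + β₄) on mean object RGB.

The chlorophyll model is exactly linear in log space and is fitted by
ordinary least squares on ln(Ct); the lycopene model is fitted by
Levenberg–Marquardt nonlinear least squares.  Fitted models record their
training range, and predictions outside it are flagged as extrapolations —
exponential calibrations with strong curvature extrapolate poorly.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy import optimize, stats


@dataclass(frozen=True)
class PigmentConstants:
    """Physical constants of the lycopene extraction formula."""

    lycopene_molar_extinction: float = 17.2e4   # M^-1 cm^-1, in hexane
    lycopene_molar_mass: float = 536.9          # g/mol
    hexane_volume_ml: float = 10.0
    litre_per_ml: float = 1e-3
    mg_per_g: float = 1e3
    g_per_kg: float = 1e3

    def lycopene_coefficient(self) -> float:
        """mg lycopene per kg tissue per unit absorbance per gram of paste.

        (A / ε) mol/l × M g/mol → g/l; × 1 l/10³ ml → g/ml; × 10³ mg/g →
        mg/ml; × 10 ml of hexane → mg; per g tissue × 10³ g/kg → mg/kg.
        """
        return (
            self.lycopene_molar_mass
            / self.lycopene_molar_extinction
            * self.litre_per_ml
            * self.mg_per_g
            * self.hexane_volume_ml
            * self.g_per_kg
        )


CONSTANTS = PigmentConstants()
# coefficient printed in the extraction formula; the recomputation from the
# physical constants must agree with it to 3 significant figures
LYCOPENE_COEFFICIENT = 31.2
assert math.isclose(
    float(f"{CONSTANTS.lycopene_coefficient():.3g}"), LYCOPENE_COEFFICIENT
)

CHL_A_663, CHL_A_646 = 12.21, 2.81
CHL_B_646, CHL_B_663 = 20.13, 5.03


def lycopene_from_absorbance(a503: float, tissue_mass: float) -> float:
    """Lycopene in mg per kg wet tissue from hexane-extract absorbance.

    ``tissue_mass`` is the grams of tissue paste extracted into 10 ml of
    hexane; the coefficient is recomputed from the physical constants.
    """
    if a503 < 0:
        raise ValueError("absorbance must be non-negative")
    if tissue_mass <= 0:
        raise ValueError("tissue mass must be positive")
    return a503 * CONSTANTS.lycopene_coefficient() / tissue_mass


def chlorophyll_from_absorbance(a646: float, a663: float) -> tuple[float, float, float]:
    """Chlorophyll a, b and total (µg/ml) from 80 % acetone extract absorbances."""
    if a646 < 0 or a663 < 0:
        raise ValueError("absorbances must be non-negative")
    ca = CHL_A_663 * a663 - CHL_A_646 * a646
    cb = CHL_B_646 * a646 - CHL_B_663 * a663
    return ca, cb, ca + cb


# ---------------------------------------------------------------------------
# Calibration models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LycopeneModel:
    """L = β₁ exp(β₂ x) + β₃ with x = a*/b*."""

    beta1: float
    beta2: float
    beta3: float
    r2: float = float("nan")
    rmse: float = float("nan")
    x_range: tuple[float, float] = (-math.inf, math.inf)

    def predict(self, x: float) -> tuple[float, bool]:
        """Predicted lycopene (mg/kg) and an extrapolation flag."""
        value = self.beta1 * math.exp(self.beta2 * x) + self.beta3
        lo, hi = self.x_range
        return value, not (lo <= x <= hi)


@dataclass(frozen=True)
class ChlorophyllModel:
    """Ct = exp(β₁R + β₂G + β₃B + β₄) on mean object RGB."""

    beta1: float
    beta2: float
    beta3: float
    beta4: float
    r2: float = float("nan")
    rmse: float = float("nan")
    rgb_range: tuple[tuple[float, float], ...] = (
        (-math.inf, math.inf),
    ) * 3

    def predict(self, rgb) -> tuple[float, bool]:
        """Predicted total chlorophyll and an extrapolation flag."""
        r, g, b = (float(v) for v in rgb)
        value = math.exp(self.beta1 * r + self.beta2 * g + self.beta3 * b + self.beta4)
        inside = all(lo <= v <= hi for v, (lo, hi) in zip((r, g, b), self.rgb_range))
        return value, not inside


class NonIdentifiableError(ValueError):
    """The calibration data cannot constrain the model parameters."""


def _fit_stats(y: np.ndarray, pred: np.ndarray) -> tuple[float, float]:
    ssr = float(((y - pred) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ssr / sst if sst > 0 else 1.0
    return r2, math.sqrt(ssr / len(y))


def fit_lycopene_model(x, y, max_iter: int = 10_000, xtol: float = 1e-10) -> LycopeneModel:
    """Levenberg–Marquardt fit of the exponential lycopene model.

    Initialisation: β₃ from min(y), β₂ from a log-linear regression of
    (y − β₃ + ε) on x, β₁ from that regression's intercept.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if len(x) < 4:
        raise ValueError(f"need at least 4 points to fit 3 parameters, got {len(x)}")
    if not np.all(np.isfinite(x)):
        raise ValueError("predictor values must be finite (b* must be nonzero upstream)")
    if np.ptp(y) == 0:
        raise NonIdentifiableError("constant response: β₂ is unconstrained")

    eps = 1e-9
    b3_0 = float(y.min())
    shifted = np.log(y - b3_0 + eps)
    slope, intercept, *_ = stats.linregress(x, shifted)
    p0 = (math.exp(intercept), slope, b3_0)

    def model(xv, b1, b2, b3):
        return b1 * np.exp(b2 * xv) + b3

    try:
        popt, _ = optimize.curve_fit(
            model, x, y, p0=p0, method="lm", maxfev=max_iter, xtol=xtol
        )
    except RuntimeError as exc:
        resid = float(np.sqrt(np.mean((model(x, *p0) - y) ** 2)))
        raise RuntimeError(
            f"lycopene fit did not converge within {max_iter} evaluations "
            f"(residual RMSE at last start {resid:.4g})"
        ) from exc
    pred = model(x, *popt)
    r2, rmse = _fit_stats(y, pred)
    return LycopeneModel(
        beta1=float(popt[0]), beta2=float(popt[1]), beta3=float(popt[2]),
        r2=r2, rmse=rmse, x_range=(float(x.min()), float(x.max())),
    )


def predict_lycopene(model: LycopeneModel, x: float) -> tuple[float, bool]:
    """Convenience wrapper around ``LycopeneModel.predict``."""
    if not math.isfinite(x):
        raise ValueError("a*/b* predictor must be finite")
    return model.predict(x)


def fit_chlorophyll_model(rgb, ct) -> ChlorophyllModel:
    """Exact log-linearised OLS fit of the exponential chlorophyll model.

    ln(Ct) is linear in (R, G, B, 1), so ordinary least squares on the log
    scale recovers the parameters exactly on noiseless data.  Diagnostics
    (r², RMSE) are computed on the original Ct scale.
    """
    rgb = np.asarray(rgb, dtype=np.float64)
    ct = np.asarray(ct, dtype=np.float64)
    if rgb.ndim != 2 or rgb.shape[1] != 3 or len(rgb) != len(ct):
        raise ValueError("rgb must be n×3 and ct length n")
    if len(ct) < 5:
        raise ValueError(f"need at least 5 points to fit 4 parameters, got {len(ct)}")
    if np.any(ct <= 0):
        raise ValueError("all chlorophyll values must be positive (log-linear fit)")
    X = np.column_stack([rgb, np.ones(len(ct))])
    if np.linalg.matrix_rank(X) < 4:
        raise NonIdentifiableError("collinear predictors: design matrix is rank deficient")
    coef, *_ = np.linalg.lstsq(X, np.log(ct), rcond=None)
    pred = np.exp(X @ coef)
    r2, rmse = _fit_stats(ct, pred)
    return ChlorophyllModel(
        beta1=float(coef[0]), beta2=float(coef[1]), beta3=float(coef[2]),
        beta4=float(coef[3]), r2=r2, rmse=rmse,
        rgb_range=tuple(
            (float(rgb[:, i].min()), float(rgb[:, i].max())) for i in range(3)
        ),
    )


def predict_chlorophyll(model: ChlorophyllModel, rgb) -> tuple[float, bool]:
    """Convenience wrapper around ``ChlorophyllModel.predict``."""
    return model.predict(rgb)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationReport:
    """Agreement statistics between model predictions and observations.

    ``r2`` is the coefficient of determination of the predicted-on-observed
    regression; ``r2_identity`` scores deviation from the y = x line
    (1 − Σ(pred−obs)² / Σ(obs−mean)²).  ``anova_F``/``anova_p`` come from
    the same regression's slope test, with ``anova_df`` = (1, n − 2).
    """

    r2: float
    r2_identity: float
    rmse: float
    standardised_residuals: np.ndarray
    anova_F: float
    anova_df: tuple[int, int]
    anova_p: float


def validate_model(predicted, observed) -> ValidationReport:
    """Compare predictions with observations (RMSE, r², ANOVA of the regression)."""
    pred = np.asarray(predicted, dtype=np.float64)
    obs = np.asarray(observed, dtype=np.float64)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("predicted and observed must be equal-length 1-D sequences")
    n = len(pred)
    if n < 3:
        raise ValueError("need at least 3 points to validate")
    sst = float(((obs - obs.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("observed values have zero variance")
    resid = pred - obs
    rmse = float(np.sqrt((resid**2).mean()))
    r2_identity = 1.0 - float((resid**2).sum()) / sst
    lr = stats.linregress(obs, pred)
    r2 = float(lr.rvalue**2)
    F = float(lr.slope / lr.stderr) ** 2 if lr.stderr > 0 else math.inf
    sd = resid.std(ddof=1)
    std_resid = resid / sd if sd > 0 else np.zeros_like(resid)
    return ValidationReport(
        r2=r2, r2_identity=r2_identity, rmse=rmse,
        standardised_residuals=std_resid,
        anova_F=F, anova_df=(1, n - 2), anova_p=float(lr.pvalue),
    )


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def save_model(model: LycopeneModel | ChlorophyllModel, path: str | os.PathLike) -> None:
    """Serialise a fitted model (parameters, diagnostics, range) to JSON."""
    tag = "lycopene" if isinstance(model, LycopeneModel) else "chlorophyll"
    with open(path, "w") as fh:
        json.dump({"model": tag, **asdict(model)}, fh, indent=2)


def load_model(path: str | os.PathLike) -> LycopeneModel | ChlorophyllModel:
    """Load a model serialised by :func:`save_model`."""
    with open(path) as fh:
        payload = json.load(fh)
    tag = payload.pop("model")
    if tag == "lycopene":
        payload["x_range"] = tuple(payload["x_range"])
        return LycopeneModel(**payload)
    if tag == "chlorophyll":
        payload["rgb_range"] = tuple(tuple(r) for r in payload["rgb_range"])
        return ChlorophyllModel(**payload)
    raise ValueError(f"unknown model tag {tag!r}")
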