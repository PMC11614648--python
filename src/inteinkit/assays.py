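"""Quantitative models for the validation assays.

Three small model families cover the measurements used to validate
trans-splicing assembly:

* a four-parameter logistic (4PL) dose-response curve for transduction
  efficiency, ``y(x) = d + (a - d) / (1 + (x/c)^b)`` with low-dose asymptote
  ``a``, high-dose asymptote ``d``, inflection dose ``c`` and Hill slope
  ``b``;
* a qPCR standard curve (ordinary least squares of Ct on log10 copies) with
  amplification efficiency ``E = 10^(-1/slope) - 1`` and the usual run
  acceptance criteria (linearity, efficiency window, replicate Ct scatter);
* densitometry normalization against a housekeeping protein and rounded
  fold-change reporting.

The 4PL fit works on log10 dose internally for conditioning; reported
parameters are on the natural dose scale and R^2 is computed on the response
scale against the raw points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats


class AssayError(ValueError):
    pass


@dataclass
class DoseResponse4PL:
    """A fitted 4PL model. ``a``/``d`` are the dose->0 / dose->inf asymptotes."""

    a: float
    d: float
    c: float
    b: float
    r2: float
    data: list = field(default_factory=list)  # (dose, response)


def _4pl(logx: np.ndarray, a: float, d: float, logc: float, b: float) -> np.ndarray:
    return d + (a - d) / (1.0 + 10.0 ** (b * (logx - logc)))


def fit_4pl(doses: Sequence[float], responses: Sequence[float]) -> DoseResponse4PL:
    """Nonlinear least-squares fit of the 4PL model.

    Requires at least 4 points with strictly positive doses.  Initialization:
    a = min response, d = max response, c = geometric mean dose, b = 1.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size != y.size:
        raise AssayError("doses and responses differ in length")
    if x.size < 4:
        raise AssayError(f"need at least 4 points to fit 4 parameters, got {x.size}")
    if np.any(x <= 0):
        raise AssayError("doses must be strictly positive")
    if np.allclose(y, y[0]):
        raise AssayError("responses are constant; dose-response model is degenerate")
    logx = np.log10(x)
    p0 = (float(y.min()), float(y.max()), float(logx.mean()), 1.0)
    popt, _ = optimize.curve_fit(_4pl, logx, y, p0=p0, maxfev=20000)
    a, d, logc, b = (float(v) for v in popt)
    resid = y - _4pl(logx, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return DoseResponse4PL(a=a, d=d, c=10.0**logc, b=b, r2=r2, data=list(zip(x.tolist(), y.tolist())))


def predict_4pl(fit: DoseResponse4PL, dose) -> float:
    """Model response at ``dose`` (scalar or array)."""
    dose = np.asarray(dose, dtype=float)
    if np.any(dose <= 0):
        raise AssayError("dose must be strictly positive")
    out = _4pl(np.log10(dose), fit.a, fit.d, np.log10(fit.c), fit.b)
    return float(out) if out.ndim == 0 else out


def inverse_4pl(fit: DoseResponse4PL, response: float) -> float:
    """Dose producing ``response``: x = c * ((a - d)/(y - d) - 1)^(1/b).

    ``response`` must lie strictly between the two asymptotes.
    """
    lo, hi = sorted((fit.a, fit.d))
    if not lo < response < hi:
        raise AssayError(f"response {response} outside the open asymptote interval ({lo}, {hi})")
    ratio = (fit.a - fit.d) / (response - fit.d) - 1.0
    return float(fit.c * ratio ** (1.0 / fit.b))


@dataclass
class StandardCurve:
    """A fitted qPCR standard curve: Ct = intercept + slope * log10(copies)."""

    slope: float
    intercept: float
    r2: float
    efficiency: float  # fraction: 1.0 == 100% (perfect doubling)
    ct_sd_max: float
    n_levels: int


def fit_standard_curve(log10_copies: Sequence[float], ct_replicates) -> StandardCurve:
    """OLS of mean Ct on log10 input copies over a dilution series.

    ``ct_replicates`` is one sequence of Ct values per dilution level;
    replicates are averaged per level before regression and the per-level Ct
    standard deviation is kept for the acceptance check.  Requires >= 3
    levels with varying copy number and non-constant Ct.
    """
    x = np.asarray(log10_copies, dtype=float)
    if x.size < 3:
        raise AssayError(f"need at least 3 dilution levels, got {x.size}")
    if np.allclose(x, x[0]):
        raise AssayError("log10 copies are constant; no dilution series")
    levels = [np.asarray(r, dtype=float).ravel() for r in ct_replicates]
    if len(levels) != x.size:
        raise AssayError("one Ct replicate group per dilution level is required")
    means = np.array([lv.mean() for lv in levels])
    sds = np.array([lv.std(ddof=1) if lv.size > 1 else 0.0 for lv in levels])
    if np.allclose(means, means[0]):
        raise AssayError("Ct values are constant across dilutions; no amplification signal")
    res = stats.linregress(x, means)
    slope = float(res.slope)
    if slope == 0:
        raise AssayError("zero slope; cannot define amplification efficiency")
    efficiency = 10.0 ** (-1.0 / slope) - 1.0
    return StandardCurve(
        slope=slope,
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        efficiency=float(efficiency),
        ct_sd_max=float(sds.max()),
        n_levels=int(x.size),
    )


#: Run-acceptance bounds: linearity, efficiency window (inclusive), replicate scatter.
ACCEPTANCE_R2_MIN = 0.9
ACCEPTANCE_EFFICIENCY = (0.85, 1.00)
ACCEPTANCE_CT_SD_MAX = 0.2


def check_curve_acceptance(curve: StandardCurve):
    """Apply the standard-curve acceptance criteria; returns (ok, failed reasons).

    The curve passes when r2 > 0.9, efficiency lies in [85%, 100%]
    (inclusive), and no dilution level has a replicate Ct SD above 0.2.
    """
    reasons = []
    if not curve.r2 > ACCEPTANCE_R2_MIN:
        reasons.append("linearity")
    lo, hi = ACCEPTANCE_EFFICIENCY
    if not lo <= curve.efficiency <= hi:
        reasons.append("efficiency")
    if not curve.ct_sd_max <= ACCEPTANCE_CT_SD_MAX:
        reasons.append("ct_sd")
    return (not reasons, reasons)


def quantify_titer(
    ct: float,
    curve: StandardCurve,
    dilution_factor: float = 1.0,
    volume_scale: float = 1.0,
) -> float:
    """Absolute quantification: copies = 10^((ct - intercept)/slope) x factors.

    ``dilution_factor`` undoes sample dilution; ``volume_scale`` converts the
    per-reaction copy number to the reporting volume (e.g. copies/mL).  A
    warning is attached when the curve fails its acceptance criteria.
    """
    ok, reasons = check_curve_acceptance(curve)
    if not ok:
        warnings.warn(f"standard curve failed acceptance ({', '.join(reasons)}); "
                      "titer is reported but unreliable")
    copies = 10.0 ** ((ct - curve.intercept) / curve.slope)
    return float(copies * dilution_factor * volume_scale)


@dataclass
class DensitometryRecord:
    """One band quantification normalized to a housekeeping reference band."""

    target_intensity: float
    reference_intensity: float

    def __post_init__(self) -> None:
        if self.target_intensity < 0 or self.reference_intensity < 0:
            raise AssayError("intensities must be non-negative")

    @property
    def normalized(self) -> float:
        return densitometry_normalize(self.target_intensity, self.reference_intensity)


def densitometry_normalize(target: float, reference: float) -> float:
    """Ratio of target-band to housekeeping-band integrated intensity."""
    if reference <= 0:
        raise AssayError("reference intensity must be positive")
    if target < 0:
        raise AssayError("target intensity must be non-negative")
    return target / reference


def fold_change(value_a: float, value_b: float, decimals: int = 1) -> float:
    """value_a / value_b rounded to ``decimals`` (1 decimal is the reporting norm)."""
    if value_b <= 0:
        raise AssayError("denominator must be positive")
    return round(value_a / value_b, decimals)
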