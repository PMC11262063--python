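"""Univariate limits of detection from peak-height calibration curves.

Two criteria are provided: the calibration-curve estimate LoD = k*SD/m
(k = 3 by default, SD = residual standard deviation, m = slope of the
peak-height vs concentration line over the linear region), and the
blank-based criterion (lowest concentration whose mean peak height exceeds
k times the SD of the blank signal in the same window).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .types import SpectraSet

__all__ = [
    "CalibrationCurve",
    "LoDEstimate",
    "measure_peak_height",
    "peak_heights",
    "fit_calibration",
    "lod_from_calibration",
    "lod_blank_criterion",
]

MIN_CALIBRATION_POINTS = 5  # linear region must hold at least five points


@dataclass
class CalibrationCurve:
    concentrations: np.ndarray  # ppm, points used in the fit
    responses: np.ndarray       # peak heights, intensity units
    slope: float                # intensity per ppm
    intercept: float            # intensity
    residual_sd: float          # intensity, sqrt(RSS / (n - 2))
    r2: float
    region: tuple[float, float]  # concentration bounds of the linear region
    n_points: int


@dataclass
class LoDEstimate:
    value: float                # ppm (nan when above the tested range)
    method: str                 # univariate_eq1 | blank_3sd | pls_ortiz
    analyte: str | None = None
    peak_wavenumber: float | None = None
    above_range: bool = False
    details: dict = field(default_factory=dict)


def measure_peak_height(
    intensities: np.ndarray,
    axis: np.ndarray,
    peak_wavenumber: float,
    half_width: float = 10.0,
) -> float:
    """Baseline-corrected peak height in a local window.

    A straight baseline is drawn between the window endpoints and the height
    is the maximum of (signal - baseline) inside the window.  May be negative
    for pure noise.
    """
    axis = np.asarray(axis, dtype=float)
    y = np.asarray(intensities, dtype=float)
    lo, hi = peak_wavenumber - half_width, peak_wavenumber + half_width
    if lo < axis[0] or hi > axis[-1]:
        raise ValueError(
            f"window {lo:.1f}-{hi:.1f} cm^-1 extends off-axis "
            f"({axis[0]:.1f}-{axis[-1]:.1f} cm^-1)"
        )
    mask = (axis >= lo) & (axis <= hi)
    idx = np.flatnonzero(mask)
    i0, i1 = idx[0], idx[-1]
    if i1 - i0 < 2:
        raise ValueError("peak window narrower than 3 channels")
    frac = (axis[idx] - axis[i0]) / (axis[i1] - axis[i0])
    baseline = y[i0] + frac * (y[i1] - y[i0])
    return float(np.max(y[idx] - baseline))


def peak_heights(
    sset: SpectraSet, peak_wavenumber: float, half_width: float = 10.0
) -> np.ndarray:
    """Vector of peak heights, one per spectrum in the set."""
    return np.array(
        [measure_peak_height(row, sset.axis, peak_wavenumber, half_width)
         for row in sset.intensities]
    )


def fit_calibration(
    concentrations: np.ndarray,
    heights: np.ndarray,
    n_lowest: int = 5,
    region: str = "lowest",
) -> CalibrationCurve:
    """OLS peak-height calibration over the linear region.

    ``region="lowest"`` uses all points at the ``n_lowest`` lowest nonzero
    concentration levels (the convention for LoD work: the uncertainty of the
    low-concentration range is what matters); ``region="auto"`` grows the
    region upward from ``n_lowest`` levels, keeping the size that maximises
    R^2.  At least five points are required.
    """
    conc = np.asarray(concentrations, dtype=float)
    h = np.asarray(heights, dtype=float)
    if conc.shape != h.shape:
        raise ValueError("concentrations and heights must have equal length")
    nz = conc > 0
    levels = np.unique(conc[nz])
    if levels.size < 2:
        raise ValueError("calibration needs at least two distinct nonzero concentrations")

    def fit_levels(k: int) -> CalibrationCurve:
        sel_levels = levels[:k]
        mask = np.isin(conc, sel_levels)
        x, y = conc[mask], h[mask]
        if x.size < MIN_CALIBRATION_POINTS:
            raise ValueError(
                f"linear region holds {x.size} points; the five-point rule "
                f"requires at least {MIN_CALIBRATION_POINTS}"
            )
        res = stats.linregress(x, y)
        resid = y - (res.slope * x + res.intercept)
        sd = math.sqrt(float(resid @ resid) / (x.size - 2))
        return CalibrationCurve(
            concentrations=x,
            responses=y,
            slope=float(res.slope),
            intercept=float(res.intercept),
            residual_sd=sd,
            r2=float(res.rvalue**2),
            region=(float(sel_levels.min()), float(sel_levels.max())),
            n_points=int(x.size),
        )

    k0 = min(n_lowest, levels.size)
    if region == "lowest":
        return fit_levels(k0)
    if region == "auto":
        fits = [fit_levels(k) for k in range(k0, levels.size + 1)]
        return max(fits, key=lambda c: c.r2)
    raise ValueError(f"unknown region rule {region!r}")


def lod_from_calibration(
    curve: CalibrationCurve,
    k: float = 3.0,
    analyte: str | None = None,
    peak_wavenumber: float | None = None,
) -> LoDEstimate:
    """Calibration-curve LoD: the critical response ``c + k*SD`` mapped back
    through the fitted line (the intercept cancels), i.e. ``k * SD / m``."""
    if curve.slope <= 0:
        raise ValueError("non-positive calibration slope: no sensitivity at this band")
    value = k * curve.residual_sd / curve.slope
    return LoDEstimate(
        value=float(value),
        method="univariate_eq1",
        analyte=analyte,
        peak_wavenumber=peak_wavenumber,
        details={"k": k, "slope": curve.slope, "residual_sd": curve.residual_sd,
                 "r2": curve.r2, "n_points": curve.n_points},
    )


def lod_blank_criterion(
    dilution_set: SpectraSet,
    analyte: str,
    peak_wavenumber: float,
    half_width: float = 10.0,
    k: float = 3.0,
) -> LoDEstimate:
    """Blank-threshold LoD: the lowest concentration whose mean peak height
    exceeds ``k`` times the SD of the blank heights in the same window.

    The set must contain at least 3 blank (0 ppm) replicates.  If no level
    qualifies the estimate is flagged ``above_range`` with value NaN.
    """
    conc = dilution_set.concentrations[analyte].to_numpy(dtype=float)
    h = peak_heights(dilution_set, peak_wavenumber, half_width)
    blank = h[conc == 0]
    if blank.size < 3:
        raise ValueError(f"need >= 3 blank replicates, found {blank.size}")
    threshold = k * float(blank.std(ddof=1))
    details = {"k": k, "blank_sd": float(blank.std(ddof=1)), "n_blanks": int(blank.size)}
    for level in np.unique(conc[conc > 0]):
        if h[conc == level].mean() > threshold:
            return LoDEstimate(
                value=float(level), method="blank_3sd", analyte=analyte,
                peak_wavenumber=peak_wavenumber, details=details,
            )
    return LoDEstimate(
        value=float("nan"), method="blank_3sd", analyte=analyte,
        peak_wavenumber=peak_wavenumber, above_range=True, details=details,
    )
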