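"""Column calibration and chromatogram -> distribution conversion.

A GPC column separates by hydrodynamic size, so larger molecules elute
earlier.  Narrow polystyrene standards of known molecular weight fix the
map from elution time t (min) to log10 M; a low-order polynomial fit of
log10 M on t is the conventional calibration model.  A baseline-corrected
refractive-index chromatogram S(t) is then converted to a weight-fraction
density per unit log10 M via the Jacobian of the fitted map:

    u(log10 M) = S(t) / |d(log10 M)/dt|

evaluated from the fitted polynomial's derivative, after which the curve is
normalized.  The detector signal is taken as proportional to mass
concentration (refractive-index detection); no dn/dc correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numpy.polynomial import Polynomial

from .mwd import EmptyDistributionError, MWDistribution, normalize

__all__ = [
    "Chromatogram",
    "CalibrationCurve",
    "NonMonotoneCalibrationError",
    "fit_calibration",
    "baseline_correct",
    "trim_to_elution_window",
    "chromatogram_to_mwd",
]

logger = logging.getLogger(__name__)

_MONOTONE_SCAN_POINTS = 1000


class NonMonotoneCalibrationError(ValueError):
    """Fitted calibration is not strictly decreasing over its valid range."""


@dataclass
class Chromatogram:
    """Detector trace: strictly ascending elution times (min) and signal."""

    label: str
    time: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.ndim != 1 or self.time.size < 2:
            raise ValueError("time must be 1-D with at least 2 points")
        if self.signal.shape != self.time.shape:
            raise ValueError("signal must have the same length as time")
        if np.any(np.diff(self.time) <= 0.0):
            raise ValueError("time must be strictly increasing")


@dataclass
class CalibrationCurve:
    """Polynomial map elution time (min) -> log10 molecular weight.

    ``coefficients`` are in ascending power order.  The map must be strictly
    decreasing over [time_valid_min, time_valid_max] (larger molecules elute
    earlier); this is asserted on every fit.
    """

    coefficients: np.ndarray
    degree: int
    time_valid_min: float
    time_valid_max: float
    standards: list[tuple[float, float]] = field(default_factory=list)
    fit_residual_rms: float = 0.0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.degree < 1:
            raise ValueError("degree must be >= 1")

    @property
    def _poly(self) -> Polynomial:
        return Polynomial(self.coefficients)

    def log10_mw(self, t):
        return self._poly(np.asarray(t, dtype=float))

    def mw(self, t):
        return 10.0 ** self.log10_mw(t)

    def dlog10_dt(self, t):
        return self._poly.deriv()(np.asarray(t, dtype=float))

    def mapped_log10_range(self) -> tuple[float, float]:
        """(low, high) log10 M covered by the valid time window."""
        lo = float(self.log10_mw(self.time_valid_max))
        hi = float(self.log10_mw(self.time_valid_min))
        return lo, hi


def _check_monotone_decreasing(poly: Polynomial, t0: float, t1: float) -> None:
    ts = np.linspace(t0, t1, _MONOTONE_SCAN_POINTS)
    deriv = poly.deriv()(ts)
    bad = deriv >= 0.0
    if np.any(bad):
        lo, hi = float(ts[bad].min()), float(ts[bad].max())
        raise NonMonotoneCalibrationError(
            f"calibration is not strictly decreasing for t in "
            f"[{lo:.4g}, {hi:.4g}] min"
        )


def fit_calibration(
    standards: Sequence[tuple[float, float]], degree: int = 3
) -> CalibrationCurve:
    """Least-squares polynomial fit of log10(M) on retention time.

    ``standards`` is a sequence of (molecular weight g/mol, retention time
    min).  Requires at least degree+1 standards with distinct times; the
    fitted map must be strictly decreasing over the standards' time span
    (checked on a 1000-point scan).
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    standards = [(float(m), float(t)) for m, t in standards]
    if len(standards) < degree + 1:
        raise ValueError(
            f"need at least {degree + 1} standards for degree {degree}, "
            f"got {len(standards)}"
        )
    mws = np.array([m for m, _ in standards])
    times = np.array([t for _, t in standards])
    if np.any(mws <= 0):
        raise ValueError("all standard molecular weights must be > 0")
    if np.unique(times).size != times.size:
        raise ValueError("duplicate retention times among standards")
    logm = np.log10(mws)
    # Fit in a shifted/scaled window for conditioning, then convert back to
    # plain power-series coefficients.
    poly = Polynomial.fit(times, logm, deg=degree).convert()
    resid = poly(times) - logm
    rms = float(np.sqrt(np.mean(resid**2)))
    t0, t1 = float(times.min()), float(times.max())
    _check_monotone_decreasing(poly, t0, t1)
    return CalibrationCurve(
        coefficients=poly.coef,
        degree=degree,
        time_valid_min=t0,
        time_valid_max=t1,
        standards=standards,
        fit_residual_rms=rms,
    )


def baseline_correct(
    chrom: Chromatogram, t_start: float, t_end: float
) -> Chromatogram:
    """Subtract a linear baseline anchored at t_start and t_end.

    The straight line through (t_start, S(t_start)) and (t_end, S(t_end)) is
    subtracted inside the window; the signal outside [t_start, t_end] is set
    to 0; negative residuals are clipped to 0 (count logged).
    """
    if not t_start < t_end:
        raise ValueError("t_start must be < t_end")
    if t_start < chrom.time[0] or t_end > chrom.time[-1]:
        raise ValueError(
            f"baseline window [{t_start}, {t_end}] outside recorded time "
            f"range [{chrom.time[0]}, {chrom.time[-1]}]"
        )
    s0 = float(np.interp(t_start, chrom.time, chrom.signal))
    s1 = float(np.interp(t_end, chrom.time, chrom.signal))
    baseline = s0 + (chrom.time - t_start) * (s1 - s0) / (t_end - t_start)
    corrected = chrom.signal - baseline
    inside = (chrom.time >= t_start) & (chrom.time <= t_end)
    corrected = np.where(inside, corrected, 0.0)
    neg = corrected < 0.0
    n_clipped = int(np.count_nonzero(neg & inside))
    if n_clipped:
        logger.warning(
            "%s: clipped %d negative point(s) after baseline subtraction",
            chrom.label, n_clipped,
        )
    corrected = np.where(neg, 0.0, corrected)
    return replace(chrom, signal=corrected)


def trim_to_elution_window(
    chrom: Chromatogram, threshold_frac: float = 0.005
) -> Chromatogram:
    """Restrict the trace to the contiguous window where the peak elutes.

    Starting from the (smoothed) peak maximum, the window is expanded in
    both directions until the smoothed signal stays below ``threshold_frac``
    times the peak for a full smoothing width.  Smoothing (boxcar, ~1% of
    the trace length) makes the window detection robust to detector noise;
    the returned signal values themselves are untouched.  This is the usual
    integration-window choice on real traces: regions that carry only
    detector noise would otherwise bias the converted distribution (the
    clipped noise floor rectifies to positive density, inflating Mn at the
    low-M end in particular).  The sample's recorded support becomes the
    trimmed window.
    """
    if not 0 <= threshold_frac < 1:
        raise ValueError("threshold_frac must be in [0, 1)")
    n = chrom.signal.size
    w = max(3, n // 100)
    kernel = np.ones(w) / w
    smooth = np.convolve(chrom.signal, kernel, mode="same")
    smax = float(smooth.max())
    if smax <= 0:
        raise ValueError(f"{chrom.label}: no positive signal to window on")
    above = smooth >= threshold_frac * smax
    peak = int(np.argmax(smooth))
    hi = peak
    while hi < n - 1 and above[hi + 1 : hi + 1 + w].any():
        hi += 1
    lo = peak
    while lo > 0 and above[max(0, lo - w) : lo].any():
        lo -= 1
    if hi - lo < 1:
        raise ValueError(f"{chrom.label}: elution window collapsed to a point")
    return replace(chrom, time=chrom.time[lo : hi + 1], signal=chrom.signal[lo : hi + 1])


def chromatogram_to_mwd(
    chrom: Chromatogram,
    cal: CalibrationCurve,
    extrapolate: bool = False,
) -> MWDistribution:
    """Convert a baseline-corrected chromatogram into a normalized MWD.

    Each time point maps to log10 M through the calibration; the density
    per unit log10 M is signal / |d(log10 M)/dt|.  Points outside the
    calibration's valid time window are dropped unless ``extrapolate`` is
    set (in which case their use is logged prominently).
    """
    t = chrom.time
    s = chrom.signal
    inside = (t >= cal.time_valid_min) & (t <= cal.time_valid_max)
    n_out = int(np.count_nonzero(~inside))
    if n_out:
        if extrapolate:
            logger.warning(
                "%s: extrapolating calibration for %d point(s) outside "
                "[%g, %g] min", chrom.label, n_out,
                cal.time_valid_min, cal.time_valid_max,
            )
        else:
            logger.warning(
                "%s: dropping %d point(s) outside calibration validity "
                "[%g, %g] min", chrom.label, n_out,
                cal.time_valid_min, cal.time_valid_max,
            )
            t, s = t[inside], s[inside]
    if t.size < 2:
        raise ValueError(f"{chrom.label}: empty time window after validity cut")
    deriv = cal.dlog10_dt(t)
    if np.any(deriv == 0.0):
        raise ValueError(
            f"{chrom.label}: calibration derivative vanishes inside the "
            "window (singular Jacobian)"
        )
    logm = cal.log10_mw(t)
    density = s / np.abs(deriv)
    # Calibration decreases with time, so reversing time order sorts M ascending.
    order = np.argsort(logm)
    dist = MWDistribution(
        label=chrom.label,
        grid=10.0 ** logm[order],
        density=density[order],
        abscissa_convention="log10_M",
    )
    try:
        return normalize(dist)
    except EmptyDistributionError as exc:
        raise EmptyDistributionError(
            f"{chrom.label}: chromatogram carries no signal inside the "
            "calibration window"
        ) from exc
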