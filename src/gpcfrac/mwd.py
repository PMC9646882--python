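"""Molecular-weight distributions and their summary statistics.

A GPC/SEC measurement of a polydisperse polymer yields a weight-fraction
density curve w over molecular weight M (g/mol).  Two abscissa conventions
are in use: the density may be per unit of linear M (``linear_M``) or per
unit of log10 M (``log10_M``, the GPC-native "dW/dlogM" curve).  The two are
related by the Jacobian u(log10 M) = ln(10) * M * w(M).

Everything downstream — number/weight averages, dispersity, and the
interval mass fractions that the interval-resolved fractionation analysis
is built on — reduces to composite-trapezoid integrals of these
piecewise-linear curves, with linear interpolation at interval cut points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MWDistribution",
    "SampleSummary",
    "EmptyDistributionError",
    "normalize",
    "summarize",
    "pdi_from_averages",
    "interval_mass_fraction",
    "resample_to_common_grid",
    "convert_convention",
    "LN10",
]

logger = logging.getLogger(__name__)

LN10 = float(np.log(10.0))

_CONVENTIONS = ("linear_M", "log10_M")


class EmptyDistributionError(ValueError):
    """Raised when a distribution has zero (or negative) total area."""


@dataclass
class MWDistribution:
    """A weight-fraction density curve over molecular weight.

    Parameters
    ----------
    label : str
        Free-text sample label.
    grid : array-like
        Strictly ascending molecular weights, g/mol, all > 0.
    density : array-like
        Non-negative weight-fraction density, one value per grid point,
        per unit of the declared abscissa.
    abscissa_convention : {"linear_M", "log10_M"}
        The variable the density is per-unit-of.
    """

    label: str
    grid: np.ndarray
    density: np.ndarray
    abscissa_convention: str = "log10_M"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.abscissa_convention not in _CONVENTIONS:
            raise ValueError(
                f"unknown abscissa_convention {self.abscissa_convention!r}; "
                f"expected one of {_CONVENTIONS}"
            )
        if self.grid.ndim != 1 or self.grid.size < 2:
            raise ValueError("grid must be 1-D with at least 2 points")
        if self.density.shape != self.grid.shape:
            raise ValueError("density must have the same length as grid")
        if np.any(self.grid <= 0.0):
            raise ValueError("all molecular weights must be > 0")
        if np.any(np.diff(self.grid) <= 0.0):
            raise ValueError("grid must be strictly increasing")
        if np.any(~np.isfinite(self.density)):
            raise ValueError("density contains non-finite values")
        neg = self.density < 0.0
        if np.any(neg):
            # Slightly negative densities can survive baseline correction;
            # clip and warn rather than refuse the curve.
            logger.warning(
                "%s: clipped %d negative density value(s) to 0",
                self.label, int(neg.sum()),
            )
            self.density = np.where(neg, 0.0, self.density)

    @property
    def support_min(self) -> float:
        return float(self.grid[0])

    @property
    def support_max(self) -> float:
        return float(self.grid[-1])

    @property
    def abscissa(self) -> np.ndarray:
        """Grid expressed in the declared abscissa variable."""
        if self.abscissa_convention == "log10_M":
            return np.log10(self.grid)
        return self.grid

    def area(self) -> float:
        """Trapezoidal area of the density over the declared abscissa."""
        return float(np.trapezoid(self.density, self.abscissa))


@dataclass
class SampleSummary:
    """Number/weight averages and dispersity of a distribution.

    ``area`` is the integral of the raw density before normalization and
    ``normalization_constant`` is mass / area — the per-sample constant that
    converts the recorded curve into absolute interval masses (it cancels
    from every composition, yield, and enrichment ratio).
    """

    Mn: float
    Mw: float
    PDI: float
    area: float
    normalization_constant: float | None = None

    def __post_init__(self) -> None:
        if not (self.Mn > 0):
            raise ValueError("Mn must be positive")
        if self.Mw < self.Mn * (1.0 - 1e-12):
            logger.warning("Mw (%g) < Mn (%g): physically impossible", self.Mw, self.Mn)

    def rounded(self) -> tuple[int, int, float]:
        """(Mn, Mw, PDI) at reporting precision: integer g/mol, PDI 2 d.p."""
        return int(round(self.Mn)), int(round(self.Mw)), round(self.PDI, 2)


def _interp_density(x: np.ndarray, y: np.ndarray, at: float) -> float:
    return float(np.interp(at, x, y))


def _segment_area(x: np.ndarray, y: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoid integral of the piecewise-linear curve (x, y) over [lo, hi].

    lo/hi are clipped to [x[0], x[-1]]; cut points falling between nodes are
    handled by linear interpolation of y.
    """
    lo = max(lo, float(x[0]))
    hi = min(hi, float(x[-1]))
    if hi <= lo:
        return 0.0
    inside = (x > lo) & (x < hi)
    xs = np.concatenate(([lo], x[inside], [hi]))
    ys = np.concatenate(
        ([_interp_density(x, y, lo)], y[inside], [_interp_density(x, y, hi)])
    )
    return float(np.trapezoid(ys, xs))


def normalize(dist: MWDistribution) -> MWDistribution:
    """Rescale the density to unit area over the declared abscissa.

    Idempotent; raises :class:`EmptyDistributionError` if the total area is
    not positive.
    """
    area = dist.area()
    if not area > 0.0:
        raise EmptyDistributionError(
            f"{dist.label}: empty distribution (total area {area:g})"
        )
    return replace(dist, density=dist.density / area)


def summarize(dist: MWDistribution, mass: float | None = None) -> SampleSummary:
    """Compute Mn, Mw and PDI of a distribution.

    With w(M) the density per unit linear M (the Jacobian
    w(M) = u(log10 M) / (ln10 * M) is applied when the declared abscissa is
    log10 M):

        Mw = int M * w dM / int w dM
        Mn = int w dM / int (w / M) dM
        PDI = Mw / Mn

    The raw (pre-normalization) area over the declared abscissa is recorded;
    if ``mass`` (g) is given, ``normalization_constant = mass / area``.
    """
    area = dist.area()
    if not area > 0.0:
        raise EmptyDistributionError(
            f"{dist.label}: empty distribution (total area {area:g})"
        )
    x = dist.abscissa
    if dist.abscissa_convention == "log10_M":
        u = dist.density  # per unit log10 M
        w0 = float(np.trapezoid(u, x))                  # int w dM
        w1 = float(np.trapezoid(u * dist.grid, x))      # int M w dM
        wm1 = float(np.trapezoid(u / dist.grid, x))     # int (w/M) dM
    else:
        w = dist.density
        w0 = float(np.trapezoid(w, x))
        w1 = float(np.trapezoid(w * dist.grid, x))
        wm1 = float(np.trapezoid(w / dist.grid, x))
    Mw = w1 / w0
    Mn = w0 / wm1
    n = mass / area if mass is not None else None
    return SampleSummary(Mn=Mn, Mw=Mw, PDI=Mw / Mn, area=area, normalization_constant=n)


def pdi_from_averages(Mn: float, Mw: float) -> float:
    """Dispersity Mw/Mn from the two averages.

    Mw < Mn is physically impossible and logs a warning (but still returns
    the ratio so that rounding artifacts in reported tables can be probed).
    """
    if not Mn > 0:
        raise ValueError("Mn must be positive")
    if Mw < Mn:
        logger.warning("Mw (%g) < Mn (%g): physically impossible input", Mw, Mn)
    return Mw / Mn


def _bounds_to_abscissa(dist: MWDistribution, a: float, b: float) -> tuple[float, float]:
    if a > b:
        raise ValueError(f"interval bounds out of order: a={a} > b={b}")
    if dist.abscissa_convention == "log10_M":
        # Clip at the support before taking logs so a=0 (or any bound below
        # the support) is legal shorthand for "from the minimum".
        a = max(a, dist.support_min)
        b = max(b, dist.support_min)
        return np.log10(a), np.log10(b)
    return a, b


def interval_mass_fraction(dist: MWDistribution, a: float, b: float) -> float:
    """Mass fraction of the sample with molecular weight in [a, b].

    The ratio of the trapezoid integral of the density over [a, b] to the
    integral over the full recorded support, both in the declared abscissa.
    Bounds outside the support are clipped; bounds between grid points cut
    the piecewise-linear density by interpolation.
    """
    total = dist.area()
    if not total > 0.0:
        raise EmptyDistributionError(
            f"{dist.label}: empty distribution (total area {total:g})"
        )
    lo, hi = _bounds_to_abscissa(dist, a, b)
    part = _segment_area(dist.abscissa, dist.density, lo, hi)
    return min(max(part / total, 0.0), 1.0)


def resample_to_common_grid(dists: Sequence[MWDistribution]) -> list[MWDistribution]:
    """Re-express several distributions on one shared molecular-weight grid.

    The shared grid is the union of the input grids.  Each sample keeps its
    own support: its density is linearly interpolated inside it and set to 0
    outside, which leaves every interval mass fraction (and hence Mn/Mw)
    unchanged because the union grid contains all original nodes.
    """
    dists = list(dists)
    if not dists:
        return []
    conventions = {d.abscissa_convention for d in dists}
    if len(conventions) > 1:
        raise ValueError(f"mixed abscissa conventions: {sorted(conventions)}")
    common = np.unique(np.concatenate([d.grid for d in dists]))
    out = []
    for d in dists:
        dens = np.interp(common, d.grid, d.density, left=0.0, right=0.0)
        outside = (common < d.support_min) | (common > d.support_max)
        dens = np.where(outside, 0.0, dens)
        out.append(replace(d, grid=common, density=dens))
    return out


def convert_convention(dist: MWDistribution, to: str) -> MWDistribution:
    """Convert between per-unit-M and per-unit-log10M densities.

    Applies the Jacobian u(log10 M) = ln(10) * M * w(M) at the grid nodes;
    interval mass fractions agree between the two parametrizations up to
    quadrature error on the shared grid.
    """
    if to not in _CONVENTIONS:
        raise ValueError(f"unknown abscissa_convention {to!r}")
    if to == dist.abscissa_convention:
        return replace(dist)
    if to == "log10_M":
        dens = dist.density * LN10 * dist.grid
    else:
        dens = dist.density / (LN10 * dist.grid)
    return replace(dist, density=dens, abscissa_convention=to)
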