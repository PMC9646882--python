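"""Synthetic parents, partitions, and chromatograms, plus a brute-force oracle.

No raw distribution curves for solvent-fractionated lignin are publicly
deposited, so every stage of the pipeline is exercised on synthetic data
built to mimic the measured setting: a broad (often bimodal) lognormal-type
weight distribution spanning roughly 10^2–10^5.5 g/mol, split into a
soluble and an insoluble fraction with the soluble yield near 42%, small
molecules dissolving preferentially.

Partitioning is done at the density level (a solubility probability p(M)
multiplies the parent curve), not by sampling molecules, so mass
conservation is exact by construction and conservation tests carry no Monte
Carlo error.  Random draws are confined to detector noise.

:func:`oracle_interval_quantities` recomputes every interval quantity by
direct per-grid-cell mass bookkeeping — split the grid at the breakpoints,
assign each cell's trapezoid mass to its interval, sum, and divide — with
none of the normalized-composition algebra of the analysis path.  It is the
independent ground truth the analysis is tested against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .calibration import CalibrationCurve, Chromatogram
from .fractionation import (
    FractionSample,
    FractionationExperiment,
    IntervalReport,
    IntervalScheme,
    classify_R,
)
from .mwd import LN10, MWDistribution, normalize

__all__ = [
    "LognormalMixtureSpec",
    "PartitionSpec",
    "make_parent",
    "partition_parent",
    "oracle_interval_quantities",
    "make_synthetic_chromatogram",
    "DEFAULT_SCHEME",
]

logger = logging.getLogger(__name__)

#: The 8-interval analysis scheme used throughout: min–2000–4000–6000–8000–
#: 10000–20000–50000–max g/mol.
DEFAULT_SCHEME = IntervalScheme(
    ["min", 2000, 4000, 6000, 8000, 10000, 20000, 50000, "max"]
)


@dataclass
class LognormalMixtureSpec:
    """Mixture of lognormal components for a synthetic parent distribution.

    ``components`` is a list of (weight fraction, median g/mol, sigma of
    log10 M).  Weights must be positive and sum to 1; medians must lie
    inside the support.  The default is a bimodal curve spanning
    10^2–10^5.5 g/mol, the shape typical of solvent-fractionation parents.
    """

    components: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(0.45, 2500.0, 0.35), (0.55, 12000.0, 0.40)]
    )
    n_grid: int = 2000
    support_decades: tuple[float, float] = (2.0, 5.5)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.support_decades
        if not lo < hi:
            raise ValueError("degenerate support")
        ws = [w for w, _, _ in self.components]
        if any(w <= 0 for w in ws) or abs(sum(ws) - 1.0) > 1e-9:
            raise ValueError("component weights must be > 0 and sum to 1")
        for _, med, sig in self.components:
            if not (10**lo < med < 10**hi):
                raise ValueError(f"median {med} outside support decades {lo}-{hi}")
            if sig <= 0:
                raise ValueError("sigma must be > 0")
        if self.n_grid < 10:
            raise ValueError("n_grid too small")


@dataclass
class PartitionSpec:
    """Solubility-probability model splitting a parent into soluble/insoluble.

    ``kind``:
      * ``logistic`` — p(M) = 1 / (1 + exp(k (log10 M - log10 M50))),
        decreasing in M (small molecules dissolve preferentially);
        ``steepness`` k is per log10 unit.
      * ``step`` — p = 1 below M50, 0 above.
      * ``uniform`` — p constant (= target yield / 100), size-blind.

    When ``target_yield_pct`` is given, M50 is solved so the soluble yield
    matches it.
    """

    kind: str = "logistic"
    M50: float | None = 6000.0
    steepness: float = 3.0
    target_yield_pct: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("logistic", "step", "uniform"):
            raise ValueError(f"unknown partition kind {self.kind!r}")
        if self.steepness <= 0:
            raise ValueError("steepness must be > 0")
        if self.target_yield_pct is not None and not (
            0 < self.target_yield_pct < 100
        ):
            raise ValueError("target yield must be in (0, 100) percent")
        if self.kind != "uniform" and self.M50 is None and self.target_yield_pct is None:
            raise ValueError("either M50 or target_yield_pct must be given")


def make_parent(spec: LognormalMixtureSpec, label: str = "parent") -> MWDistribution:
    """Normalized lognormal-mixture density on a log10 M grid."""
    lo, hi = spec.support_decades
    x = np.linspace(lo, hi, spec.n_grid)
    dens = np.zeros_like(x)
    for w, med, sig in spec.components:
        dens += w * norm.pdf(x, loc=np.log10(med), scale=sig)
    dist = MWDistribution(
        label=label, grid=10.0**x, density=dens, abscissa_convention="log10_M"
    )
    return normalize(dist)


def _solubility_profile(x: np.ndarray, spec: PartitionSpec, x50: float) -> np.ndarray:
    if spec.kind == "logistic":
        return 1.0 / (1.0 + np.exp(spec.steepness * (x - x50)))
    if spec.kind == "step":
        return np.where(x < x50, 1.0, 0.0)
    raise AssertionError(spec.kind)


def partition_parent(
    parent: MWDistribution,
    m0: float,
    spec: PartitionSpec,
    soluble_label: str = "soluble",
    insoluble_label: str = "insoluble",
) -> FractionationExperiment:
    """Split a parent curve into soluble/insoluble fractions, conserving mass.

    The soluble density is p(M) times the parent density and the insoluble
    density is its complement, so the two curves sum back to the parent
    pointwise and the masses (m0 times each part's share of the parent
    area) sum to m0 exactly.
    """
    if not m0 > 0:
        raise ValueError("m0 must be > 0")
    total = parent.area()
    if not total > 0:
        raise ValueError("parent has zero area")
    x = parent.abscissa

    if spec.kind == "uniform":
        p_const = (
            spec.target_yield_pct / 100.0 if spec.target_yield_pct is not None else 0.42
        )
        p = np.full_like(x, p_const)
    elif spec.target_yield_pct is not None:
        target = spec.target_yield_pct / 100.0

        def soluble_share(x50: float) -> float:
            prof = _solubility_profile(x, spec, x50)
            return float(np.trapezoid(prof * parent.density, x)) / total

        lo, hi = float(x[0]), float(x[-1])
        f_lo, f_hi = soluble_share(lo) - target, soluble_share(hi) - target
        if f_lo * f_hi > 0:
            raise ValueError(
                f"target soluble yield {spec.target_yield_pct}% unreachable "
                f"within support (attainable range "
                f"{100 * (f_lo + target):.1f}–{100 * (f_hi + target):.1f}%)"
            )
        x50 = brentq(lambda v: soluble_share(v) - target, lo, hi, xtol=1e-10)
        p = _solubility_profile(x, spec, x50)
    else:
        p = _solubility_profile(x, spec, np.log10(spec.M50))

    dens_sol = p * parent.density
    dens_ins = parent.density - dens_sol  # exact complement, conserves pointwise
    area_sol = float(np.trapezoid(dens_sol, x))
    m_sol = m0 * area_sol / total
    m_ins = m0 - m_sol

    sol = MWDistribution(
        label=soluble_label, grid=parent.grid.copy(), density=dens_sol,
        abscissa_convention=parent.abscissa_convention,
    )
    ins = MWDistribution(
        label=insoluble_label, grid=parent.grid.copy(), density=dens_ins,
        abscissa_convention=parent.abscissa_convention,
    )
    return FractionationExperiment(
        parent=parent,
        m0=m0,
        fractions=[
            FractionSample(sol, m_sol, soluble_label),
            FractionSample(ins, m_ins, insoluble_label),
        ],
    )


def _cell_masses(
    x: np.ndarray, density: np.ndarray, mass: float, cuts: np.ndarray
) -> np.ndarray:
    """Mass in each interval between consecutive cuts, by per-cell bookkeeping.

    The grid is split at every cut (linear interpolation of the density at
    the cut point); each resulting cell's trapezoid mass is assigned wholly
    to the interval containing it.  Cuts are in abscissa units.
    """
    xs = np.unique(np.concatenate([x, cuts]))
    xs = xs[(xs >= x[0]) & (xs <= x[-1])]
    ys = np.interp(xs, x, density)
    cell_mass = 0.5 * (ys[:-1] + ys[1:]) * np.diff(xs)
    total = cell_mass.sum()
    if not total > 0:
        return np.zeros(len(cuts) - 1)
    scale = mass / total  # per-sample normalization constant
    mids = 0.5 * (xs[:-1] + xs[1:])
    idx = np.clip(np.searchsorted(cuts, mids, side="right") - 1, 0, len(cuts) - 2)
    out = np.zeros(len(cuts) - 1)
    np.add.at(out, idx, cell_mass * scale)
    # Cells outside [cuts[0], cuts[-1]] do not belong to any interval.
    out_of_range = (mids < cuts[0]) | (mids > cuts[-1])
    if np.any(out_of_range):
        np.subtract.at(out, idx[out_of_range], (cell_mass * scale)[out_of_range])
    return out


def oracle_interval_quantities(
    experiment: FractionationExperiment, scheme: IntervalScheme
) -> IntervalReport:
    """Ground-truth interval report by direct mass bookkeeping.

    Requires the experiment's curves to share one grid (as built by
    :func:`partition_parent`).  Every composition, interval yield, and
    enrichment ratio is formed from summed per-cell masses — no
    normalized-composition algebra — so the result is an independent check
    on :func:`gpcfrac.fractionation.analyze`.
    """
    parent = experiment.parent
    for fs in experiment.fractions:
        if not np.array_equal(fs.dist.grid, parent.grid):
            raise ValueError(
                "oracle requires all curves on one shared grid "
                f"({fs.label!r} differs from parent)"
            )
    x = parent.abscissa
    bps = np.array(scheme.resolve(parent.support_min, parent.support_max))
    cuts = np.log10(bps) if parent.abscissa_convention == "log10_M" else bps
    labels = scheme.labels()
    n_int = len(bps) - 1

    m0_cells = _cell_masses(x, parent.density, experiment.m0, cuts)
    rows = []
    for i in range(n_int):
        rows.append(
            {
                "sample": parent.label,
                "role": "parent",
                "interval_index": i,
                "interval_label": labels[i],
                "interval_low": bps[i],
                "interval_high": bps[i + 1],
                "composition_pct": 100.0 * m0_cells[i] / experiment.m0,
                "interval_mass_g": m0_cells[i],
            }
        )

    balance = np.zeros(n_int)
    for fs in experiment.fractions:
        mx_cells = _cell_masses(x, fs.dist.density, fs.mass, cuts)
        y_total = 100.0 * fs.mass / experiment.m0
        for i in range(n_int):
            if m0_cells[i] > 0:
                y_ab = 100.0 * mx_cells[i] / m0_cells[i]
                r = y_ab / y_total if y_total > 0 else np.nan
            else:
                y_ab = np.nan
                r = np.nan
            if not np.isnan(y_ab):
                balance[i] += y_ab
            rows.append(
                {
                    "sample": fs.label,
                    "role": "fraction",
                    "interval_index": i,
                    "interval_label": labels[i],
                    "interval_low": bps[i],
                    "interval_high": bps[i + 1],
                    "composition_pct": 100.0 * mx_cells[i] / fs.mass
                    if fs.mass > 0
                    else np.nan,
                    "interval_mass_g": mx_cells[i],
                    "yield_total_pct": y_total,
                    "interval_yield_pct": y_ab,
                    "ratio_R": r,
                    "classification": classify_R(r) if not np.isnan(r) else "undefined",
                }
            )

    balance_rows = [
        {
            "interval_index": i,
            "interval_label": labels[i],
            "balance_total_pct": balance[i],
            "balance_flag": bool(abs(balance[i] - 100.0) > 7.0),
        }
        for i in range(n_int)
    ]
    return IntervalReport(
        table=pd.DataFrame(rows),
        balance=pd.DataFrame(balance_rows),
        scheme=scheme,
        tol_R=0.15,
        balance_warn_pct=7.0,
    )


def make_synthetic_chromatogram(
    mwd: MWDistribution,
    cal: CalibrationCurve,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_points: int = 2000,
    drift: tuple[float, float] = (0.0, 0.0),
    scale: float = 1.0,
) -> Chromatogram:
    """Detector trace a GPC run of ``mwd`` would produce under ``cal``.

    Inverse of the chromatogram conversion: on a uniform time grid over the
    calibration's valid window, signal(t) = u(log10 M(t)) * |d log10 M/dt|
    (so the conversion round-trips), plus optional seeded Gaussian noise of
    standard deviation ``noise_sd`` and a linear drift
    ``drift = (intercept, slope per min)``.
    """
    if mwd.abscissa_convention != "log10_M":
        from .mwd import convert_convention

        mwd = convert_convention(mwd, "log10_M")
    lo, hi = cal.mapped_log10_range()
    xs = mwd.abscissa
    if xs[0] < lo - 1e-9 or xs[-1] > hi + 1e-9:
        raise ValueError(
            f"{mwd.label}: support (log10 M {xs[0]:.3f}–{xs[-1]:.3f}) outside "
            f"calibration's mapped range ({lo:.3f}–{hi:.3f})"
        )
    t = np.linspace(cal.time_valid_min, cal.time_valid_max, n_points)
    x_of_t = cal.log10_mw(t)
    u = np.interp(x_of_t, xs, mwd.density, left=0.0, right=0.0)
    signal = scale * u * np.abs(cal.dlog10_dt(t))
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    intercept, slope = drift
    signal = signal + intercept + slope * t
    return Chromatogram(label=mwd.label, time=t, signal=signal)
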