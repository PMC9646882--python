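"""Interval-resolved fractionation analysis of a polydisperse polymer.

When a parent polymer sample of mass m0 is split by solvent extraction into
fractions of masses m_x, the ordinary fraction yield Y_x = 100 * m_x / m0
says nothing about *which* molecules went where.  With the weight-fraction
density curves of the parent and each fraction in hand, the mass of any
sample lying in a molecular-weight interval [a, b] is

    m_{s -> a-b} = mass_s * ( int_a^b w_s ) / ( int_min^max w_s ),

so for every interval one can form

* the interval composition (percent of a sample's mass in [a, b]),
* the interval yield  Y_{x -> a-b} = 100 * m_{x -> a-b} / m_{0 -> a-b},
  the share of the parent's [a, b] material that ended up in fraction x,
* the enrichment ratio  R_{x -> a-b} = Y_{x -> a-b} / Y_{x -> total}.

R > 1 means molecules in [a, b] preferentially enter the fraction,
R < 1 that they avoid it, R = 1 that the split is proportional.  Under
exact mass conservation, interval yields summed over all fractions equal
100% on every interval, and R can never exceed 100 / Y_{x -> total}; both
serve as data-quality diagnostics on real measurements.

The per-sample normalization constant n = mass / (curve area) — the
"lignin-mole" bridge between a recorded detector curve and absolute
interval masses — cancels from every composition, yield, and R; it is
exposed via :func:`moles` and used only when absolute interval masses are
requested.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .mwd import (
    EmptyDistributionError,
    MWDistribution,
    interval_mass_fraction,
    summarize,
)

__all__ = [
    "FractionSample",
    "FractionationExperiment",
    "IntervalScheme",
    "IntervalReport",
    "YieldUndefinedError",
    "fraction_yield",
    "moles",
    "interval_mass",
    "interval_composition",
    "interval_yield",
    "ratio_R",
    "classify_R",
    "max_R_bound",
    "analyze",
    "balance_check",
    "DEFAULT_TOL_R",
    "DEFAULT_BALANCE_WARN_PCT",
]

logger = logging.getLogger(__name__)

DEFAULT_TOL_R = 0.15
DEFAULT_BALANCE_WARN_PCT = 7.0

MIN = "min"
MAX = "max"


class YieldUndefinedError(ZeroDivisionError):
    """Parent has no mass in an interval where a fraction does."""


@dataclass
class FractionSample:
    dist: MWDistribution
    mass: float
    label: str

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise ValueError(f"{self.label}: fraction mass must be >= 0")


@dataclass
class FractionationExperiment:
    """Parent distribution + fraction distributions + measured masses."""

    parent: MWDistribution
    m0: float
    fractions: list[FractionSample]
    balance_tolerance: float = 0.02  # relative slack on sum(mx) <= m0

    def __post_init__(self) -> None:
        if not self.m0 > 0:
            raise ValueError("parent mass m0 must be > 0")
        labels = [f.label for f in self.fractions]
        if len(set(labels)) != len(labels):
            raise ValueError(f"fraction labels must be unique, got {labels}")
        total = sum(f.mass for f in self.fractions)
        if total > self.m0 * (1.0 + self.balance_tolerance):
            logger.warning(
                "fraction masses sum to %.4g g > parent mass %.4g g "
                "(mass balance violated)", total, self.m0,
            )

    def total_fraction_mass(self) -> float:
        return sum(f.mass for f in self.fractions)


@dataclass
class IntervalScheme:
    """Ordered breakpoints defining contiguous molecular-weight intervals.

    Breakpoints are g/mol values, optionally starting/ending with the
    symbolic endpoints ``"min"`` / ``"max"`` which resolve per sample to its
    own recorded support.  Intervals are half-open [a, b) except the last,
    which is closed, so contiguous schemes partition the support exactly.
    """

    breakpoints: list[float | str]

    def __post_init__(self) -> None:
        if len(self.breakpoints) < 2:
            raise ValueError("a scheme needs at least 2 breakpoints")
        bps: list[float | str] = []
        for i, b in enumerate(self.breakpoints):
            if isinstance(b, str):
                name = b.strip().lower()
                if name not in (MIN, MAX):
                    raise ValueError(f"unknown symbolic breakpoint {b!r}")
                if (name == MIN and i != 0) or (
                    name == MAX and i != len(self.breakpoints) - 1
                ):
                    raise ValueError(
                        "'min' is only legal first, 'max' only legal last"
                    )
                bps.append(name)
            else:
                bps.append(float(b))
        numeric = [b for b in bps if isinstance(b, float)]
        if any(b <= 0 for b in numeric):
            raise ValueError("numeric breakpoints must be > 0 g/mol")
        if any(x >= y for x, y in zip(numeric, numeric[1:])):
            raise ValueError("breakpoints must be strictly ascending")
        self.breakpoints = bps

    @classmethod
    def from_string(cls, text: str) -> "IntervalScheme":
        """Parse e.g. ``"min,4000,10000,max"`` or ``"min-4000-10000-max"``."""
        sep = "," if "," in text else "-"
        parts = [p.strip() for p in text.split(sep) if p.strip()]
        bps: list[float | str] = [
            p if p.lower() in (MIN, MAX) else float(p.replace("_", "")) for p in parts
        ]
        return cls(bps)

    def resolve(self, support_min: float, support_max: float) -> list[float]:
        """Concrete ascending breakpoints for one sample's support."""
        out = []
        for b in self.breakpoints:
            if b == MIN:
                out.append(float(support_min))
            elif b == MAX:
                out.append(float(support_max))
            else:
                out.append(float(b))
        if any(x >= y for x, y in zip(out, out[1:])):
            raise ValueError(
                f"scheme {self.breakpoints} not strictly ascending once "
                f"resolved against support [{support_min:g}, {support_max:g}]"
            )
        return out

    def intervals(
        self, support_min: float, support_max: float
    ) -> list[tuple[float, float]]:
        bps = self.resolve(support_min, support_max)
        return list(zip(bps, bps[1:]))

    def labels(self) -> list[str]:
        def fmt(b):
            return b if isinstance(b, str) else f"{b:g}"

        return [
            f"{fmt(a)}-{fmt(b)}"
            for a, b in zip(self.breakpoints, self.breakpoints[1:])
        ]


@dataclass
class IntervalReport:
    """Per-interval, per-sample results of :func:`analyze`.

    ``table`` holds one row per (interval, sample) in long format with the
    columns: sample, role (parent/fraction), interval_index, interval_label,
    interval_low, interval_high (sample-resolved bounds), composition_pct,
    interval_mass_g, yield_total_pct, interval_yield_pct, ratio_R,
    classification, r_bound, r_bound_exceeded.  ``balance`` holds one row
    per interval: balance_total_pct and balance_flag.
    """

    table: pd.DataFrame
    balance: pd.DataFrame
    scheme: IntervalScheme
    tol_R: float
    balance_warn_pct: float

    def fraction_rows(self) -> pd.DataFrame:
        return self.table[self.table["role"] == "fraction"]

    def parent_rows(self) -> pd.DataFrame:
        return self.table[self.table["role"] == "parent"]

    def to_json(self, indent: int | None = 2) -> str:
        payload = {
            "scheme": [
                b if isinstance(b, str) else b for b in self.scheme.breakpoints
            ],
            "tol_R": self.tol_R,
            "balance_warn_pct": self.balance_warn_pct,
            "rows": json.loads(self.table.to_json(orient="records", double_precision=15)),
            "balance": json.loads(
                self.balance.to_json(orient="records", double_precision=15)
            ),
        }
        return json.dumps(payload, indent=indent)


def fraction_yield(mx: float, m0: float) -> float:
    """Total fraction yield, percent: 100 * mx / m0."""
    if not m0 > 0:
        raise ValueError("parent mass m0 must be > 0")
    if mx < 0:
        raise ValueError("fraction mass mx must be >= 0")
    return 100.0 * mx / m0


def moles(dist: MWDistribution, mass: float) -> float:
    """Normalization constant n = mass / (curve area).

    The bridge from a recorded (arbitrarily scaled) density curve to
    absolute masses; cancels from all compositions, yields, and ratios.
    """
    if not mass > 0:
        raise ValueError("mass must be > 0")
    area = dist.area()
    if not area > 0:
        raise EmptyDistributionError(f"{dist.label}: zero curve area")
    return mass / area


def interval_mass(dist: MWDistribution, mass: float, a: float, b: float) -> float:
    """Mass (g) of the sample with molecular weight in [a, b].

    Bounds outside [support_min, support_max] are clipped (with a log note,
    since physically min <= a < b <= max).
    """
    if not mass > 0:
        raise ValueError("mass must be > 0")
    if a > b:
        raise ValueError(f"interval bounds out of order: a={a} > b={b}")
    if a < dist.support_min or b > dist.support_max:
        logger.debug(
            "%s: interval [%g, %g] clipped to support [%g, %g]",
            dist.label, a, b, dist.support_min, dist.support_max,
        )
    return interval_mass_fraction(dist, a, b) * mass


def interval_composition(dist: MWDistribution, a: float, b: float) -> float:
    """Percent of the sample's mass in [a, b]; independent of sample mass."""
    return 100.0 * interval_mass_fraction(dist, a, b)


def ratio_R(
    parent: MWDistribution, frac: MWDistribution, a: float, b: float
) -> float:
    """Enrichment ratio: fraction composition over parent composition in [a, b].

    Returns NaN when both compositions are zero (no material of either
    sample in the interval); raises :class:`YieldUndefinedError` when the
    parent composition is zero but the fraction's is not.
    """
    comp_p = interval_mass_fraction(parent, a, b)
    comp_f = interval_mass_fraction(frac, a, b)
    if comp_p == 0.0:
        if comp_f == 0.0:
            return math.nan
        raise YieldUndefinedError(
            f"parent {parent.label!r} has no mass in [{a:g}, {b:g}] but "
            f"fraction {frac.label!r} does: interval yield undefined"
        )
    return comp_f / comp_p


def interval_yield(
    parent: MWDistribution,
    frac: MWDistribution,
    Y_total: float,
    a: float,
    b: float,
) -> float:
    """Interval yield, percent: share of the parent's [a, b] mass captured
    by the fraction.

    Computed as R * Y_total so the identity
    ``interval_yield == ratio_R * yield_total`` holds to float precision.
    NaN (both compositions zero) propagates.
    """
    return ratio_R(parent, frac, a, b) * Y_total


def max_R_bound(Y_total: float) -> float:
    """Supremum of the enrichment ratio under mass conservation: 100/Y_total.

    A fraction capturing *all* of the parent's material in some interval has
    interval yield 100%, hence R = 100 / Y_total; any measured R above this
    bound signals a data-accuracy problem.
    """
    if not 0 < Y_total <= 100:
        raise ValueError("total yield must be in (0, 100] percent")
    return 100.0 / Y_total


def classify_R(R: float, tol: float = DEFAULT_TOL_R) -> str:
    """Classify an enrichment ratio: enriched / neutral / depleted.

    ``neutral`` within +-tol of 1; NaN classifies as ``undefined``.
    """
    if math.isnan(R):
        return "undefined"
    if R < 0:
        raise ValueError("R must be >= 0")
    if R > 1.0 + tol:
        return "enriched"
    if R < 1.0 - tol:
        return "depleted"
    return "neutral"


def analyze(
    experiment: FractionationExperiment,
    scheme: IntervalScheme,
    tol_R: float = DEFAULT_TOL_R,
    balance_warn_pct: float = DEFAULT_BALANCE_WARN_PCT,
) -> IntervalReport:
    """Full interval-resolved report for one fractionation experiment.

    For every interval of the scheme and every sample: compositions and
    interval masses; for every fraction additionally the total yield, the
    interval yield, the enrichment ratio R with its classification, and a
    flag when R exceeds the conservation bound 100/Y_total.  Per interval,
    the balance total (sum of fraction interval yields) is computed and
    flagged when it deviates from 100% by more than ``balance_warn_pct``.
    """
    conventions = {experiment.parent.abscissa_convention} | {
        f.dist.abscissa_convention for f in experiment.fractions
    }
    if len(conventions) > 1:
        raise ValueError(f"mixed abscissa conventions: {sorted(conventions)}")

    parent = experiment.parent
    n_intervals = len(scheme.breakpoints) - 1
    labels = scheme.labels()
    rows: list[dict] = []

    def sample_rows(dist: MWDistribution, mass: float, role: str):
        empty = not dist.area() > 0
        if empty and role == "parent":
            raise EmptyDistributionError(f"parent {dist.label!r}: zero curve area")
        intervals = (
            [(math.nan, math.nan)] * n_intervals
            if empty
            else scheme.intervals(dist.support_min, dist.support_max)
        )
        out = []
        for i, (a, b) in enumerate(intervals):
            comp = (
                math.nan if empty else interval_composition(dist, a, b)
            )
            m_ab = 0.0 if empty else interval_mass_fraction(dist, a, b) * mass
            out.append(
                {
                    "sample": dist.label,
                    "role": role,
                    "interval_index": i,
                    "interval_label": labels[i],
                    "interval_low": a,
                    "interval_high": b,
                    "composition_pct": comp,
                    "interval_mass_g": m_ab,
                }
            )
        return out

    parent_rows = sample_rows(parent, experiment.m0, "parent")
    rows.extend(parent_rows)

    balance = np.zeros(n_intervals)
    balance_any = np.zeros(n_intervals, dtype=bool)

    for fs in experiment.fractions:
        y_total = fraction_yield(fs.mass, experiment.m0)
        frow = sample_rows(fs.dist, fs.mass, "fraction")
        r_cap = max_R_bound(y_total) if y_total > 0 else math.inf
        for i, row in enumerate(frow):
            a_p = parent_rows[i]["interval_low"]
            b_p = parent_rows[i]["interval_high"]
            if y_total == 0.0 or not fs.dist.area() > 0:
                r = 0.0 if parent_rows[i]["composition_pct"] > 0 else math.nan
            else:
                try:
                    # Evaluate on the parent-resolved bounds: min/max are
                    # per-curve, and a fraction's density is zero outside
                    # its own support anyway.
                    r = ratio_R(parent, fs.dist, a_p, b_p)
                except YieldUndefinedError as exc:
                    raise YieldUndefinedError(
                        f"{fs.label!r} in interval {labels[i]}: {exc}"
                    ) from exc
            y_ab = r * y_total
            row.update(
                yield_total_pct=y_total,
                interval_yield_pct=y_ab,
                ratio_R=r,
                classification=classify_R(r, tol_R) if not math.isnan(r) else "undefined",
                r_bound=r_cap,
                r_bound_exceeded=bool(not math.isnan(r) and r > r_cap * (1 + 1e-12)),
            )
            if not math.isnan(y_ab):
                balance[i] += y_ab
                balance_any[i] = True
            if row["r_bound_exceeded"]:
                logger.warning(
                    "%s, interval %s: R = %.3f exceeds conservation bound %.3f",
                    fs.label, labels[i], r, r_cap,
                )
        rows.extend(frow)

    balance_rows = []
    for i in range(n_intervals):
        total = balance[i] if balance_any[i] else math.nan
        flag = bool(balance_any[i] and abs(total - 100.0) > balance_warn_pct)
        if flag:
            logger.warning(
                "interval %s: fraction yields sum to %.2f%% "
                "(deviation beyond %.1f%%)", labels[i], total, balance_warn_pct,
            )
        balance_rows.append(
            {
                "interval_index": i,
                "interval_label": labels[i],
                "balance_total_pct": total,
                "balance_flag": flag,
            }
        )

    return IntervalReport(
        table=pd.DataFrame(rows),
        balance=pd.DataFrame(balance_rows),
        scheme=scheme,
        tol_R=tol_R,
        balance_warn_pct=balance_warn_pct,
    )


def balance_check(
    report: IntervalReport, threshold_pct: float = DEFAULT_BALANCE_WARN_PCT
) -> list[str]:
    """Interval labels whose fraction-yield total deviates from 100% by
    more than ``threshold_pct`` percentage points."""
    bal = report.balance
    dev = (bal["balance_total_pct"] - 100.0).abs()
    flagged = bal[dev > threshold_pct]
    return list(flagged["interval_label"])
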