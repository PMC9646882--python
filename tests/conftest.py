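import numpy as np
import pytest
from numpy.polynomial import Polynomial

from gpcfrac import (
    LognormalMixtureSpec,
    PartitionSpec,
    fit_calibration,
    make_parent,
    partition_parent,
)

# Decreasing cubic elution map covering log10 M ~ [1.84, 5.64] over 14-30 min,
# comfortably spanning the default parent support (10^2 - 10^5.5 g/mol).
CAL_POLY = Polynomial([10.0, -0.38, 0.006, -0.00008])


@pytest.fixture(scope="session")
def cubic_calibration():
    times = np.linspace(14.0, 30.0, 8)
    standards = [(10.0 ** CAL_POLY(t), t) for t in times]
    return fit_calibration(standards, degree=3)


@pytest.fixture(scope="session")
def parent():
    """Default bimodal lognormal parent on a 2000-point log10 M grid."""
    return make_parent(LognormalMixtureSpec())


@pytest.fixture(scope="session")
def experiment(parent):
    """Parent of 2.5 g split by a logistic partition at 42% soluble yield."""
    spec = PartitionSpec(kind="logistic", target_yield_pct=42.0)
    return partition_parent(parent, 2.5, spec)


def lognormal_mwd(median, sigma_log10, n=2000, decades=(2.0, 5.5)):
    """Single weight-lognormal density on a log10 M grid (test helper)."""
    from gpcfrac import MWDistribution, normalize

    x = np.linspace(*decades, n)
    dens = np.exp(-0.5 * ((x - np.log10(median)) / sigma_log10) ** 2)
    return normalize(
        MWDistribution("lognormal", 10.0**x, dens, abscissa_convention="log10_M")
    )


def lognormal_closed_form(median, sigma_log10):
    """Analytic (Mn, Mw) of a weight-lognormal with the given log10-M width."""
    s_ln = sigma_log10 * np.log(10.0)
    return median * np.exp(-0.5 * s_ln**2), median * np.exp(0.5 * s_ln**2)
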