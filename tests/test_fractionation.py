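import math

import numpy as np
import pytest

from gpcfrac import (
    FractionSample,
    FractionationExperiment,
    IntervalScheme,
    LognormalMixtureSpec,
    PartitionSpec,
    YieldUndefinedError,
    analyze,
    balance_check,
    classify_R,
    fraction_yield,
    interval_composition,
    interval_mass,
    interval_yield,
    make_parent,
    max_R_bound,
    moles,
    normalize,
    partition_parent,
    ratio_R,
)
from gpcfrac.mwd import MWDistribution

from conftest import lognormal_mwd


class TestFractionYield:
    @pytest.mark.parametrize(
        "mx,m0,expected", [(1.05, 2.5, 42.0), (0.0, 2.5, 0.0), (2.5, 2.5, 100.0)]
    )
    def test_values(self, mx, m0, expected):
        assert fraction_yield(mx, m0) == pytest.approx(expected)

    def test_zero_parent_mass_rejected(self):
        with pytest.raises(ValueError):
            fraction_yield(1.0, 0.0)


class TestMoles:
    def test_unit_area_returns_mass(self, parent):
        assert moles(parent, 2.5) == pytest.approx(2.5, rel=1e-9)

    def test_scaling(self, parent):
        doubled = MWDistribution(
            "d", parent.grid, 2 * parent.density, parent.abscissa_convention
        )
        assert moles(doubled, 2.5) == pytest.approx(moles(parent, 2.5) / 2, rel=1e-9)

    def test_matches_independent_trapezoid(self):
        rng = np.random.default_rng(11)
        grid = np.sort(rng.uniform(100, 1e5, 200))
        dens = rng.uniform(0.1, 1.0, 200)
        d = MWDistribution("r", grid, dens, "linear_M")
        expected = 2.5 / np.trapezoid(dens, grid)
        assert moles(d, 2.5) == pytest.approx(expected, rel=1e-9)


class TestIntervalMass:
    def test_full_support(self, parent):
        assert interval_mass(
            parent, 2.5, parent.support_min, parent.support_max
        ) == pytest.approx(2.5)

    def test_zero_density_interval(self):
        d = lognormal_mwd(5000.0, 0.1, n=2000, decades=(2.0, 5.5))
        # ten sigmas away from the median: essentially no mass
        assert interval_mass(d, 2.5, 100.0, 120.0) == pytest.approx(0.0, abs=1e-6)

    def test_median_split(self):
        d = lognormal_mwd(5000.0, 0.3, n=2000, decades=(2.0, 5.8))
        assert interval_mass(d, 2.0, d.support_min, 5000.0) == pytest.approx(
            1.0, abs=0.002
        )


class TestIntervalComposition:
    def test_full_support_is_100(self, parent):
        assert interval_composition(
            parent, parent.support_min, parent.support_max
        ) == pytest.approx(100.0)

    def test_complementary_intervals(self, parent):
        lo = interval_composition(parent, parent.support_min, 8000.0)
        hi = interval_composition(parent, 8000.0, parent.support_max)
        assert lo + hi == pytest.approx(100.0, abs=1e-9)

    def test_matches_refined_grid_oracle(self):
        rng = np.random.default_rng(3)
        grid = np.sort(rng.uniform(100, 1e5, 50))
        dens = rng.uniform(0.1, 1.0, 50)
        d = MWDistribution("r", grid, dens, "linear_M")
        a, b = 2500.0, 60000.0
        fine = np.linspace(grid[0], grid[-1], 100_000)
        fdens = np.interp(fine, grid, dens)
        inside = (fine >= a) & (fine <= b)
        expected = 100 * np.trapezoid(fdens[inside], fine[inside]) / np.trapezoid(
            fdens, fine
        )
        assert interval_composition(d, a, b) == pytest.approx(expected, abs=0.01)


class TestRatioAndYield:
    def test_fraction_equal_to_parent_gives_unity(self, parent):
        for a, b in [(100, 2000), (2000, 10000), (10000, 316227)]:
            assert ratio_R(parent, parent, a, b) == pytest.approx(1.0, rel=1e-12)
            assert interval_yield(parent, parent, 42.0, a, b) == pytest.approx(42.0)

    def test_zero_fraction_mass_in_interval(self, parent):
        gone = lognormal_mwd(1000.0, 0.1, n=2000, decades=(2.0, 3.6))
        # the narrow fraction has no mass above ~4000 g/mol
        assert ratio_R(parent, gone, 200000.0, 300000.0) == pytest.approx(0.0, abs=1e-9)

    def test_parent_empty_but_fraction_full_is_undefined(self):
        x = np.linspace(2.0, 5.0, 601)
        grid = 10.0**x
        parent_d = normalize(
            MWDistribution("p", grid, np.where(x < 4.0, 1.0, 0.0), "log10_M")
        )
        frac_d = normalize(
            MWDistribution("f", grid, np.where(x > 4.2, 1.0, 0.0), "log10_M")
        )
        with pytest.raises(YieldUndefinedError):
            ratio_R(parent_d, frac_d, 30000.0, 90000.0)

    def test_both_empty_gives_nan(self):
        x = np.linspace(2.0, 5.0, 601)
        grid = 10.0**x
        d = normalize(
            MWDistribution("p", grid, np.where(x < 4.0, 1.0, 0.0), "log10_M")
        )
        assert math.isnan(ratio_R(d, d, 30000.0, 90000.0))

    def test_eq11_identity(self, experiment):
        parent = experiment.parent
        for fs in experiment.fractions:
            y_total = fraction_yield(fs.mass, experiment.m0)
            for a, b in [(100, 2000), (4000, 9000), (10000, 316227)]:
                r = ratio_R(parent, fs.dist, a, b)
                assert interval_yield(
                    parent, fs.dist, y_total, a, b
                ) == pytest.approx(r * y_total, abs=1e-9)


class TestClassifyAndBound:
    @pytest.mark.parametrize(
        "r,tol,expected",
        [
            (1.84, 0.15, "enriched"),
            (0.64, 0.15, "depleted"),
            (1.0, 0.15, "neutral"),
            (1.09, 0.15, "neutral"),
            (0.87, 0.15, "neutral"),
            (float("nan"), 0.15, "undefined"),
        ],
    )
    def test_classification(self, r, tol, expected):
        assert classify_R(r, tol) == expected

    @pytest.mark.parametrize(
        "y,expected", [(42.0, 2.38), (58.0, 1.72), (100.0, 1.00)]
    )
    def test_conservation_bound(self, y, expected):
        assert round(max_R_bound(y), 2) == expected

    def test_bound_rejects_bad_yield(self):
        with pytest.raises(ValueError):
            max_R_bound(0.0)
        with pytest.raises(ValueError):
            max_R_bound(120.0)


class TestIntervalScheme:
    def test_from_string(self):
        s = IntervalScheme.from_string("min,4000,10000,max")
        assert s.breakpoints == ["min", 4000.0, 10000.0, "max"]

    def test_resolution(self):
        s = IntervalScheme(["min", 4000, 10000, "max"])
        assert s.resolve(100.0, 316227.0) == [100.0, 4000.0, 10000.0, 316227.0]

    def test_rejects_non_ascending(self):
        with pytest.raises(ValueError, match="ascending"):
            IntervalScheme(["min", 10000, 4000, "max"])

    def test_rejects_unresolvable(self):
        s = IntervalScheme(["min", 4000, "max"])
        with pytest.raises(ValueError):
            s.resolve(100.0, 3000.0)  # max below the interior breakpoint

    def test_labels(self):
        s = IntervalScheme(["min", 2000, 50000, "max"])
        assert s.labels() == ["min-2000", "2000-50000", "50000-max"]


class TestAnalyze:
    def test_single_fraction_identical_to_parent(self, parent):
        exp = FractionationExperiment(
            parent=parent,
            m0=2.5,
            fractions=[FractionSample(parent, 2.5, "all")],
        )
        scheme = IntervalScheme(["min", 2000, 10000, 50000, "max"])
        report = analyze(exp, scheme)
        fr = report.fraction_rows()
        np.testing.assert_allclose(fr["ratio_R"], 1.0, atol=1e-9)
        np.testing.assert_allclose(fr["interval_yield_pct"], 100.0, atol=1e-7)
        np.testing.assert_allclose(
            report.balance["balance_total_pct"], 100.0, atol=1e-7
        )
        assert balance_check(report) == []

    def test_compositions_sum_to_100(self, experiment):
        from gpcfrac.synthetic import DEFAULT_SCHEME

        report = analyze(experiment, DEFAULT_SCHEME)
        for sample, grp in report.table.groupby("sample"):
            assert grp["composition_pct"].sum() == pytest.approx(100.0, abs=0.1)

    def test_logistic_partition_monotone_soluble_R(self, experiment):
        from gpcfrac.synthetic import DEFAULT_SCHEME

        report = analyze(experiment, DEFAULT_SCHEME)
        fr = report.fraction_rows()
        sol = fr[fr["sample"] == "soluble"].sort_values("interval_index")
        rs = sol["ratio_R"].to_numpy()
        assert np.all(np.diff(rs) <= 1e-9)
        ins = fr[fr["sample"] == "insoluble"].sort_values("interval_index")
        assert np.all(np.diff(ins["ratio_R"].to_numpy()) >= -1e-9)

    def test_r_respects_conservation_bound(self, experiment):
        from gpcfrac.synthetic import DEFAULT_SCHEME

        report = analyze(experiment, DEFAULT_SCHEME)
        fr = report.fraction_rows()
        assert not fr["r_bound_exceeded"].any()
        assert np.all(
            fr["ratio_R"].to_numpy() <= fr["r_bound"].to_numpy() * (1 + 1e-9)
        )

    def test_mixture_identity(self, experiment):
        # parent composition equals the mass-weighted mixture of fraction
        # compositions when the parent is the exact sum of the fractions
        from gpcfrac.synthetic import DEFAULT_SCHEME

        report = analyze(experiment, DEFAULT_SCHEME)
        parent_rows = report.parent_rows().sort_values("interval_index")
        fr = report.fraction_rows()
        mix = np.zeros(len(parent_rows))
        for fs in experiment.fractions:
            rows = fr[fr["sample"] == fs.label].sort_values("interval_index")
            mix += (fs.mass / experiment.m0) * rows["composition_pct"].to_numpy()
        np.testing.assert_allclose(
            mix, parent_rows["composition_pct"].to_numpy(), atol=1e-9
        )

    def test_inflated_fraction_mass_flags_balance(self, experiment):
        bad = FractionationExperiment(
            parent=experiment.parent,
            m0=experiment.m0,
            fractions=[
                FractionSample(
                    experiment.fractions[0].dist,
                    experiment.fractions[0].mass * 1.2,
                    "soluble",
                ),
                experiment.fractions[1],
            ],
        )
        from gpcfrac.synthetic import DEFAULT_SCHEME

        report = analyze(bad, DEFAULT_SCHEME)
        dev = (report.balance["balance_total_pct"] - 100.0).abs()
        flagged = balance_check(report, 7.0)
        assert list(report.balance["interval_label"][dev > 7.0]) == flagged
        assert flagged  # soluble-dominated intervals must trip the check
        assert balance_check(report, 0.0) == list(
            report.balance["interval_label"][dev > 0.0]
        )

    def test_total_yields_sum_to_100(self, experiment):
        total = sum(
            fraction_yield(fs.mass, experiment.m0) for fs in experiment.fractions
        )
        assert total == pytest.approx(100.0, abs=1e-9)
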