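# Methods

## Data model

A molecular-weight distribution (`MWDistribution`) is a strictly ascending
grid of molecular weights M (g/mol) with a non-negative weight-fraction
density, declared as per-unit-linear-M (`linear_M`) or per-unit-log10-M
(`log10_M`). The two parametrizations are related by the Jacobian
u(log10 M) = ln(10) · M · w(M); all ratios of integrals (compositions,
yields, enrichment ratios) are invariant under this change of variable, so
every quantity is computed in the curve's native convention. The internal
canonical convention is `log10_M` — it is what a GPC calibration produces
naturally, and distribution curves are conventionally plotted against log M.
Whether a given instrument export is per-unit-M or per-unit-logM is often
undocumented, so the flag is explicit rather than guessed; `convert_convention`
moves between the two.

All integrals are composite trapezoids, and interval cut points falling
between grid nodes are handled by linear interpolation of the density. This
matches the piecewise-linear data model of exported chromatograms exactly:
the integration rule introduces no error beyond the discretization already
present in the file. The per-sample support [min, max] is the recorded grid
range after baseline trimming, not a global constant, because the integrals
are per-sample; symbolic `min`/`max` breakpoints in an interval scheme
resolve per sample. Negative densities (possible after baseline subtraction)
are clipped to zero with a logged warning.

## Averages

With w(M) the density per unit linear M,

    Mw = ∫ M·w dM / ∫ w dM,   Mn = ∫ w dM / ∫ (w/M) dM,   PDI = Mw/Mn ≥ 1.

Reported values follow the field's precision conventions: integer g/mol for
Mn/Mw, two decimals for PDI. Note that recomputing PDI from *rounded*
published averages can disagree with a published PDI in the last digit
(e.g. the pair 4282/11975 gives 2.7966 → 2.80 where 2.79 may be printed from
unrounded inputs); `pdi_from_averages` returns the exact ratio and leaves
rounding to the caller.

## The interval method

For parent mass m0 and fraction masses m_x, the normalization constant
n = mass / (curve area) converts a recorded curve into absolute interval
masses, m_{s→a–b} = n_s · ∫_a^b (density). This constant — dimensionally a
scale factor, not a physical mole count — cancels from every composition,
yield, and enrichment ratio; it is exposed as `moles` and used only when
absolute interval masses are requested (`interval_mass`). The separate
identity m = n·M is subsumed by these two operations rather than exposed on
its own.

The interval yield is computed as R · Y_total with R the ratio of fraction
to parent interval compositions, so the identity
`interval_yield = ratio_R × yield_total` holds to float precision by
construction.

Degenerate intervals: if the parent composition in [a, b] is zero while the
fraction's is positive, the yield is undefined and an error names the
interval; if both are zero, R is NaN, classified "undefined", and excluded
from balance totals. Measured data do not pin down a convention here, so
this is a deliberate design choice — a 0/0 interval carries no information
about fractionation preference.

Intervals are half-open [a, b) with the last closed. For trapezoid integrals
of continuous densities the choice is immaterial; it matters only for the
bookkeeping oracle's cell assignment at exact breakpoints, where it prevents
double counting.

## Classification and diagnostics

R is classified enriched / neutral / depleted with a neutrality half-width
of 0.15 by default: ratios in roughly 0.85–1.15 are treated as "close to 1",
consistent with how practitioners read values like 1.09 or 0.87; the width
is configurable because no standard threshold exists.

Two conservation diagnostics apply to any mass-conserving fractionation:
fraction interval yields must sum to 100% on every interval, and
0 ≤ R ≤ 100/Y_total. The balance warning threshold defaults to 7.0
percentage points — the error level reported for careful GPC work of this
kind — and is configurable. Note that intervals carrying very little parent
mass amplify small absolute curve errors into large relative balance errors;
flags on such intervals should be read together with the parent composition.

## Calibration and conversion

The calibration is a least-squares polynomial of log10 M on elution time,
degree 3 by default (common practice; eight standards support it),
configurable 1–5. The fit is rejected unless strictly decreasing over the
standards' time span (checked on a 1000-point scan) — size exclusion elutes
large molecules first. Extrapolation beyond the standards' window is off by
default and loudly logged when enabled, because high-M tails are routinely
calibration-extrapolated in practice and should be flagged.

Chromatogram conversion divides the signal by |d(log10 M)/dt| from the
fitted polynomial's derivative (error if it vanishes in the window), maps
times to molecular weights, sorts ascending, and normalizes. The detector
signal is taken as proportional to mass concentration (refractive-index
detection); no dn/dc correction is applied.

Baseline correction subtracts the straight line through the signal at two
anchor times and zeroes the trace outside the window. With noisy data the
single-point anchors inherit detector noise, which tilts the subtracted
baseline; `trim_to_elution_window` (peak-anchored, on a boxcar-smoothed copy
of the trace, default threshold 0.5% of peak) is the preferred way to
exclude noise-only regions, because integrating the rectified noise floor
biases Mn at the low-M end in particular. With window trimming, Mn and Mw
survive a signal-to-noise ratio of 100 to within ~1%.

## Synthetic study conditions

`LognormalMixtureSpec` defaults emulate a solvent-fractionation parent: a
bimodal mixture (45% at median 2500 g/mol, σ(log10 M) = 0.35; 55% at
12000 g/mol, σ = 0.40) on a 2000-point grid over 10²–10^5.5 g/mol. The
default partition is logistic in log10 M (steepness 3 per decade) with the
midpoint solved by root finding so the soluble yield is exactly 42% — the
soluble/insoluble split of the motivating experiments — and the default
analysis scheme is min–2000–4000–6000–8000–10000–20000–50000–max. The
parent mass defaults to 2.5 g, a typical extraction batch.

Partitioning happens at the density level: the soluble curve is p(M) times
the parent density, the insoluble curve its exact complement, so
conservation is exact by construction and conservation tests carry no
sampling error. Randomness enters only through detector noise in synthetic
chromatograms (seeded `numpy` generators; identical seeds give bit-identical
outputs).

What the generator does *not* emulate: column band broadening, detector
response differences between fractions, acetylation or solubility chemistry,
injection-to-injection drift, and real lignin's departure from lognormal
mixtures. Passing tests therefore demonstrate the correctness of the
integration and bookkeeping machinery under exact mass conservation, not the
accuracy of any particular instrument's output.

## The bookkeeping oracle

`oracle_interval_quantities` recomputes every interval quantity without the
composition algebra of the analysis path: it splits the shared grid at the
resolved breakpoints, computes each cell's trapezoid mass scaled by
mass/area, assigns cells wholly to intervals, sums, and divides mass by
mass. Analysis and oracle agree to ~1e-13 on conserving partitions; the
tests require |ΔR| < 0.01 and |Δyield| < 0.5 pp over 20 randomized
experiments.

One resolution effect is worth knowing: a step partition (discontinuous
p(M)) cannot be represented exactly by a piecewise-linear density — the
grid cell containing the step holds the transition ramp. Intervals wholly
on either side of the step give exact closed-form results; the single
interval whose edge carries the step is accurate to about half a grid cell
relative to the interval width (~2.5% on a 701-point grid for a
0.097-decade interval).

## Problem sizes and numerics

Default grids are 2000 points (interval fractions accurate to ~1e-7 against
a 100 000-point refined-grid oracle; lognormal moments to ≲0.01%). The
conservation and oracle suites run 20 randomized experiments each; the whole
test suite completes in a few seconds. Normalization demands positive total
area and raises an "empty distribution" error otherwise; bounds outside a
sample's support are clipped; a > b is an error rather than a silent zero.

## Known limitations

* Single-detector processing only: no universal (Mark–Houwink) calibration,
  light-scattering/viscometry combination, or peak deconvolution.
* No Mz or higher averages; no absolute molecular weights.
* The enrichment analysis presumes the parent and fraction curves are
  measured on comparable instruments/calibrations; systematic calibration
  differences between runs propagate directly into R.
* Balance diagnostics flag inconsistency but cannot attribute it to a
  specific curve or mass measurement.
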