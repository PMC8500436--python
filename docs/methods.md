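# Methods

This note documents the models, estimators, numerical conventions and design
choices in `hrvscaling`, and what the synthetic-data calibrations do and do
not establish about real recordings.

## Input model and quality screen

The atomic input is one subject's RR-interval sequence (ms) from a 24-h
Holter record, typically 10⁴–10⁵ beats, with optional beat times (seconds
since record start) and age/sex metadata. Readers accept one-value-per-line
text and CSV (`rr_ms`, optional `time_s`), convert seconds to ms on ingest,
and reject non-numeric or non-positive entries with the offending line
number. Writers render values with `repr`, so read(write(x)) reproduces the
doubles bit-exactly.

The quality screen implements the two normality criteria computable from
intervals alone: no pause ≥ 3000 ms and mean night-time rate ≥ 60/min
(mean RR ≤ 1000 ms in the night window). Criteria requiring ECG morphology
(ectopy counts, conduction blocks) are out of scope. "Night" has no
universal clock definition for ambulatory records; the window is therefore
caller-supplied in record time, with a whole-series fallback that is
conservative for both criteria. Intervals outside 200–3000 ms are counted
and reported; nothing is corrected automatically — an explicit
`drop_out_of_bounds` helper removes and counts them when the caller asks.

## Time-domain indices

Computed on the complete series with no detrending, windowing or beat
exclusion: ⟨RR⟩ (arithmetic mean), SD_RR (sample standard deviation, n−1
divisor, the SDNN convention), rMSSD (root of the mean of the n−1 squared
successive differences), pNN50 (percentage of successive differences
strictly greater than 50 ms). The strict inequality follows the index's
definition as intervals that *vary by more than* 50 ms; with 8 ms-quantized
data, ≥ versus > at exactly 50 ms is a real difference.

## Spectral exponent β

Model: S(f) ∝ f^−β at low frequency. Estimator: the series is mean-centred
once as a whole (not per segment), cut into ⌊N/4096⌋ consecutive
non-overlapping 4096-beat segments from the start (remainder discarded), and
the plain squared-magnitude FFT periodogram of each segment — rectangular
window, no per-segment detrending — is averaged bin-wise. DC and Nyquist
bins are excluded (log undefined; aliasing). A Hann-taper option exists but
is off by default, since the reference pipeline uses no taper or detrending.

Spectra are computed in cycles/beat and the axis converted to Hz by dividing
by the subject's mean RR in seconds; the conversion constant is stored in
the result. β is the negated OLS slope of log₁₀ power on log₁₀ frequency
over a fit window, default 2×10⁻⁴–5×10⁻² Hz. Two alternatives are provided:

- `select_fit_range` scans contiguous log-frequency windows (≥ 1.5 decades,
  0.05-dex grid) inside the default clip range and returns the window with
  the largest R², ties (within 10⁻⁶) broken toward the widest then the
  lowest window. The per-participant "optimal range" procedure it stands in
  for is unpublished, so this is a declared surrogate and results carry an
  `auto_range` flag in CLI output.
- `fit_beta_logbinned` reproduces the historical comparison variant: powers
  are averaged within 0.0167-dex log-frequency bins and the slope fitted on
  bin centres over 10⁻⁴–10⁻² Hz. Averaging (logarithmic smoothing) rather
  than raw summation is used because only smoothing preserves a pure power
  law's slope when bins hold unequal numbers of Fourier points; for
  4096-beat segment spectra the bins hold at most one point each and the
  distinction is immaterial.

## DFA exponents

The five canonical steps: cumulative profile of the mean-centred series;
division into ⌊N/s⌋ non-overlapping windows of length s *from the start
only* (the common variant that also scans from the series end is
deliberately not used); least-squares polynomial detrending of degree m on
abscissa k = 1…s per window; per-window mean squared residual; F_m(s) =
square root of the window-mean. The implementation shares one Vandermonde
design per scale across windows and is verified against a naive double-loop
oracle to 10⁻¹⁰ relative error.

Exponents are OLS slopes of log₁₀ F on log₁₀ s over inclusive ranges
α₀: 5–10, α₁: 10–50, α₂: 50–200 beats (s = 10 and s = 50 each serve two
ranges). The default scale grid is ~25 geometrically spaced integers over
[5, 200] with all four range endpoints forced in — enough points for stable
slopes at modest cost. Defaults use m = 1; m = 3, 4 are computed on request
but flagged (`artifact_warning`), as high-order detrending distorts the
small-scale fluctuation function. `alpha_suite` requires N ≥ 400 so s = 200
still averages two windows.

Calibration facts the tests assert: i.i.d. Gaussian input gives
α₁, α₂ = 0.5 (mean over 20 seeds within ±0.03); integrated noise gives
≈ 1.5; a linear trend moves F for m = 1 but not m = 2.

## The unified statistic q

For stationary power-law series, β = 2α − 1. q = β/(2α₂ − 1) is reported
per subject when both estimates exist; it is left undefined (with a
machine-readable reason, never zero or infinity) when |2α₂ − 1| ≤ 10⁻⁶.
Closed-loop on exact-spectrum β = 1 series (2¹⁷ beats), the mean q over ten
seeds is 1.00 ± 0.02 — the two independent estimators agree where theory
says they must. Stage failures in `summarize_subject` degrade to absent
fields so population analyses tolerate records that support only some
measurements.

## Population scaling

All fits are unweighted OLS of log₁₀(value) on log₁₀(age): exponent =
slope, prefactor = 10^intercept (error by the delta method), residual sd in
log₁₀ space, Pearson R, slope-t p-value. pNN50 values of exactly 0 cannot
enter a log fit; they are excluded and counted, with the count reported.

**Breakpoint.** "Best fits on both sides" is operationalized as the
candidate cut-off minimizing the pooled residual SSE of the two independent
branch fits, on a default grid of 25 log-spaced ages in [2, 30]; ties go to
the smaller cut-off, points exactly at the cut-off to the left (child)
branch, and the single-branch SSE is co-reported so users can judge whether
a break is warranted at all. Note a structural caveat: the published SD_RR
branch laws 80·x^0.26 and 290·x^−0.20 cross again near x ≈ 16, so on data
generated from them the pooled-SSE profile is nearly flat between ~12 and
~17 years and the selected cut-off scatters into that band in roughly a
fifth of realizations even at n ≈ 600. The estimator's mode and mean remain
at the true 12 years; single-realization cut-offs should be read with that
flatness in mind.

**ANOVA / model comparison.** `anova_table` decomposes any fit (SST = SSE +
SSM, MSM = SSM/df_model, MSE = SSE/df_error; log-space for log-log fits);
`quadratic_comparison` fits a quadratic in linear or log-log space for
side-by-side SSE comparison with the piecewise law.

**Prediction intervals.** Standard OLS new-observation intervals in log₁₀
space, t·sd·√(1 + 1/n + (x₀−x̄)²/Sxx), back-transformed by 10^(·) — hence
asymmetric in index units. Coverage is verified at 95 % ± 2 % on 10⁴ fresh
synthetic draws.

**Sex ANCOVA.** Per-sex power laws above age 12 plus a joint F-test of the
pooled single-line model against the full model with sex-specific intercept
and slope; the full interaction model is used because the published
comparisons report sex-specific slopes, so "any sex effect" is the relevant
null.

## Synthetic generators: what they emulate and what they do not

`synth_powerlaw_series` uses spectral synthesis: amplitude k^(−β/2) at
positive beat-frequency k/n, i.i.d. uniform phases, inverse real FFT, exact
rescaling to the target mean and sd (matched to 10⁻⁶ relative before
quantization), optional rounding to an 8 ms grid mirroring Holter R-peak
timing resolution. Defaults are n a power of two, mean 800 ms, sd 50 ms —
a typical healthy adult — with mean > 3·sd enforced for positivity
headroom. The output is Gaussian and linear *by construction*: it carries
the second-order structure of HRV and nothing else, which makes it the
right null for estimator calibration and for surrogate logic, but passing
tests on it say nothing about nonsinus beats, nonstationarity, circadian
structure or nonlinear phase coupling in real records. ARFIMA/Davies–Harte
constructions would give the same second-order target less transparently.

`synth_population` draws ages log-uniformly by default over [0.08, 99] so
both extremes of life are populated (a histogram sampler with the recruited
cohort's age distribution is available), and sets each index to its branch
law times 10^ε, ε ~ N(0, sd_log₁₀) — multiplicative scatter, because the
fits operate in log space and published residual sds live there, and
because it guarantees positive values. `synth_index_branches` instead draws
the published per-branch sample sizes (e.g. 177 child + 435 adult for
SD_RR) log-uniformly within each branch, reproducing the composition of the
pooled study data; the breakpoint calibrations use it. Real populations are
neither log-uniform nor exactly power-law with homoscedastic log-normal
scatter; these generators test estimator correctness, not demographic
realism.

All generators are bit-reproducible given (spec, seed).

## Problem sizes and numerical conventions

Calibration runs use 2¹⁵-beat series for DFA nulls, 2¹⁷-beat series for the
q closed loop (10 seeds), 100 seeds for exponent-recovery coverage and 50
for breakpoint recovery — sizes at which every quoted tolerance is
comfortably resolved while the whole suite runs in seconds. Log-log fits
use base-10 logarithms throughout; all slope fits are plain OLS
(`scipy.stats.linregress` / `statsmodels`); fitted-range masks are
inclusive on both ends; zero power or zero fluctuation inside a fit range
is an error naming the offending bin or scale, never silently dropped.

## Known limitations

- The per-participant optimal-range algorithm for β and the original
  stationarity/surrogate screening protocol are not published in detail;
  `select_fit_range` and the phase-randomization surrogate are declared
  stand-ins.
- Ectopy handling is detection-free: out-of-bounds intervals are counted
  (or dropped on request), not corrected as an expert reader would.
- Only second-order fluctuation functions are computed (no multifractal
  q-order spectrum), and no LF/HF band powers.
- The q < 1 deviation expected at early ages reflects age-dependent scale
  ranges; no age-adaptive range algorithm is implemented — exponents are
  always fitted on the fixed ranges above.
- The population model is cross-sectional; prediction intervals describe a
  future *observation* at an age, not an individual's trajectory.
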