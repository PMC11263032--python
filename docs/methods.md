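# Methods

This note documents the models, numerical choices and known limitations of
`ictalcycles`. It states no empirical result that the test suite or the
analysis drivers do not themselves compute.

## 1. Signal path

Raw recordings (40–120 intracranial channels at 256/512/1024 Hz, organised
in contiguous hour-long segments; sub-hour segments are dropped) pass
through: 50 Hz notch (second-order IIR, Q = 30), 4th-order Butterworth
high-pass at 0.1 Hz and low-pass at 95 Hz, then Fourier-method resampling
to 256 Hz. Every filter is applied forward–backward, so the nominal order
refers to one pass and the phase response is identically zero — checked by
a cross-correlation-at-lag-zero test. Canonical bands: theta 4–8, alpha
8–13, beta 13–30, gamma 55–95, broadband 1–99 Hz (gamma starts at 55 Hz to
stay clear of the 50 Hz line; delta 1–4 Hz is exposed but not a default
output, since broadband behaves near-identically).

Band-power fluctuation series use non-overlapping 125 ms frames (8/s).
Each frame's power is the Hann-weighted mean square (a single-segment
Welch estimate — the frame is too short for segment averaging), floored at
1e-12 before log₁₀ so silent frames stay finite.

Per-hour z-scoring of each channel is implemented (`normalize_hour`,
`compute_patient_windows(..., normalize_hourly=True)`) but **off by
default**: forcing every hour to unit variance would erase exactly the
between-hour variance signal that the VM metric tracks. Pipelines that
need the normalization for detector stability can switch it on.

## 2. Markers

All five markers are evaluated on non-overlapping 2-min windows, with
windows intersecting [onset − 300 s, offset + 300 s] of any seizure
excluded (strict interior overlap, so a window merely touching the margin
boundary survives). Hourly values are means over surviving windows, and
over electrodes for the univariate markers.

* **VM**: per-channel unbiased sample variance of the broadband signal.
* **TCM**: the biased (divide-by-n) normalized autocorrelation of the
  mean-subtracted gamma log-power frames; the reported value is the first
  downward crossing of 0.5, linearly interpolated between bracketing lags,
  in seconds. The crossing is one-sided (the time for the ACF to *decay*
  to half maximum); a `two_sided` doubling is a caller-side multiplication.
  The mean-subtracted biased ACF sums to zero over all lags, so with the
  full lag range a crossing always exists; the "never crossed" flag can
  only fire when a caller restricts `max_lag`.
* **NS**: the per-sample Kuramoto order parameter — the **modulus** of the
  channel-mean unit phasor of Hilbert phases — averaged over the window.
  The literal real part printed in the source equations is available as
  `literal_re=True`, but only the modulus satisfies the stated properties
  (1 for aligned phases regardless of the common phase, range [0, 1]); the
  same convention applies to the PLV.
* **SCM**: mean Pearson correlation of gamma log-power frames over
  electrode pairs separated by 10–80 mm (Euclidean); undefined (NaN) when
  no pair falls in the band.
* **IEDF**: discharges per channel per minute on seizure-onset-zone (SOZ)
  channels. The detector runs at 200 Hz: candidates are local maxima of
  the rectified, 10 Hz high-passed signal convolved with a 60 ms
  triangular kernel, above mean + 4·std of that envelope, with a 200 ms
  refractory period. The spike-band high-pass is essential on 1/f-heavy
  signals, whose slow excursions otherwise dominate the envelope
  statistics. The published deep-learning classifier is replaced by a
  surrogate: a candidate is accepted when the largest absolute second
  difference of the spike-band signal within ±10 ms of the peak exceeds
  16 × the std of the surrounding ±0.5 s spike-band context (±50 ms
  guard). For ongoing oscillations this statistic is amplitude-invariant
  and bounded (≈ 2(1 − cos 2πfΔt)·√2, under ~10 at 200 Hz), while
  isolated spikes score several-fold higher; the threshold was calibrated
  on synthetic 8×-background injections over 1/f noise with and without a
  strong shared gamma line (sensitivity 1.0, 0 false positives/min in the
  calibration runs; the tests assert > 95% / < 1 per min). Any callable
  `classifier(segment, fs, peak_idx) -> bool` — e.g. a wrapper around an
  external trained model — drops in via `count_ieds`/`classify_candidates`.

## 3. Cycle detection

Hourly series are cleaned (interior gaps linearly interpolated, edge gaps
nearest-value filled, |z| > 3 outliers replaced by interpolation; series
with > 50% missing hours or < 48 points rejected), then transformed with
Welch's method: 96-h Hann segments, 50% overlap, mean detrended — 96 h
puts 1/24 cycles/hour exactly on bin 4; shorter series fall back to one
full-length segment and the nearest bin.

The null is a red-noise spectrum 1/f^α: ordinary least squares of log₁₀
power on log₁₀ frequency, excluding non-positive bins and the bins nearest
24 h *and* 12 h. The 12-h exclusion is default because amplitude
modulation (1 + d·cos)² of a planted cycle squares into a 12-h harmonic
(the source study likewise reports 12-h peaks), which would otherwise bias
the fit. Monte-Carlo values at the 24-h bin are drawn in the log-power
domain — where the fit is linear and residuals are approximately Gaussian
— as fit mean + N(0, residual variance); the p-value uses the add-one
estimator (1 + #{sim ≥ obs})/(n_sim + 1), so p never reaches 0 and its
floor at the production n_sim = 10,000 is ~1e-4. A `global_peak` flag
compares max-over-bins excess instead of the single 24-h bin (the more
conservative reading of "a peak larger than the peak measured"). The fit
is per patient; degenerate (zero-variance) series report p = 1.
Calibration: analysis/01 measures the type-I error on pure 1/f hourly
series; the acceptance suite requires 0.05 ± 0.03 at 200 series.

## 4. Seizure phase locking

The cleaned hourly series is band-passed to periods of 2–30 h with a
first-order Butterworth applied forward–backward ("single order,
zero-phase"); the upper band edge (2 h = Nyquist of an hourly series) is
pulled to 0.499 cycles/hour for realizability. Before filtering and the
FFT Hilbert transform the series is mirror-extended by 72 h and cropped
afterwards: without padding the analytic phase is badly distorted over
roughly the first and last day (measured phase-error sd ~0.75 rad on edge
days vs ~0.17 interior), which systematically depresses the PLV of
seizures occurring there. Each seizure takes the phase of its onset hour
(no sub-hour interpolation — hourly resolution matches the series);
seizures outside the span are dropped with a count. PLV is the modulus of
the mean unit phasor; group summaries are mean ± SD of per-patient PLVs.
The CDF reference cos(2π·clock_hour/24 − φ₀) (φ₀ = 0: peak at midnight,
configurable) runs through the identical phase/PLV machinery.

## 5. Synthetic cohorts: what is emulated, what is not

The real study cohort is access-restricted, so validation rests on
synthetic data with planted truth. The stated world
(`SyntheticConfig` defaults): 23 patients, 60 channels on a 10 mm 3-D
grid (the real geometry is unpublished; only the 10–80 mm band matters),
256 Hz, 10 days (5–14 in the source cohort), 1/f^1.5 background,
circadian modulation depth 0.5, discharge rate 0.5/min/channel on 3 SOZ
channels (zero off-SOZ: discharges are a property of epileptogenic
tissue; an optional unmodulated floor exists), 20 seizures at von Mises
(μ = 0, κ = 2) phases of the driver, 60 s nominal seizure duration (only
the ±5 min bracketing matters).

All modulated processes share one circadian driver,
cos(2πt/24 h − φ − J_d), where J_d is a day-to-day random-walk drift
(0.35 rad/day) of the physiological phase against the wall clock. The
drift is what separates the clock-only CDF from markers that track the
driver: PLV is rotation-invariant, so with a rigid clock the CDF would
phase-lock exactly as well as any perfectly cycling marker.

Two generation levels:

* `simulate_recording` — full continuous raw signal: spectrally shaped
  (FFT) colored noise, a shared band-passed gamma line mixed in with
  weight 0.15·(1 + 0.3·cos φ(t)) (≈ 2% of variance, the realistic gamma
  share of 1/f-dominated iEEG), a variance envelope 1 + 0.5·cos φ(t),
  spike-wave templates (4 ms-σ Gaussian spike + 200 ms opposite slow
  wave) injected as an inhomogeneous Poisson process on SOZ channels.
  Used at minutes-to-hours scale where the whole pipeline runs end to end.
* `simulate_patient_windows` / `simulate_cohort` — multi-day cohorts
  generated at the level each marker consumes: VM window variances drawn
  through the exact Parseval identity on the synthesized spectrum
  (distribution-identical to generating the window and computing its
  variance — a unit test asserts the identity to 1e-9); TCM from AR(1)
  log-power frames whose half-decay time τ = 0.2 s·(1 + d·cos φ); IEDF
  from Poisson counts; NS from phase ensembles with dispersion
  σ = √(−2 ln s), s = 0.5·(1 + 0.3·cos φ); SCM from shared-factor frames
  with ρ = 0.4·(1 + 0.3·cos φ). Days of continuous 256 Hz raw signal
  (~50 GB/patient at study scale) are thereby avoided.
  `windows_per_hour` duty-cycles each hour (windows taken from the hour's
  start) to scale compute further; it changes estimator noise, never the
  planted structure.

**What a green test establishes — and does not.** The generator plants
clean sinusoidal modulation, stationary noise, independent patients and a
single shared driver. Green cycle/PLV/robustness tests therefore verify
the estimators and their calibration, not clinical performance: real
iEEG adds artifacts, medication tapering, state transitions, electrode
drift, and metric-specific dynamics the generator does not model. In
particular, with one shared driver all markers are near-perfectly
correlated (analysis/05 shows r ≈ 0.99 among the criticality markers),
unlike the partial correlations of real data — the correlation machinery
is exercised, the real-data correlation structure is not reproduced.

## 6. Robustness design

Spatial subsampling fixes one random electrode subset per patient for the
whole record (an implant's montage is fixed); temporal subsampling
redraws the retained windows every hour (a duty-cycled recorder records
every hour). Spatial subsampling applies to univariate markers only.
IEDF's spatial pool is the SOZ by default (mirroring that discharges
concentrate there); pools `all` and `non_soz` reproduce the degradation
when subsampling may or must miss the SOZ. Level "s" is one electrode or
one window/hour. The comparison test against full sampling is a
two-sided paired Wilcoxon signed-rank on per-patient values (mean over
repeats), with a paired t-test alternative; the source figures show
significance stars without naming a test. Default 20 repeats (drivers use
5 for runtime); fraction 1.0 is deterministic and evaluated once. The
"70 percent" reference in the source figure legend is read as comparison
against the full-sampling detected-cycle count, not a fixed constant.

## 7. Open choices, resolved

* Red-noise fit per patient (the source text is ambiguous between
  per-patient and group-average); a group-null variant would be a
  straightforward extension, per-patient matches "significance … in each
  patient".
* MC noise in the log-power domain (flag-selectable linear domain left to
  callers); per-bin comparison at 24 h rather than max-over-bins
  (`global_peak` flag).
* Seizure phase from the onset-hour bin, not interpolated.
* Inter-metric correlations per patient then averaged (Fisher-z t-test
  for stars), on the intersection of non-missing hours (≥ 48).

## 8. Known limitations

* The surrogate IED classifier is a stand-in with the same interface as
  the published deep model, calibrated only on synthetic morphology.
* In the default world the clock drift (0.35 rad/day) costs the CDF only
  a few hundredths of PLV, while IEDF's Poisson count noise costs more:
  the CDF can edge out IEDF, and beats no criticality marker only on
  average (paired difference ≈ +0.02). The qualitative gap between
  metrics and clock grows with drift and with discharge rate; both are
  config knobs, deliberately not tuned post hoc.
* Multi-dien (> 24 h period) cycles, sleep staging, artifact rejection
  and surface electrodes are out of scope; hours shorter than 60 min are
  dropped rather than partially used.
* EDF support covers the standard continuous 16-bit layout with a single
  sampling rate across channels (EDF+ annotations are not parsed;
  seizure times and electrode coordinates arrive as side metadata).
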