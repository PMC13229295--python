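# Methods

This note documents the models, parameter choices and numerical decisions
behind `wristmotion`, and what the synthetic-data tests do and do not
establish about real wrist-accelerometer data.

## Signal model and processing chain

Raw input is tri-axial acceleration in gravitational units (g) at 30 Hz,
dominant wrist, with a start timestamp in device-local time. Two streams
are derived:

**Count stream.** Each axis passes through the count-conversion filter — a
causal cascade of three first-order Butterworth sections (high-pass at
0.719351 Hz; low-passes at 1.054265 Hz and 1.916345 Hz). The corner
frequencies were solved numerically so the cascade's digital magnitude
response at 30 Hz sampling peaks at 0.759 Hz and crosses −6 dB at
0.212 Hz and 2.148 Hz, the published characteristics of the wrist devices
this pipeline targets; the implementation claims no bit-compatibility with
vendor software. The filtered signal is rectified, a dead band of 0.01 g
zeroes sub-threshold output, amplitudes clip at 2.0 g, and each sample is
quantized at 0.01 g per count before summation into 1 s and 15 s epochs
(each computed independently from the 30 Hz stream). Per-epoch vector
magnitude is √(x²+y²+z²), rounded to 2 decimals; axis counts are integers.
The first and last 5 s of every wear period are discarded before epoching
to drop filter transients — negligible against multi-day wear.

**Metric stream.** Jerk and the spectral moments are computed on the
band-passed *magnitude* of the raw signal: the Euclidean norm of
gravity-plus-movement is ≈ 1 g plus the projection of the dynamic
acceleration onto the gravity axis, so band-passing the scalar norm at
0.2–12 Hz (zero-phase, order-4 Butterworth) removes the static component
while preserving the movement's oscillation frequency. Taking the norm
*after* per-axis filtering would rectify the signal and double its
apparent frequency content; the chosen order makes a 3 Hz oscillation
register at 3 Hz, which the signal-recovery tests verify. A separate
per-axis band-pass (`bandpass_movement`) is provided for axis-level
inspection.

## The ten variables

Quantity measures: total activity counts, counts per minute and counts per
day come from the 15 s VM series; median and SD of acceleration are taken
over *moving* seconds only (1 s VM > 0) and peak over all seconds. An
all-quiet record leaves median/SD undefined (NaN), never zero.

Quality measures are computed per calendar day of the device clock and
averaged across days:

* **Sample entropy** (m = 2, r = 0.2 × SD — the physiological time-series
  convention; both exposed in `PipelineConfig`) of the 1 Hz VM series in
  the hour of highest activity (the 3600 s window maximizing summed VM,
  earliest window on ties). Template counts follow the standard
  convention: both the m- and (m+1)-length counts run over the same N−m
  template set, self-matches excluded, Chebyshev distance ≤ r. A constant
  hour contributes 0; an hour with no template matches is undefined and
  excluded. Days with under an hour of data are dropped.
* **Jerk**: mean absolute first difference of the band-passed magnitude ×
  30 Hz, in g/s. "Mean difference" is read as mean *absolute* difference —
  signed differences of a band-passed signal average to ≈ 0 — and the
  g-scale stream (not counts) is used, as the unit g/s requires. Days with
  under a minute of data are skipped.
* **Mean and SD frequency**: power-weighted first and second moments of a
  periodogram smoothed by a 5-ordinate moving average (span in config),
  0 Hz ordinate excluded, zero-padded to the next fast FFT length (pure
  efficiency; the moments are insensitive to the interpolation). Zero
  total power leaves both undefined.

Counting identities hold by construction: total = CPM × worn minutes, and
counts/day = total / n_days with n_days the wear duration rounded to whole
days (minimum 1). Undefined metrics propagate as NaN and drop the wear
period from affected statistics only.

## Statistics

Cross-sectional comparisons restrict DMD participants to their first
observed visit. Kruskal–Wallis is the omnibus across the three classes
(healthy control, ambulatory DMD, non-ambulatory DMD), with two-sided
rank-sum tests for pairwise follow-ups and Benjamini–Hochberg adjustment
across the ten metrics ("false-discovery-rate" is the standard reading of
the clinical description). Spearman matrices are Holm-adjusted over the
unique off-diagonal entries.

Longitudinal models are `log(metric) ~ non-ambulatory + (1 | participant)`
fit by maximum likelihood (not REML) so log-likelihoods are comparable
across fixed-effect specifications. The slope is on a *non-ambulatory*
indicator, so metrics that fall after loss of ambulation get negative B.
Rows with non-positive values are excluded with a reported count.

The binary classifier is an unpenalized logistic regression of ambulatory
status on jerk and mean frequency; accuracy uses the fixed 0.5 threshold.
Complete separation (divergent MLE) triggers a lightly ridge-penalized
refit (α = 0.01) that keeps coefficients finite and probabilities
discriminative, flagged on the result. Bootstrap validation uses the
standard optimism loop: refit on each with-replacement resample, score on
both resample and original data, subtract the mean excess from the
apparent AUC/accuracy; degenerate single-class resamples are redrawn and
counted. The ordinal model is proportional-odds over the severity-ordered
classes and reports all one-vs-rest AUCs rather than privileging one.
External validation applies frozen coefficients per wear period.

## Synthetic cohort generator

Each wear period is gravity + bouts + sensor noise:

* a unit gravity vector whose spherical angles precess slowly
  (5 × 10⁻⁴ Hz default) — the count filter and band-pass must and do
  reject it;
* a fixed 23:00–07:00 sleep window with no movement (all-day wear is
  analyzed without wake/sleep splitting, so one fixed window suffices);
* Poisson-timed bouts during waking hours. Within a bout, a Hann envelope
  modulated by low-pass (2 Hz) log-normal amplitude jitter multiplies a
  mixture of: a narrowband oscillation at the profile's center frequency
  (±8% log-normal jitter), a 5.5–11 Hz tremor-band noise component
  weighted by `tremor_fraction`, and a roughness noise component low-pass
  shaped at `smoothness_corner`. Each bout has a random fixed direction in
  the sensor frame. Exponential durations (clipped 2–120 s) and log-normal
  peak amplitudes complete the bout;
* white Gaussian sensor noise (0.003 g default) below the count dead band.

The three default profiles grade bout rate, amplitude and smoothness
corner downward, and center frequency and tremor fraction upward, from
healthy control → ambulatory DMD → non-ambulatory DMD. The numeric values
are this package's own calibration with two anchors: the downstream
ten-variable ordinal pattern across the three groups, and healthy-control
counts-per-minute on a 48 h wear landing in the clinically reported
interquartile band (≈ 4300–5200 CPM). No further distributional fidelity
is claimed or asserted: in particular, absolute entropy values of the
synthetic series sit well below clinically reported magnitudes (the
generator's bout envelopes are more predictable and heavier-tailed than
real behaviour), and only the *ordering* of entropy across groups is a
design target. Passing cohort tests therefore demonstrate that the
pipeline preserves group-graded structure of this kind, not that the
generator reproduces real wrist-wear distributions.

Cohort designs default to the clinical wear protocol (72 h controls,
7-day DMD wears, 1–3 annual visits, a fraction of ambulatory participants
transitioning at a later visit). Tests and examples use shortened wear
periods (hours rather than days) and single visits so full
simulate-and-extract passes stay fast; the ordinal pattern is robust to
wear duration. All randomness flows from a single integer seed through
`numpy.random.SeedSequence` spawning, so a fixed design is byte-identical
across runs, including written CSV files.

## Numerical and edge-case decisions

* Epoch grids align to the trace start; trailing partial epochs are
  discarded. Per-axis 15 s counts equal the sum of their fifteen 1 s
  counts exactly; vector magnitudes obey norm-of-sums ≤ sum-of-norms, so
  VM consistency across grids is a bounded inequality, not an identity.
* The busiest-hour search rounds sliding sums to 6 decimals before argmax
  so floating-point dust cannot break earliest-window tie-breaking.
* Sample entropy is computed from a single pairwise point-match matrix
  with shifted-diagonal ANDs — bitwise identical to direct pair counting
  (verified against a brute-force oracle to 10⁻⁹) but O(n²) in memory
  rather than O(n²·m) in time.
* Readers validate rather than coerce: malformed headers, ragged rows,
  NaN samples, duplicate participant/visit pairs, controls marked
  non-ambulatory, and dangling file references all raise errors naming
  the offending line.

## Known limitations

* No wheelchair/assistive-device motion, device non-wear, bilateral wear,
  or wake/sleep sub-analysis is simulated or modelled.
* The generator's circadian structure is a fixed binary sleep window; real
  activity has graded diurnal rhythm.
* The count-conversion stage approximates a proprietary algorithm from its
  three published response characteristics only; absolute count scales are
  calibrated, not device-validated.
* Ambulatory status is binary; no staging within ambulatory or
  non-ambulatory phases is represented.
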