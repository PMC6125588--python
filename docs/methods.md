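# Methods

This note records the models, numerical choices and assumptions behind
`psap`, and what the synthetic-data tests do and do not demonstrate.

## Sensor model and frame alignment

Each sensor reports specific force (m/s², gravity included) and angular
velocity (deg/s) at 100 Hz. Body-worn sensors are never mounted flush
with anatomical axes, so every recording is rotated into a common
pelvis-aligned frame (X anterior, Y leftward, Z up) before any metric is
computed.

Tilt (roll/pitch) is estimated from the mean accelerometer vector over a
static calibration window — the protocol's "stand still and count to
five" — as the shortest-arc rotation taking that vector onto +Z. The
window must span ≥ 1 s with gyro RMS < 5 deg/s (configurable); the
calibration instant is the window midpoint. Yaw is pinned to zero:
heading is unobservable from the accelerometer, and the magnetometer is
deliberately not trusted (indoor steel environments distort the field).
All downstream metrics are heading-invariant once every site shares the
pelvis frame, so this loses nothing. When device orientation
quaternions are present they are used instead: the site-to-pelvis
relative rotation is taken from the quaternions at the calibration
instant and the pelvis tilt from its static accelerometer.

The alignment is fixed for the whole trial (no continuous re-estimation
during movement). Free acceleration = R·a_sensor − (0, 0, g) with
g = 9.80665 m/s² exactly.

## Displacement by filtered double integration

Double integration of accelerometer noise and residual bias diverges, so
a zero-phase (forward–backward) 4th-order Butterworth high-pass at
0.1 Hz is applied before each integration stage and once after the
second (three passes total). Body sway at 0.3–1 Hz passes essentially
unattenuated (gain > 0.999 at 0.5 Hz) while drift is rejected. Defaults
`hp_order=4`, `hp_cutoff_hz=0.1`, `edge_trim_s=1.0` are configurable;
the first/last second of each scored phase is trimmed to keep filter
transients out of the metrics. The residual mean of the final curve is
subtracted (zero-phase high-passing leaves a small edge-effect offset).

The displacement area is ∫|x(t)| dt (trapezoid) — sway oscillates about
zero, so a signed area would cancel. Phases are half-open [start, end),
so the final sample contributes no area; at 100 Hz this is a 0.5 %
effect at most.

Two caveats established during development:

- The noise floor of this chain is not negligible: white accelerometer
  noise just above the 0.1 Hz cutoff is amplified by ~1/ω⁴, giving
  zero-motion displacement areas of order 0.5 cm·s at realistic sensor
  noise over a 15 s walk — one to two orders of magnitude below
  centimetre-scale sway signals, but not zero.
- An abruptly switched-on sinusoid leaves a long (~10 s) low-frequency
  transient after high-passing. Amplitude recovery is therefore measured
  by quadrature projection at the known frequency in analytic tests, and
  by √2·SD over the envelope-flat interior for generated (smoothly
  ramped) sway.

## Toe-off detection and DTW gait regularity

Sagittal shank angular velocity (rotation about the aligned ML axis)
shows one dominant peak per stride during tandem walking. Events are
peaks of the 6 Hz low-passed signal with prominence
≥ max(20 deg/s, 0.3·(max − median)) and separation ≥ 0.6 s (tandem gait
is slow; the refractory period suppresses double peaks). A flat signal
yields no events rather than an error.

Strides are the half-open intervals between consecutive events;
≥ 3 strides (4 events) are required. Each stride is linearly resampled
to 100 points; the template is the pointwise mean (pointwise SD is kept
for band plots). First and last strides are retained by default
(`exclude_boundary_strides` flips this). The template is built per
trial.

DTW is computed by dynamic programming over the local cost |a_i − b_j|
with steps (1,1), (1,0), (0,1) and full boundary conditions, no band
constraint. Ties prefer the diagonal, then the step along the first
argument, making the path deterministic. The reported distance is
accumulated cost divided by warping-path length, so it keeps deg/s
units; the un-normalized cost is available (`normalize_dtw=False`).
Correctness is pinned to two independent oracles in the tests: a
top-down recursive formulation and full enumeration of every monotone
warping path on short sequences.

Per foot, regularity = mean, sample SD (ddof 1) and range of the
per-stride distances to the template.

## Postural sway

ML and AP displacement reuse the double-integration chain. Over the
quiet-stand phase: path length = Σ√(Δml² + Δap²); total area = convex
hull of the (ml, ap) cloud (degenerate clouds → 0), with a 95 %
prediction-ellipse area (π·χ²₂,₀.₉₅·√det Σ) as a config alternative;
excursions = per-axis peak-to-peak. Sway is scored on displacement (not
raw acceleration) for unit coherence (cm, cm²). Phases shorter than 5 s
are rejected.

## SNOW jerk and sample entropy

Jerk is computed on free acceleration (gravity must not contribute)
after a 5 Hz low-pass, by central differences; the cost is
∫(j_x² + j_y²) dt (horizontal) and ∫j_z² dt (vertical) over the write
phase. A duration-normalized (mean-square) variant is available.
Sample entropy uses the Richman–Moorman convention: B counts unordered
pairs of m-length templates within Chebyshev tolerance r among the
first n−m templates, A the same for m+1; SampEn = −ln(A/B), +∞ when
A = 0, an error when B = 0. Defaults m = 2, r = 0.2·SD of the analyzed
series, which makes the result invariant to affine rescaling. Entropy
is computed on acceleration — the signal closest to the sensor, with no
integration drift — horizontally on √(a_x² + a_y²) and vertically on
a_z; the parameters are recorded with every result.

## Longitudinal statistics

Per (cohort, test, condition, variable): Pearson r of the pooled
(subject, session) values against days elapsed (session index behind a
flag), p from the t transform. Where p ≤ α (0.05), a one-way
within-subject ANOVA across sessions on complete cases
(SS_total = SS_subject + SS_session + SS_error,
F = MS_session/MS_error on (k−1, (k−1)(n−1)) df; Greenhouse–Geisser
correction behind a flag, off by default). Where that is significant,
Fisher's LSD: all pairwise t = Δmean/√(2·MS_error/n) on the error df,
two-sided, uncorrected — that is what LSD means. Missing data: pairwise
deletion for correlation, complete-case for the ANOVA. No multiplicity
control across variables. A mixed-model analysis is explicitly out of
scope.

## Synthetic-data generator

All generators build ground-truth kinematics first, then render them
through a rigid-body sensor model: world acceleration is the numerical
second derivative of truth position (so forward generation and inverse
double-integration analysis are mutually consistent by construction),
gravity is added, the result is rotated into a fixed tilted sensor
frame (rotation about a random horizontal axis — no yaw, so the static
tilt estimate recovers it exactly), and white sensor noise is appended.
One seeded generator per call makes every output bit-reproducible.

Defaults and what they emulate:

- **Tandem**: 12 strides of 1.25 s; sagittal swing = raised-cosine
  pulses (smooth, analytic derivatives) of 200 deg/s peak, alternating
  feet at half-period offset; timing/amplitude jitter as fractions of
  period/peak. Upper-body ML sway = 0.5 Hz sinusoid with smooth 1 s
  on/off ramps, 3 cm at the trunk (head ×1.2, pelvis ×0.5 — the head
  and trunk compensate for the constrained lower body while the pelvis
  guards the centre of mass). 3 s static lead-in is the calibration
  phase.
- **Prone-to-stand**: quiet-stand ML/AP position = 0.3 Hz low-passed
  Gaussian noise scaled to the requested stationary SD (0.5 cm
  default); a smooth 5 cm anterior excursion renders the stand-up. The
  prone phase is shortened to 10 s — enough for calibration without
  simulating the protocol's full 2 min rest — and a 5 s settle gap
  separates the transition from the scored stand so the high-pass
  transient of the stand-up (which spreads over ~10 s) stays out of the
  scored window.
- **SNOW**: the foot traces a cubic spline through fixed S-N-O-W
  control points (module constants, 15 cm letter height) in the
  ML-vertical plane at constant speed with 0.5 s ramps over 16 s;
  tremor = 4–8 Hz band-limited noise of the requested RMS added to the
  acceleration during the write phase.
- **Sensor noise**: 0.003 m/s² and 0.1 deg/s per sample — the quiet end
  of the output noise observed from commercial strapdown-filtered IMUs.
- **Cohort table**: each cell is the mean of 3 trial-level draws
  (matching the protocol's three trials per condition) with trial noise
  SD 1; per-subject baselines spread with SD 0.2 (the pooled-correlation
  analysis assumes subjects share a metric scale); crew trend = the
  requested multiple of the trial noise SD over the full stay, linear in
  days {0, 2, 13, 14}; controls get zero trend over days {0, 3, 6, 8}.
- **Mission**: crew severity grows linearly with days (sway amplitude,
  stride jitter, writing tremor; eyes-closed ×1.5), controls stay at
  baseline; controls perform the tandem walk only, as in the protocol.
  Problem sizes for the shipped end-to-end run: 10 crew + 5 controls,
  4 sessions, 2 tandem trials per vision condition, 10 strides per
  trial, 30 s stands — a deliberately scaled study that keeps a full
  run around a minute.

What passing tests show — and do not. The generator reproduces the
*statistical structure* the analysis assumes: periodic stride trains
with controllable irregularity, band-limited sway of known amplitude,
smooth letter traces with controllable tremor, fixed mounting tilt,
white sensor noise, and linear cohort trends. It does not model soft
tissue artifact, sensor repositioning between sessions, turning steps,
non-stationary fatigue within a trial, magnetometer disturbance, or
correlated (random-walk) sensor bias. Recovery of truth under the
generator therefore validates the signal-processing chain and the
statistics, not claims about any particular human population.

## Known limitations

- Alignment is calibration-instant only; slow sensor migration during a
  trial is not tracked.
- The pooled Pearson analysis ignores within-subject correlation; it is
  mildly conservative when between-subject spread is large.
- DTW distances depend on the resampling length (100) and the
  path-length normalization; values are comparable within a
  configuration, not across different ones.
- Sample entropy is reported as +∞ when no (m+1)-template pair matches;
  cohort aggregation treats such trials as missing.
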