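# Methods

This note documents the models, conventions, numerical choices and
limitations of `lumbokin`. It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## Conventions

**Quaternions** are scalar-first `(w, x, y, z)`, Hamilton product,
passive sensor-to-global rotations; streams are validated to unit norm
within 1e-3 (renormalized thereafter, but only when meaningfully
off-unit so that file round-trips stay bit-exact).

**Anatomical axes** (rows of every alignment matrix): X longitudinal
(superior), Y mediolateral oriented so flexion is a positive rotation,
Z = X × Y anteroposterior. The Euler decomposition is
`R = R_X(α) · R_Z(γ) · R_Y(β)` (sagittal/frontal/transverse clinical
order): α axial rotation, γ lateral bend (range-limited to ±90°),
β flexion/extension. Closed form: `γ = −asin R₀₁`,
`α = atan2(R₂₁, R₁₁)`, `β = atan2(R₀₂, R₀₀)`; the reconstruction
`R_X(α)R_Z(γ)R_Y(β)` matches the input to < 1e-9 away from gimbal lock.
Within 0.1° of |γ| = 90° the decomposition is flagged and the residual
rotation is assigned to α (β forced to 0) — an arbitrary but documented
tie-break; physiologic trunk lateral bend never approaches this
configuration.

Internally, left axial rotation, left lateral bend and flexion are all
positive. Reported tables use the field's conventions via one sign-map
table (`conventions.REPORT_SIGN`): spinal AR left negative, LB left
positive, spinal flexion negative; the hip pair carries the opposite
multiplier of the spinal pairs in every family. The hip/L5 pair is
reported in the reference frame of the femur sensor, whose functional
calibration (thigh lift) defines its mediolateral axis with opposite
polarity to the spinal sensors; relative angles are unaffected because
the neutral reference cancels any constant factor on the reference-side
frame, and the sign map realizes the reporting convention.

**Units**: seconds, degrees, deg/s, deg/s², accelerometer in g.
Unwrapping works on the 360° period; processing order is decompose →
unwrap → filter.

## Filtering

All angle and gyro channels use a zero-phase (forward–backward)
third-order Butterworth low-pass, cutoff 5 Hz at 62.5 Hz sampling
(`scipy.signal.filtfilt`). The effective magnitude response is the
squared single-pass response; at 1 Hz the measured gain is ≥ 0.9998 with
zero lag, at 15 Hz the digital filter passes ≤ 4.2e-4 of the amplitude —
somewhat below the analog approximation 1/(1+(15/5)⁶) ≈ 1.4e-3, because
the bilinear transform attenuates faster near Nyquist. Series must
exceed the filter's padding length (12 samples) or `TooShort` is raised.

## Alignment

The calibration choreography is: stomp, 10 s quiet standing, forward
bend, 10 s quiet standing, right thigh lift. Detection rules:

* **Stomp**: first sample on any sensor where |‖accel‖ − 1 g| exceeds
  2 g (configurable); all streams crop to that sample.
* **Quiet window**: longest span ≥ 2 s where the 0.4 s-smoothed gyro
  magnitude stays below max(3 deg/s, 1.5× the trial's own noise floor,
  estimated as the median smoothed magnitude — the calibration trial is
  mostly quiet standing). The adaptive floor keeps the detector working
  when gyro noise alone exceeds the fixed threshold.
* **Vertical axis**: normalized mean accelerometer direction over the
  quiet window (gravity reaction points superior); a mean norm below
  0.5 g is rejected as degenerate.
* **Mediolateral axis**: first principal direction (SVD) of the gyro
  samples in the sensor's own first movement window (bend for spinal
  sensors, thigh lift for the femur sensor — each is still during the
  other's event), signed so the initial rotation is positive; quality =
  fraction of gyro variance explained, rejected below 0.6.
* **Frame**: rows X = vertical, Z = normalize(X × Y_raw),
  Y = Z × X — the final cross product restores exact orthonormality;
  inputs within 10° of parallel are rejected.

With zero noise and random mounting offsets ≤ 15°, recovery is exact to
numerical precision; with gyro noise of 1/2/5 deg/s the median recovery
error grows monotonically (≈ 0.09/0.17/0.48°, computed by the test
suite over 100 seeds per level).

## Metrics

* Self-paced ROM: signed extremes of the (filtered, neutral-referenced)
  primary-axis series per the sign maps; total ROM = |left| + |right|
  (identically max − min).
* Functional ROM (CRF/5STS/PLS): per-repetition sagittal peaks →
  absolute values → plain mean.
* Velocity: filtered gyro rotated to the global frame through the fused
  orientation, differenced moving − reference, expressed in the
  reference sensor's anatomical frame. Acceleration: central differences
  of velocity (one-sided at the ends). Fast-paced summaries are
  20%-trimmed means (symmetric, `floor(0.2 n)` dropped per end;
  configurable) of per-repetition peak magnitudes.
* Peak extraction: `scipy.signal.find_peaks` with prominence defaults of
  5° (angles) and 5 deg/s (velocity), minimum separation a quarter of
  the expected repetition period, and a relative height floor of 25% of
  the largest peak — direction-change junctions otherwise register as
  small but topographically prominent extrema and would dilute the
  trimmed means.
* Screening: a trial is flagged when a summary leaves the editable
  physiologic-bounds table (`lumbokin/data/physiologic_bounds.csv`,
  seeded from published non-invasive lumbar ranges, e.g. flexion up to
  ~92° and extension up to ~56° per side), when bilateral sides differ
  by more than 3:1, or when the first excursion beyond 2° opposes the
  cued direction (left / flexion first). Flagged ROM is recomputed by
  the integrated method and labelled `method="integrated"`.
* Integrated ROM: each sensor's **raw** gyro is projected onto its own
  anatomical cued axis (a row of its constant alignment matrix), the
  moving − reference difference is integrated by the trapezoid rule, and
  ROM is max − min of the integral. The fused quaternion channel is
  never touched, so slow fusion drift cannot enter; on clean signals the
  two routes agree within 0.5°, and under 1 deg/s injected drift the
  integrated route stays within 1° of truth while the orientation route
  absorbs an error of the order of drift rate × trial duration.

## Lumbopelvic rhythm

Phases are segmented automatically from the summed lumbar + hip sagittal
signal (the study tradition is manual selection): each phase runs from
the last 2° crossing away from neutral to the following apex (prominence
5°). Within a phase, excursions are measured from the phase start; the
window opens at the first sample with hip excursion ≥ 1° and closes when
the later-peaking of the two regions reaches 98% of its own maximum
excursion. The per-sample ratio |lumbar| / max(|hip|, 1°) is averaged in
four equal-duration quartiles (`np.array_split`, boundaries within one
sample of exact quarters). Measuring excursion from the phase start —
not from the window onset — is what makes the 1° onset rule guarantee a
non-degenerate denominator throughout; with proportional trajectories
the ratio is recovered exactly in every quartile. A switch
(`incremental=True`) provides the per-sample-increment alternative
reading.

## Cohort summaries

Median and quartiles use linear interpolation between order statistics
(`np.percentile` default). Strata: total, male, female, age ≥ 60,
age < 60; sexes other than male/female stay in the totals only.
Normality is a one-sample Kolmogorov–Smirnov test against a normal with
the sample's own moments (n ≥ 8, non-constant); with estimated moments
this is the uncorrected (non-Lilliefors) variant, and the result is a
flag only — reported statistics are always median/IQR. Participant
accounting is plain arithmetic with negative results rejected.
`run_pipeline` processes a directory of trial files per participant
(SYNC required), logs and skips per-trial failures, and writes tidy
metrics, LPR and cohort-table CSVs; identical inputs reproduce identical
bytes.

## Synthetic rig

The body is a rotation chain femur → (hip joint) → L5 → (lumbar) → L1 →
(thoracic) → T1; the femur is fixed in the global frame except during
the thigh-lift calibration step. Joint trajectories are closed-form:
raised-cosine repetitions (so velocity and acceleration have analytic
forms), pure sinusoids (peak rate 2πfA, used by the analytic dynamics
checks), ramp-hold (the CRF rotation hold), or quiet. Default scripted
amplitudes per test were chosen once to sit near the cohort-scale
central values for each segment pair (e.g. self-paced F/E: hip 65°
flexion / 14° extension, lumbar 28/16°, thoracic 15/20°; 5STS hip 54°;
PLS hip 78° with a 20 s ceiling on four repetitions); self-paced
repetitions take 8 s, fast-paced 1.5 s, 5STS 2 s, PLS 4 s. Bilateral
movements go left first, then right.

Sensors observe their segment through a mounting offset (default: random
rotation ≤ 15°, drawn from the rig seed). The gyroscope reports the
exact angular velocity of the sensor frame plus white noise; the
accelerometer reports the gravity reaction in the sensor frame (plus a
4 g impulse at the stomp sample and white noise); the quaternion channel
reports the true orientation perturbed by per-sample orientation noise
and, optionally, a constant-rate drift about a fixed axis — emulating a
miscalibrated on-board fusion algorithm. Default noise magnitudes
(gyro 1 deg/s, orientation 0.5°, accelerometer 0.01 g) are plausible
consumer-IMU values, stated here as artifact choices: the study hardware
publishes no channel noise figures. `corrupt_stream` additionally
injects fusion drift, gyro bias or sample dropout into an existing
recording, deterministically under a seed.

Ground truth (angle series, relative angular velocities, event indices,
metric summaries, scripted lumbar:hip ratios) is derived from the script
alone and is identical across noise seeds.

**What the rig does not emulate** — soft-tissue artifact, magnetometer
behavior, sensor translation/linear acceleration during movement,
inter-repetition variability within a trial, and genuinely pathologic
movement strategies. Passing recovery tests therefore demonstrates the
correctness of the processing chain under the stated noise model, not
the clinical accuracy of any specific hardware.

## Problem sizes and calibration of the checks

The recovery suites use: all nine tests at zero noise (one rig seed),
100 seeds at gyro 1 deg/s + orientation 0.5° for the noisy ROM branch
(run on self-paced F/E, the richest multi-joint test), 100 seeds per
level for the alignment-noise monotonicity curve, 10⁵ rotations for the
Euler round trip, and a 200-participant draw for the cohort-median
convergence check. The cohort generator's lognormal sigmas are
calibrated a priori from the sample-median standard error
(1.2533 · median · σ / √n) so that 3·SE stays below the 1° tolerance of
that convergence check at n = 200; real cohort dispersion is
substantially wider (IQR/median ≈ 0.4), and per-participant variability
at that scale is exercised through the trial-level simulator instead.

## Known limitations

* Automated LPR phase segmentation and expected-movement screening
  replace human visual adjudication; thresholds are configurable but the
  defaults were not tuned against expert labels.
* The 98%-of-maximum LPR end rule is applied to the later-peaking of the
  lumbar and hip regions (an interpretation; "trunk movement" is
  ambiguous between the composite trunk and its regions).
* ROM for the fast-paced AR/LB/flexion tests is deliberately not
  computed (only velocity/acceleration are defined for them in the
  protocol's metric table).
* Resampling (slerp for quaternions, linear for vector channels) is the
  package's own repair policy for corrupted streams; the study reports
  such streams as unusable without describing a fix.
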