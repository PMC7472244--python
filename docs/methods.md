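# Methods

This note documents the models behind `margkin`, the parameters that
matter, the numerical choices, and what the built-in simulator does and
does not emulate.

## Conventions

Hamilton quaternions, right-handed, scalar-first `(w, x, y, z)`; a
quaternion maps the sensor (or segment) frame into the global frame, so
the columns of its direction cosine matrix are the sensor axes expressed
globally. Composition `a ⊗ b` applies `b` first. The global frame is
z-up with x along magnetic north — defined operationally from the
quasi-static initialization window of each recording (tilt from the mean
specific force, heading from the tilt-compensated calibrated field), so
every sensor fused against the same field lands in the same frame, which
is what makes per-segment orientations comparable when differenced into
joint rotations. All internal angles are radians; every reporting
boundary (CSV, JSON, printed output) uses degrees, seconds and meters.

Quaternions and DCMs are used throughout the processing chain; Euler
angles appear only at the reporting boundary. The default decomposition
for joint rotations is intrinsic **Y-X-Z** — sagittal axis first — so
flexion/extension is exact over ±180°. A sagittal-in-the-middle sequence
(e.g. Z-Y-X) clips at ±90° and cannot represent squat-scale knee flexion
(>120°); that is why sagittal-first is the default. The sequence is
configurable for users who need a different convention.

## Magnetometer calibration

Hard/soft-iron distortion is corrected by an ellipsoid-to-sphere fit:
the general quadric `mᵀM m + bᵀm = 1` is fitted to the raw readings by
linear least squares; the recentred shape matrix is factored through its
symmetric eigendecomposition into an SPD soft-iron correction normalized
to unit determinant, so the fitted field magnitude (reported in µT) is
the geometric-mean radius of the ellipsoid. Degenerate coverage is
rejected on two grounds: per-axis min–max spread below 10 µT, or a
near-planar point cloud (smallest principal extent < 5 % of the
largest) — both make the quadric ill-posed. The calibration cannot
increase the coefficient of variation of the field magnitude on its own
fitting set; this is asserted in tests.

## Processing configurations

Two named configurations drive both the pre-processing and the fusion
filter. The `DEF` tuning uses default-scale noise variances and no
gyroscope filtering; `TAF` uses tuned variances plus a 6th-order low-pass
Butterworth at 60 Hz on the gyroscope (only). Acceleration is never
filtered in either configuration.

| parameter | units | DEF | TAF |
|---|---|---|---|
| accelerometer noise variance | (m/s²)² | 1.92e-3 | 3.45e-4 |
| gyroscope noise variance | (rad/s)² | 9.14e-4 | 1.40e-6 |
| gyroscope offset drift | (rad/s)²/sample | 3.05e-13 | 1.77e-8 |
| magnetometer disturbance noise | µT² | 0.5 | 0.1 |
| linear-acceleration compensation factor | – | 0.5 | 0.9 |
| expected magnetic field strength | µT | 50.0 | from calibration |

The Butterworth stage is applied forward–backward (`sosfiltfilt`): the
passband/stopband behavior is that of two order-6 passes and the phase
delay is zero, which matters because gait-event timing is derived
downstream from the same streams. The magnetometer (sampled at a tenth
of the IMU rate) is placed on the IMU time base by linear interpolation
with held endpoints — a smoothness assumption appropriate for a 112.5 Hz
measurement of a slowly varying field. Out-of-range samples are clipped
to the sensor range and counted, not dropped, to preserve the uniform
time base.

## Orientation: error-state Kalman AHRS

The nominal quaternion is propagated each sample by the bias-corrected
gyro increment. The error state is 9-dimensional: attitude error (sensor
frame, rad), gyro-bias error (rad/s), and linear-acceleration error
(global frame, m/s²). Process noise maps directly from the table above:
gyro noise × dt² drives attitude, offset drift drives the bias random
walk. Measurement updates run at every sample:

* accelerometer: predicted specific force `Rᵀ(g ẑ + a_lin)`; the
  innovation Jacobian couples attitude error through `[f̂]×` and the
  linear-acceleration error through `Rᵀ`, with the accel noise variance
  as measurement noise;
* magnetometer: predicted field `Rᵀ m_ref`; measurement noise is the
  disturbance variance plus a small instrument-noise floor (0.1 µT²).

The **compensation factor** `c ∈ [0,1]` governs linear-acceleration
handling in two coupled ways: it is the per-sample decay of the
linear-acceleration state (`a ← c·a`), and it scales that state's
process noise — a baseline `σ_la²·c²` (σ_la² = 0.5 (m/s²)² default) plus
an adaptive term `c² · max(0, ‖y‖²/3 − σ_acc²)` injected when the
accelerometer innovation energy exceeds its noise floor. The adaptive
term is what shields attitude during dynamics: innovation energy that
cannot be explained by sensor noise is attributed to body acceleration
in proportion to `c²`, while quasi-static samples keep full-strength
gravity corrections. At `c = 0` linear-acceleration compensation is off
and dynamic accelerations corrupt attitude directly (tens of degrees RMS
on a fast squat); at the operating values (0.5, 0.9) attitude error
stays a few tenths of a degree. One honest caveat: error is *not*
strictly monotone in `c` over the full range — protection saturates at
small `c` and very large `c` pays a small covariance-inflation penalty —
so the tested property is the on/off contrast at the operating values,
not monotonicity across a grid.

Initialization assumes the first 0.5 s quasi-static: attitude from the
mean specific force, heading from the mean calibrated field, gyro bias
from the mean rate (only when the window is plausibly static, all rates
< 0.2 rad/s). Covariance starts at (0.01 rad)² attitude, (0.05 rad/s)²
bias. A `gyro_only` mode disables all corrections and bias handling for
drift demonstrations. Near-zero specific force (free-fall artifacts) is
flagged per-sample as degraded confidence rather than repaired.

The filter equals pure gyro integration to <0.01° over 10 s when the
measurements agree exactly with the propagated state, holds a static
pose to <0.1° indefinitely, and with corrections enabled holds attitude
under a 0.01 rad/s gyro bias to <1° where open-loop integration drifts
by ~34° per minute.

## Sensor-to-segment alignment and joint angles

The calibration instant is the first sample of the first ≥0.25 s window
with foot-gyro magnitude < 0.1 rad/s — not literally sample zero, for
robustness to start-of-recording transients. At that instant the foot
sensor's x-axis is assumed anterior/posterior; its horizontal projection
(rejected if within 5° of vertical) and the global vertical define a
single right-handed segment frame assigned to all four segments (the
aligned-pose assumption of a minimal-modeling calibration). Each
segment's constant alignment transform, per-sample orientation and joint
rotation follow the three-equation chain in the README; the chain is
algebraically exact (1e-9 on random configurations) because the mount
offsets cancel identically.

Joints are fixed (proximal, distal) pairs: hip = (pelvis, thigh), knee =
(thigh, shank), ankle = (shank, foot). Sign convention: hip flexion and
ankle dorsiflexion positive; the knee's sagittal sense is negated so
knee flexion also reads positive. Repetitions are segmented by peak
prominence on the flexion trace (defaults: prominence ≥ 20°, peaks ≥ 1 s
apart, windows bounded by adjacent minima); ROM = max − min flexion per
window, reported per repetition and as mean ± SD.

Because the calibration frames are anchored to gravity, ROM is invariant
under global rotations about the vertical (tested), but **not** under
arbitrary global rotations — an arbitrary tilt invalidates the vertical
anchor the construction depends on. Misaligning the assumed calibration
frames propagates multiplicatively down the chain; tests assert that
joint-angle bias grows with injected calibration error.

## Gait events, timing, and ZUPT stride length

A movement-intensity envelope combines the deviation of the
specific-force magnitude from gravity with two gyro terms (scaled by g):
a slow-baseline-removed term (2 s double moving average subtracted, so a
drifting gyro bias cannot masquerade as movement) and an absolute-rate
term with a 0.25 rad/s deadband (so sustained fast rotation still
registers). The envelope is smoothed by a zero-phase 10 ms double moving
average. Stance = envelope < 0.5 m/s²-equivalent for ≥ 0.1 s; swing =
the gap between stances (≥ 80 ms); FC is the last still sample before
swing onset and IC the first still sample after it. Each event carries a
confidence score from the swing's envelope margin over threshold —
deliberately low for timid swings, where contact identification on a
heel-mounted sensor is genuinely ambiguous. Stride time is consecutive
IC-to-IC; stance time is IC to the next FC within the stride.

Stride length: specific force is rotated to the global frame with the
fused orientation, gravity subtracted, and velocity integrated with the
trapezoidal rule. Each detected stance is a known instance of zero
velocity. Two drift corrections are implemented: a per-stride
closed-form linear de-drift (interpolating the stance-to-stance velocity
error), and the default error-state Kalman tracker over the
accelerometer-bias error, updated by each stride's zero-velocity
pseudo-measurement and applied retroactively over that stride (a
fixed-interval smoothing pass, so the two methods agree to <0.01 m on
constant-bias scenarios — the linear form is the brute-force oracle in
the tests). Stride length is the horizontal displacement magnitude
between consecutive stance midpoints; a unit direction-of-travel vector
(e.g. from the initial pelvis heading) can be supplied to report the
projected displacement instead.

With a deliberately injected 0.05 m/s² accelerometer bias and true
orientations, uncorrected stride error grows without bound (≈1 m by
stride 20 at shuffle-walk cadence) while the corrected error stays below
a millimeter-to-centimeter scale — the mechanism the ZUPT exists for.

## Agreement statistics

Differences are **reference − test** throughout, so a positive
Bland–Altman bias means the test method underestimates (conventions vary
between papers; this one is fixed and asserted in tests). Limits of
agreement are bias ± 1.96 SD of the differences; normality is gated by
Shapiro–Wilk at α = 0.05, and on failure the analysis is recomputed on
log-differences (unitless, flagged). MAPE is classified excellent
(≤5 %), good (≤10 %), acceptable (≤15 %), unacceptable (>15 %), with
inclusive upper boundaries; its SD is across observations. RMSE over ROM
comparisons is computed over per-repetition ROM values (not pooled
time-series samples). E₁₀ counts samples with |error| ≤ 10 % of the
reference ROM, boundary inclusive. Time-series synchronization is
automated: the test trace is anti-alias resampled to 100 Hz
(`resample_poly` with the exact 4/45 ratio) and shifted so the flexion
maxima coincide; the recovered offset is exposed for audit rather than
performed by hand.

## The simulator: what it emulates, and what it does not

`simdata` generates C² joint trajectories (raised-cosine squat cycles;
swing-confined cycles for gait), composes segment orientations down the
chain, and synthesizes sensors at arbitrary seeded mounting offsets —
an identity mount would let alignment bugs cancel silently, so mounts
are randomized by default (the foot sensor keeps its anterior/posterior
x-axis, varying only in roll, matching its deliberate placement).
Squat-family sensor positions follow a fixed-length segment chain
pivoting about the planted ankle, so thigh and shank sensors experience
genuine linear acceleration (several m/s² at default cadence); gait
moves the foot through minimum-jerk swing arcs with exact zero-velocity
stance dwells and advances the pelvis smoothly. Angular velocity comes
from central differences of the orientation sequence (O(h²) at 1125 Hz,
negligible against modeled noise); linear acceleration from double
`np.gradient` of position; accelerometer streams are sensor-frame
specific force, magnetometer streams the rotated Earth field (50 µT,
60° inclination) with optional hard/soft-iron distortion, decimated ×10.
Noise: white accelerometer/gyroscope/magnetometer noise at the
configuration variances, gyro bias random walk at the drift variance,
optional constant accelerometer bias. Everything is bit-reproducible per
seed. Default motion parameters are the study conditions: squat-family
joint excursions at the reference-system means (hip 96.8°, knee 121.2°,
ankle 31.2° for the squat), shuffle-walk at 0.339 m / 0.846 s / 0.568 s
and bear-crawl at 0.515 m / 1.912 s / 1.502 s; squat cycle duration
(2.5 s) and stride counts are package choices at realistic scales.

Deliberately not emulated: heel-strike impact transients (contacts are
identified from the stance/swing stillness boundary, not an impact
ring — the accelerometer stream stays exactly consistent with the
position truth, which the integration tests rely on); soft-tissue
artifact; marker-level optics (the 100 Hz reference is the decimated
truth plus optional white noise and dropout); musculoskeletal dynamics;
spatially varying magnetic disturbance during a trial. Passing tests
therefore demonstrate correctness of the estimation chain under the
modeled error sources, not performance on real recordings — in real
data, impact transients, tissue wobble and indoor field gradients are
the dominant additional error sources, and reported real-world ROM
errors are degrees rather than the tenths of degrees seen here.

## Numerical choices and degenerate inputs

* Quaternions are renormalized after every product; canonicalization
  fixes `w ≥ 0`. DCM→quaternion uses Shepperd's maximal-pivot method.
* Near gimbal lock the Euler reporting path emits a warning rather than
  failing; internal processing never passes through Euler angles.
* The fusion inner loop is plain float64 with 9×9 covariance algebra,
  JIT-compiled by numba when available (pure-Python fallback otherwise);
  covariance is re-symmetrized each step and verified PSD after 10⁵
  random-input steps.
* Stance windows in the simulator are rounded inward so every labeled
  sample is exactly still; event detection tolerances are therefore
  meaningful at the millisecond scale.
* Degenerate inputs rejected with diagnostics: near-planar magnetometer
  coverage, cutoff ≥ Nyquist, foot x-axis near vertical, empty
  magnetometer stream, non-monotone or >1 %-jittered time stamps,
  windows outside series bounds, zero reference values in MAPE (excluded
  per pair), non-positive values under the Bland–Altman log transform.

## Problem sizes used in tests and the acceptance script

Simulated trials are kept at realistic but modest sizes: squat trials of
5 repetitions (~14 s at 1125 Hz), gait trials of 10–20 strides, 5 seeds
for stochastic claims, 60 s static runs for drift demonstrations. These
sizes give stable statistics while keeping the whole suite fast on a
single CPU.

## Known limitations

* Sagittal plane only: frontal/transverse angles are representable in
  the quaternion chain but not validated outputs.
* The aligned-pose calibration assumption is load-bearing; habitual
  out-toeing or a sloped calibration surface violates it and biases all
  downstream angles (tested qualitatively via injected misalignment).
* Heading observability rests entirely on the magnetometer; in a
  magnetically hostile environment the shared global frame degrades and
  inter-segment angles inherit the heading error.
* The FC detector is threshold-based; for modified gaits with gradual
  swing onset, FC confidence drops and stance time is the least reliable
  of the three spatiotemporal measures.
* The AHRS absorbs constant accelerometer bias as a small (~0.3°) tilt;
  this is invisible in joint angles (differences) but means the ZUPT
  stage sees bias only through orientation error, not directly.
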