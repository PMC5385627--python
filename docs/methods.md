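# Methods

## Model and assumptions

The pipeline estimates the *relative* orientation of a lower-back-worn
sensor — relative to an earth frame whose Z axis is the gravity direction
and whose heading is arbitrary — and detects turns purely from the yaw
component. The assumptions this rests on:

* The recording begins (or at least contains) a quasi-static phase, so that
  the accelerometer momentarily measures only the gravity reaction and the
  initial orientation can be aligned to it. If no 5-sample window with
  per-axis peak-to-peak below 0.2 m/s² exists anywhere, initialisation fails
  loudly rather than guessing: every downstream angle depends on it.
* Heading is unobservable with a 6DOF unit (no magnetometer, by design:
  magnetometers are unreliable indoors), so yaw is defined to start at 0 and
  only yaw *changes* are meaningful. That is sufficient, because turns are
  yaw excursions.
* Gyroscope bias is not calibrated out. A constant vertical bias `b`
  integrates into a linear yaw drift `b·t`; at realistic magnitudes
  (≲ 0.5°/s) this drift is orders of magnitude slower than turning dynamics
  and never qualifies as a turn (a 90° excursion would need 180 s, far above
  the 10 s duration ceiling). The drift test in the acceptance script
  verifies both the `b·t` model and the absence of false turns over 90 min.

### Attitude propagation

The sensor-to-global matrix has the global axes as rows expressed in sensor
coordinates, so `R v_sensor = v_global`. Initialisation sets row 3 to the
normalised mean stable-window acceleration; the X row is seeded with
`[1 0 0]` and orthogonalised via `Y = Z × X`, `X = Y × Z` (this cross-product
order yields det +1, i.e. a right-handed triad, and initial yaw exactly 0).
If gravity is numerically parallel to the X seed the seed falls back to
`[0 1 0]`.

Each gyro sample is applied as a Rodrigues axis-angle step with the
*normalised* axis `ω/‖ω‖` and angle `θ = ‖ω‖/f_s` — Rodrigues' formula
requires a unit axis; using raw rate components would give a non-orthogonal
matrix. The update is `R ← T(ω_G)·R` with `ω_G = R·ω_S`; the algebraically
identical body-frame form `R ← R·T(ω_S)` is implemented as a cross-check
(the test suite requires agreement to 1e-10 per sample). The sign convention
is right-handed: positive vertical rate increases yaw. The left/right label
is a separate, configurable mapping (see below).

Euler angles use the intrinsic Z-Y-X (yaw-pitch-roll) convention. Only yaw
is consumed downstream, and yaw is convention-stable for the near-upright
orientations a lower-back sensor sees; |pitch| > 89.9° is flagged as
gimbal-adjacent. Orthonormality is checked every 128 samples; drift beyond
1e-6 triggers an SVD projection onto SO(3) (logged — in practice the
per-step analytic matrices keep drift near 1e-11 even over 90-minute runs).

## Turning detection

Unwrapped yaw (seam jumps > 180° corrected by ±360°) is cut at direction
reversals into monotone pieces that tile the recording. Two boundary details
the reversal rule alone does not fix:

* **Quiet plateaus.** An *exactly* flat yaw run (zero rate, only possible in
  noise-free synthetic data) lasting ≥ `plateau_split_s` (default 0.1 s)
  becomes its own zero-magnitude piece, so the turns on either side keep
  their true start and end and same-direction turns separated by quiet
  stance stay separate events. Shorter flat runs — isolated zero-rate
  samples at profile junctions — attach to the preceding piece, breaking at
  the last flat sample when the direction reverses across them. On real or
  noise-injected data exact plateaus do not occur (integrated gyro noise
  reverses sign every few samples) and the rule reduces to plain reversal
  segmentation.
* **Recording edges** act as extrema: a turn in progress at the start or end
  of the recording is an eligible event rather than silently dropped.

**Hesitations.** A piece with duration < 0.5 s and |magnitude| < 10% of both
neighbours (each > 10°, same direction) merges its triple into one piece
spanning the full interval; the merged magnitude is the *net* yaw change
from start to end (not the sum of absolute sub-magnitudes). The scan repeats
left-to-right to a fixed point, so chains of hesitations collapse into one
turn deterministically. All four rule bounds are strict inequalities; the
turn-magnitude threshold itself is inclusive (≥ 90°).

**Direction.** The vertical (global-frame) angular rate is integrated over
the event by the trapezoid rule. Internally, positive yaw change equals a
positive integral by construction; the *label* mapping is configurable
(`direction_convention`), defaulting to positive → right. The absolute
left/right assignment depends on how the sensor is mounted and cannot be
verified without hardware; internal consistency (integral sign = yaw-excursion
sign for every accepted turn) is what the tests pin down.

No smoothing is applied before extrema detection: gyro integration already
low-passes the noise, and fidelity of the boundary placement matters more
than cosmetic smoothness.

## Validation statistics

Matching is greedy on |midpoint difference| among pairs that overlap or lie
within `match_tolerance` (default 2.5 s, covering the ±2.2 s limits of
agreement typical for human-annotated turn times); ties break toward the
earlier detected event, making the output deterministic. True negatives
have no natural unit for event detection, so the package defines one
explicitly: a maximal reference-quiet gap (≥ `duration_min`) containing no
false-positive midpoint. The definition is isolated in one function so that
alternatives (e.g. fixed windows) can be swapped; statistics that depend on
TN (specificity, accuracy, NPV, kappa) inherit whichever definition is used.
Statistics with zero denominators are reported as undefined, never as 0.
Full precision is kept internally; two-decimal rounding (half away from
zero) happens only at the report layer.

Bland–Altman uses detected-minus-reference *start* times (midpoint or end
differences would be equally defensible; start is implemented), reporting
mean, SEM = SD/√n and limits of agreement mean ± 1.96·SD.

## Synthetic data

The generator renders a scripted phase sequence into exact ground truth:

* Turn profiles are analytic (raised cosine by default, trapezoid optional),
  so each scripted magnitude is the exact integral of the angular-velocity
  profile. Hesitations insert brief opposite-sign dips inside the turn while
  preserving the net excursion exactly.
* The body-frame gyro is built from the exact per-sample yaw increments
  about the vertical, rotated through the static mounting tilt — because all
  increments share one axis, discrete strapdown integration of the
  noise-free channels reproduces the scripted yaw to rounding error, which
  makes recovery tolerances meaningful rather than estimator-limited.
* Noise model: constant gyro bias (default 0 in hand-built scripts;
  (0.05, 0.05, 0.1)°/s in the sensor-grade scenarios), white Gaussian gyro
  noise (0.5°/s), white accelerometer noise (0.05 m/s²). These are
  conservative consumer-IMU figures; the original hardware's noise spec is
  not public, so they are deliberately config-exposed.
* The realistic random script draws magnitudes ~N(155°, 25°) clipped to
  100–180° and durations ~N(2.4 s, 0.5 s) clipped to 1.2–4 s — centred on
  the mean turn magnitude (~155°) and duration (~2.4 s) reported for indoor
  daily-living turning — with 2–5 s of quiet stance between turns.

What the generator does **not** emulate: step impacts, trunk sway during
gait (an optional roll sinusoid exists but is off by default), large-radius
walking turns, or activities like driving. Passing tests on these fixtures
therefore demonstrates the correctness of the arithmetic — attitude
propagation, segmentation, merging, metrics, statistics — not the field
performance of the algorithm on real gait data.

### Expected recovery accuracy under noise

With sensor-grade noise, detected boundaries sit where the turn's angular
velocity emerges from the noise floor. A raised-cosine profile starts
quadratically slowly, so each boundary shifts inward by ~30–40 ms,
shortening detected durations by ~0.07 s on average while barely affecting
magnitudes (< 0.3° mean error). Recovery requirements are therefore stated
as aggregate (mean) errors over many turns, matching how method-comparison
differences are normally reported.

## Problem sizes and runtimes

The default test suite simulates ~35 min of total signal (the largest single
fixtures: 200 noisy turns ≈ 19 min, and one 90-min quiet drift run) and
completes in well under a minute; `scripts/acceptance.py` re-renders its
inputs from the seed and runs in ~10 s on one CPU. Propagation is a plain
per-sample Python loop (~10⁵ samples/s), which is ample for these sizes.

## Known limitations

* Heading drift is unmodelled and uncorrected (inherent to 6DOF sensing).
* Same-direction turns separated by *sub-plateau-threshold* pauses merge
  only via the hesitation rule; under heavy noise a hesitation shredded into
  micro-pieces may fail the neighbour conditions and split a turn (the
  optional pre-detection low-pass exists for such hardware).
* Turns slower than 10 s (large-radius walking turns) are rejected by design
  — the documented miss case, reproduced by the `wide-radius` scenario.
* The TN definition (and hence specificity/accuracy/kappa on real
  annotation sets) is a package convention, not a universal standard.
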