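"""Seeded synthetic 6DOF IMU generator for a lower-back-worn sensor.

A :class:`TurnScript` is a sequence of quiet-standing and turn phases. Each
turn has a scripted signed yaw excursion rendered with a smooth analytic
angular-velocity profile (raised cosine by default) that integrates exactly
to the scripted magnitude, optionally interrupted by brief opposite-sign
hesitation dips. The scripted yaw trajectory is composed with a static
mounting tilt into a full orientation trajectory; the gyroscope channel is
the exact body-frame angular rate plus a constant bias and white Gaussian
noise, and the accelerometer channel is gravity rotated into the sensor
frame plus white noise.

Because the body rates are derived from exact per-sample yaw increments
about a fixed vertical axis, strapdown integration of the noise-free
channels reproduces the scripted yaw to rounding error — ground truth is
exact, not estimated. The same seed always yields bit-identical output.

What is emulated: quiet-stance gravity alignment, scripted turn
magnitude/duration/direction, hesitations, gyro bias drift, sensor noise,
yaw wrap at ±180°. What is not: gait dynamics (step impacts, trunk sway is
optional and off by default), so detection results on these fixtures bound
the algorithm's arithmetic, not its behaviour on real walking data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .imu_io import ImuRecording, TurnEvent
from .turning import direction_label

__all__ = [
    "QuietPhase",
    "TurnPhase",
    "TurnScript",
    "RenderResult",
    "ScriptError",
    "render",
    "random_script",
    "scenario_suite",
    "SCENARIO_NAMES",
]

GRAVITY = 9.81


class ScriptError(ValueError):
    """Raised for scripts that violate generator preconditions."""


@dataclass(frozen=True)
class QuietPhase:
    """Quiet standing: zero angular rate for ``duration`` seconds."""
    duration: float


@dataclass(frozen=True)
class TurnPhase:
    """One scripted turn.

    ``magnitude_deg`` is the signed net yaw excursion (positive increases
    yaw); ``hesitations`` is a list of ``(offset_fraction, dip_deg,
    dip_duration_s)`` triples — each inserts a brief opposite-direction dip
    of ``dip_deg`` degrees at the given fraction of the forward excursion,
    inside the stated total duration. The net excursion stays exactly
    ``magnitude_deg``.
    """
    magnitude_deg: float
    duration: float
    profile: str = "raised-cosine"
    hesitations: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self):
        if self.duration <= 0:
            raise ScriptError("turn duration must be positive")
        if self.profile not in ("raised-cosine", "trapezoid"):
            raise ScriptError(f"unknown profile {self.profile!r}")
        t_dips = sum(h[2] for h in self.hesitations)
        if t_dips >= self.duration:
            raise ScriptError("hesitation dips exceed the turn duration")
        for f, dip, dur in self.hesitations:
            if not 0 < f < 1 or dip < 0 or dur <= 0:
                raise ScriptError(f"invalid hesitation {(f, dip, dur)}")


@dataclass(frozen=True)
class TurnScript:
    """Full specification of one synthetic recording.

    Noise defaults are conservative consumer-IMU figures (the sensor-grade
    condition used throughout the tests): gyro white noise 0.5°/s RMS per
    sample, accelerometer white noise 0.05 m/s², and a small constant gyro
    bias. Set the noise fields to zero for analytically exact fixtures.
    """
    phases: tuple = ()
    tilt_deg: float = 10.0                      # static mounting inclination about sensor x
    gyro_bias_dps: tuple[float, float, float] = (0.0, 0.0, 0.0)
    gyro_noise_sd_dps: float = 0.0
    accel_noise_sd: float = 0.0                 # m/s²
    sway_amplitude_deg: float = 0.0             # optional roll sway sinusoid
    sway_freq_hz: float = 0.25
    fs: float = 128.0
    seed: int = 0
    direction_convention: str = "positive_right"

    def __post_init__(self):
        if not self.phases:
            raise ScriptError("script needs at least one phase")
        first = self.phases[0]
        min_quiet = 5 / self.fs + 0.1
        if not isinstance(first, QuietPhase) or first.duration < min_quiet:
            raise ScriptError(
                f"first phase must be quiet for >= {min_quiet:.3f} s so the "
                "gravity alignment window exists"
            )

    @property
    def total_duration(self) -> float:
        return sum(p.duration for p in self.phases)

    def truth_events(self) -> list[TurnEvent]:
        """Exact scripted turns as reference annotations."""
        events = []
        t = 0.0
        for p in self.phases:
            if isinstance(p, TurnPhase):
                events.append(TurnEvent(
                    t_start=t, t_end=t + p.duration,
                    magnitude=abs(p.magnitude_deg),
                    direction=direction_label(p.magnitude_deg,
                                              self.direction_convention),
                    source="reference",
                ))
            t += p.duration
        return events


@dataclass(frozen=True)
class RenderResult:
    recording: ImuRecording
    truth: list[TurnEvent]
    yaw_deg: np.ndarray        # exact scripted yaw at each sample
    script: TurnScript


# ---------------------------------------------------------------------------
# yaw trajectory construction
# ---------------------------------------------------------------------------

def _shape(u: np.ndarray, profile: str) -> np.ndarray:
    """Fraction of the excursion completed at normalised time u ∈ [0, 1]."""
    u = np.clip(u, 0.0, 1.0)
    if profile == "raised-cosine":
        return u - np.sin(2 * np.pi * u) / (2 * np.pi)
    # trapezoid: 10% ramps; plateau rate chosen so the integral is 1
    r = 0.1
    peak = 1.0 / (1.0 - r)
    out = np.empty_like(u)
    a = u < r
    b = u > 1 - r
    m = ~(a | b)
    out[a] = 0.5 * peak * u[a] ** 2 / r
    out[m] = 0.5 * peak * r + peak * (u[m] - r)
    out[b] = 1.0 - 0.5 * peak * (1.0 - u[b]) ** 2 / r
    return out


def _turn_pieces(p: TurnPhase) -> list[tuple[float, float]]:
    """Split a turn into (displacement_deg, duration_s) sub-pieces.

    Forward pieces carry the excursion between hesitations; each hesitation
    contributes a dip piece of opposite sign. The pieces sum exactly to
    (magnitude_deg, duration).
    """
    sgn = 1.0 if p.magnitude_deg >= 0 else -1.0
    dips = sorted(p.hesitations)
    dip_total = sum(h[1] for h in dips)
    forward_total = abs(p.magnitude_deg) + dip_total
    t_forward = p.duration - sum(h[2] for h in dips)
    fracs = [0.0] + [h[0] for h in dips] + [1.0]
    pieces: list[tuple[float, float]] = []
    for k in range(len(fracs) - 1):
        share = fracs[k + 1] - fracs[k]
        if share < 0:
            raise ScriptError("hesitation offsets must be ascending")
        if share > 0:
            pieces.append((sgn * share * forward_total, share * t_forward))
        if k < len(dips):
            _, dip, dur = dips[k]
            pieces.append((-sgn * dip, dur))
    return pieces


def _yaw_trajectory(script: TurnScript, t: np.ndarray) -> np.ndarray:
    """Exact scripted yaw (degrees) evaluated at the sample times."""
    starts, durs, bases, deltas, profiles = [], [], [], [], []
    t0, base = 0.0, 0.0
    for p in script.phases:
        if isinstance(p, QuietPhase):
            starts.append(t0); durs.append(p.duration)
            bases.append(base); deltas.append(0.0); profiles.append("raised-cosine")
            t0 += p.duration
        else:
            for delta, dur in _turn_pieces(p):
                starts.append(t0); durs.append(dur)
                bases.append(base); deltas.append(delta)
                profiles.append(p.profile)
                t0 += dur
                base += delta
    starts_arr = np.asarray(starts)
    yaw = np.full(len(t), base)   # samples beyond the last phase hold the end value
    idx = np.clip(np.searchsorted(starts_arr, t, side="right") - 1, 0, len(starts) - 1)
    for k in range(len(starts)):
        sel = idx == k
        if not sel.any():
            continue
        if deltas[k] == 0.0:
            yaw[sel] = bases[k]
        else:
            u = (t[sel] - starts[k]) / durs[k]
            yaw[sel] = bases[k] + deltas[k] * _shape(u, profiles[k])
    return yaw


def _rot_x(angle_rad: float) -> np.ndarray:
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def render(script: TurnScript) -> RenderResult:
    """Render a script into an IMU recording plus exact ground truth.

    The noise-free gyroscope is constructed from the exact per-sample yaw
    increments (so discrete strapdown integration reproduces the scripted
    yaw), rotated into the sensor frame through the static mounting tilt;
    bias and seeded Gaussian noise are then added. The accelerometer is
    gravity in the sensor frame plus seeded Gaussian noise.
    """
    fs = script.fs
    n = int(round(script.total_duration * fs)) + 1
    t = np.arange(n) / fs
    yaw = _yaw_trajectory(script, t)

    tilt = _rot_x(math.radians(script.tilt_deg))   # sensor→global at yaw 0
    # body-frame rate producing exactly yaw[k+1]-yaw[k] per step about global z
    dpsi = np.zeros(n)
    dpsi[:-1] = np.radians(np.diff(yaw)) * fs
    gyro = np.outer(dpsi, tilt.T @ np.array([0.0, 0.0, 1.0]))

    if script.sway_amplitude_deg:
        # roll sway about the sensor x axis adds rate on gyro x only
        sway_rate = np.radians(script.sway_amplitude_deg) * \
            2 * np.pi * script.sway_freq_hz * \
            np.cos(2 * np.pi * script.sway_freq_hz * t)
        gyro[:, 0] += sway_rate

    accel = np.tile(tilt.T @ np.array([0.0, 0.0, GRAVITY]), (n, 1))

    rng = np.random.default_rng(script.seed)
    gyro = gyro + np.radians(np.asarray(script.gyro_bias_dps))
    if script.gyro_noise_sd_dps:
        gyro = gyro + rng.normal(0.0, math.radians(script.gyro_noise_sd_dps), (n, 3))
    if script.accel_noise_sd:
        accel = accel + rng.normal(0.0, script.accel_noise_sd, (n, 3))

    rec = ImuRecording(t=t, accel=accel, gyro=gyro, fs=fs)
    return RenderResult(recording=rec, truth=script.truth_events(),
                        yaw_deg=yaw, script=script)


# ---------------------------------------------------------------------------
# canned scenarios
# ---------------------------------------------------------------------------

def random_script(n_turns: int, seed: int, *,
                  noise: bool = True,
                  magnitude_range: tuple[float, float] = (100.0, 180.0),
                  duration_range: tuple[float, float] = (1.2, 4.0),
                  quiet_range: tuple[float, float] = (2.0, 5.0),
                  fs: float = 128.0) -> TurnScript:
    """A realistic daily-living-like script of ``n_turns`` random turns.

    Magnitudes center on ~155° and durations on ~2.4 s — typical figures for
    indoor turning — with alternating-plus-random directions and quiet
    standing between turns. With ``noise=True`` the sensor-grade noise model
    is applied (gyro 0.5°/s, accel 0.05 m/s², small constant bias).
    """
    rng = np.random.default_rng(seed)
    phases: list = [QuietPhase(3.0)]
    for _ in range(n_turns):
        mag = float(np.clip(rng.normal(155.0, 25.0), *magnitude_range))
        dur = float(np.clip(rng.normal(2.4, 0.5), *duration_range))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        phases.append(TurnPhase(sign * mag, dur))
        phases.append(QuietPhase(float(rng.uniform(*quiet_range))))
    kw = dict(
        gyro_noise_sd_dps=0.5, accel_noise_sd=0.05,
        gyro_bias_dps=(0.05, 0.05, 0.1),
    ) if noise else {}
    return TurnScript(phases=tuple(phases), fs=fs, seed=seed, **kw)


SCENARIO_NAMES = ("clean", "noisy", "hesitant", "wide-radius", "wrap")


def scenario_suite(seed: int = 0) -> dict[str, RenderResult]:
    """Canned named fixtures covering the algorithm's operating conditions.

    * ``clean`` — six noise-free turns (±90°…±180°, 1.5–2.5 s) with quiet
      standing between; exact recovery expected.
    * ``noisy`` — the same turns under sensor-grade noise and bias.
    * ``hesitant`` — parkinsonian-style turns, each interrupted by a 0.2–0.4 s
      dip of ~5% of the turn; merging must restore one event per turn.
    * ``wide-radius`` — very slow 180° turns (12 s, ~0.08 Hz), slower than the
      10 s duration ceiling: the algorithm's acknowledged miss case.
    * ``wrap`` — same-direction turns accumulating past ±180° so the wrapped
      yaw crosses the seam mid-turn.
    """
    turns = [(+90, 1.5), (-135, 2.0), (+180, 2.5), (-120, 2.0), (+150, 2.2), (-110, 1.8)]

    def alternating(specs, **kw):
        phases: list = [QuietPhase(3.0)]
        for mag, dur in specs:
            phases.append(TurnPhase(mag, dur, **kw))
            phases.append(QuietPhase(3.0))
        return tuple(phases)

    suite = {
        "clean": TurnScript(phases=alternating(turns), seed=seed),
        "noisy": TurnScript(
            phases=alternating(turns), seed=seed,
            gyro_noise_sd_dps=0.5, accel_noise_sd=0.05,
            gyro_bias_dps=(0.05, 0.05, 0.1),
        ),
        "hesitant": TurnScript(
            phases=tuple(
                [QuietPhase(3.0)] + [
                    x for mag, dur, hes in [
                        (+140, 2.8, ((0.5, 6.0, 0.3),)),
                        (-160, 3.0, ((0.4, 5.0, 0.25),)),
                        (+120, 2.6, ((0.6, 4.0, 0.35),)),
                        (-150, 3.2, ((0.3, 4.0, 0.2), (0.7, 4.0, 0.3))),
                    ]
                    for x in (TurnPhase(mag, dur, hesitations=hes), QuietPhase(3.0))
                ]
            ),
            seed=seed,
        ),
        "wide-radius": TurnScript(
            phases=alternating([(+180, 12.0), (-180, 13.0)]), seed=seed),
        "wrap": TurnScript(
            phases=tuple([QuietPhase(3.0),
                          TurnPhase(+170, 2.0), QuietPhase(3.0),
                          TurnPhase(+120, 2.0), QuietPhase(3.0),
                          TurnPhase(-400, 4.0), QuietPhase(3.0)]),
            seed=seed,
        ),
    }
    return {name: render(s) for name, s in suite.items()}
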