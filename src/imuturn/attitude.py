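"""6DOF attitude estimation by relative orientation.

The sensor-to-global rotation matrix ``R`` (rows = global axes expressed in
the sensor frame, so ``R @ v_sensor`` gives global coordinates) is

1. initialised from gravity over the first quasi-static accelerometer window
   (global Z = normalised mean specific force; heading is arbitrary, chosen so
   yaw starts at exactly 0), and
2. propagated sample-by-sample with the gyroscope through an axis-angle
   (Rodrigues) update ``R[k+1] = T(w_global) @ R[k]`` with rotation angle
   ``θ = ‖w‖ / f_s``.

Only yaw — the angular displacement about the gravity axis — is consumed by
turning detection downstream. No magnetometer is used, so a constant gyro
bias about the vertical integrates into a slow linear yaw drift; this is an
accepted limitation because turning dynamics are much faster than the drift.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .imu_io import DetectionConfig, ImuRecording

__all__ = [
    "GravityEstimate",
    "AttitudeTrack",
    "InitializationError",
    "find_stable_window",
    "init_orientation",
    "axis_angle_transform",
    "propagate",
    "to_euler",
    "unwrap_yaw",
    "estimate_attitude",
]

logger = logging.getLogger(__name__)

#: Orthonormality drift that triggers SVD re-orthonormalisation.
ORTHO_DRIFT_TOL = 1e-6
#: Samples between orthonormality checks during propagation.
ORTHO_CHECK_EVERY = 128
#: |pitch| (degrees) beyond which Euler extraction is flagged as near gimbal lock.
GIMBAL_PITCH_DEG = 89.9

GRAVITY = 9.81  # m/s²


class InitializationError(RuntimeError):
    """No quasi-static accelerometer window found — orientation cannot be initialised."""


@dataclass(frozen=True)
class GravityEstimate:
    """Mean specific force over the first quasi-static window.

    ``inclination_deg`` is the tilt of the sensor +z axis away from the
    measured gravity direction (diagnostic only; 0 for a flat-mounted sensor).
    """

    mean_accel: np.ndarray     # 3-vector, m/s²
    inclination_deg: float
    window_start: int          # sample index

    def __post_init__(self):
        norm = float(np.linalg.norm(self.mean_accel))
        if not (0.8 * GRAVITY <= norm <= 1.2 * GRAVITY):
            raise ValueError(
                f"mean accel norm {norm:.3f} m/s² is not within 20% of g; "
                "the window is not quasi-static"
            )


@dataclass(frozen=True)
class AttitudeTrack:
    """Per-sample orientation and Euler angles of a recording.

    ``R`` holds sensor-to-global rotation matrices; ``yaw_deg`` is wrapped to
    (−180°, 180°] while ``yaw_unwrapped_deg`` is seam-free and is the signal
    segmented into turns. ``gimbal_flags`` marks samples with |pitch| > 89.9°.
    """

    t: np.ndarray                 # (n,)
    R: np.ndarray                 # (n, 3, 3)
    roll_deg: np.ndarray
    pitch_deg: np.ndarray
    yaw_deg: np.ndarray
    yaw_unwrapped_deg: np.ndarray
    gimbal_flags: np.ndarray      # bool (n,)
    n_reorthonormalizations: int = 0

    @property
    def fs(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])


def find_stable_window(rec: ImuRecording, cfg: DetectionConfig | None = None) -> GravityEstimate:
    """Locate the earliest quasi-static accelerometer window for gravity alignment.

    Scans for the first run of ``cfg.stable_window_samples`` consecutive
    samples whose per-axis peak-to-peak amplitude is below
    ``cfg.stable_pp_threshold`` (0.2 m/s²); at 128 Hz the default 5-sample
    window covers the first ~0.04 s of stillness.

    Raises
    ------
    InitializationError
        If no such window exists anywhere in the recording.
    """
    cfg = cfg or DetectionConfig()
    w = int(cfg.stable_window_samples)
    n = rec.n_samples
    if n < w:
        raise InitializationError(
            f"recording has {n} samples, fewer than the {w}-sample stable window"
        )
    a = rec.accel
    # sliding per-axis peak-to-peak via a stride-free windowed view
    windows = np.lib.stride_tricks.sliding_window_view(a, w, axis=0)  # (n-w+1, 3, w)
    pp = windows.max(axis=2) - windows.min(axis=2)                    # (n-w+1, 3)
    ok = np.nonzero((pp < cfg.stable_pp_threshold).all(axis=1))[0]
    if ok.size == 0:
        raise InitializationError(
            f"no {w}-sample window with per-axis peak-to-peak accel "
            f"< {cfg.stable_pp_threshold} m/s²; cannot align to gravity"
        )
    start = int(ok[0])
    mean_accel = a[start:start + w].mean(axis=0)
    norm = np.linalg.norm(mean_accel)
    cos_inc = np.clip(mean_accel[2] / norm, -1.0, 1.0)
    return GravityEstimate(
        mean_accel=mean_accel,
        inclination_deg=float(np.degrees(np.arccos(cos_inc))),
        window_start=start,
    )


def init_orientation(grav: GravityEstimate) -> np.ndarray:
    """Build the initial sensor-to-global rotation from the gravity estimate.

    Global Z (row 3) is the normalised mean specific force in sensor
    coordinates. Global X is seeded as ``[1, 0, 0]`` and made orthogonal via
    two cross products (Y = Z × X, then X = Y × Z), which fixes a
    right-handed triad with det +1 and an initial yaw of exactly 0. If the
    gravity direction is (numerically) parallel to the X seed, the seed falls
    back to ``[0, 1, 0]``.
    """
    z = np.asarray(grav.mean_accel, dtype=float)
    z = z / np.linalg.norm(z)
    seed = np.array([1.0, 0.0, 0.0])
    y = np.cross(z, seed)
    ny = np.linalg.norm(y)
    if ny < 1e-6:
        logger.warning("gravity parallel to X seed; falling back to [0, 1, 0]")
        seed = np.array([0.0, 1.0, 0.0])
        y = np.cross(z, seed)
        ny = np.linalg.norm(y)
    y /= ny
    x = np.cross(y, z)
    x /= np.linalg.norm(x)
    R = np.array([x, y, z])
    return R


def axis_angle_transform(w: np.ndarray, fs: float) -> np.ndarray:
    """Rodrigues rotation matrix for one gyroscope sample.

    The rotation axis is ``w/‖w‖`` and the rotation angle ``θ = ‖w‖/fs`` —
    the angle swept at rate ``w`` (rad/s) during one sampling interval. A
    zero rate returns the identity. Positive rate about +z yields a rotation
    that increases yaw (right-handed convention).
    """
    w = np.asarray(w, dtype=float)
    norm = float(np.linalg.norm(w))
    if norm == 0.0:
        return np.eye(3)
    wx, wy, wz = w / norm
    theta = norm / fs
    c = math.cos(theta)
    s = math.sin(theta)
    t = 1.0 - c
    return np.array([
        [t * wx * wx + c,      t * wx * wy - s * wz, t * wx * wz + s * wy],
        [t * wx * wy + s * wz, t * wy * wy + c,      t * wy * wz - s * wx],
        [t * wx * wz - s * wy, t * wy * wz + s * wx, t * wz * wz + c],
    ])


def _reorthonormalize(R: np.ndarray) -> np.ndarray:
    """Project onto SO(3) via SVD (nearest rotation in Frobenius norm)."""
    U, _, Vt = np.linalg.svd(R)
    Rn = U @ Vt
    if np.linalg.det(Rn) < 0:
        U[:, -1] *= -1.0
        Rn = U @ Vt
    return Rn


def propagate(
    rec: ImuRecording,
    R0: np.ndarray,
    start: int = 0,
    frame: str = "global",
) -> AttitudeTrack:
    """Integrate the gyroscope into a per-sample orientation track.

    From sample ``start`` onward, each gyro sample is rotated to the global
    frame (``w_g = R @ w_s``) and applied as ``R[k+1] = T(w_g) @ R[k]``.
    With ``frame="sensor"`` the algebraically identical body-frame form
    ``R[k+1] = R[k] @ T(w_s)`` is used instead (the two agree to rounding;
    the equivalence is exercised in the test suite). Samples before ``start``
    carry the initial orientation.

    Orthonormality is checked every ``ORTHO_CHECK_EVERY`` samples; drift
    beyond 1e-6 triggers an SVD projection back onto SO(3) (logged).
    """
    if frame not in ("global", "sensor"):
        raise ValueError(f"unknown frame {frame!r}")
    n = rec.n_samples
    fs = rec.fs
    gyro = rec.gyro
    Rs = np.empty((n, 3, 3))
    Rs[: start + 1] = R0
    R = np.array(R0, dtype=float)
    n_fix = 0
    eye = np.eye(3)
    for k in range(start, n - 1):
        w = gyro[k]
        if frame == "global":
            R = axis_angle_transform(R @ w, fs) @ R
        else:
            R = R @ axis_angle_transform(w, fs)
        if (k - start) % ORTHO_CHECK_EVERY == ORTHO_CHECK_EVERY - 1:
            drift = np.abs(R @ R.T - eye).max()
            if drift > ORTHO_DRIFT_TOL:
                logger.info("re-orthonormalizing at sample %d (drift %.2e)", k, drift)
                R = _reorthonormalize(R)
                n_fix += 1
        Rs[k + 1] = R

    roll, pitch, yaw, gimbal = _euler_array(Rs)
    return AttitudeTrack(
        t=rec.t,
        R=Rs,
        roll_deg=roll,
        pitch_deg=pitch,
        yaw_deg=yaw,
        yaw_unwrapped_deg=unwrap_yaw(yaw),
        gimbal_flags=gimbal,
        n_reorthonormalizations=n_fix,
    )


def _euler_array(Rs: np.ndarray):
    """Vectorised intrinsic Z-Y-X Euler extraction (degrees) with gimbal flags."""
    Rs = np.asarray(Rs, dtype=float)
    yaw = np.degrees(np.arctan2(Rs[..., 1, 0], Rs[..., 0, 0]))
    pitch = np.degrees(np.arcsin(np.clip(-Rs[..., 2, 0], -1.0, 1.0)))
    roll = np.degrees(np.arctan2(Rs[..., 2, 1], Rs[..., 2, 2]))
    # map yaw −180 → +180 so the wrapped range is (−180, 180]
    yaw = np.where(yaw <= -180.0, yaw + 360.0, yaw)
    gimbal = np.abs(pitch) > GIMBAL_PITCH_DEG
    return roll, pitch, yaw, gimbal


def to_euler(R: np.ndarray) -> tuple[float, float, float]:
    """Convert one rotation matrix to (roll, pitch, yaw) in degrees.

    Intrinsic Z-Y-X convention: ``R = Rz(yaw) @ Ry(pitch) @ Rx(roll)``.
    Yaw lies in (−180°, 180°]. Near gimbal lock (|pitch| > 89.9°) roll/yaw
    are individually ill-conditioned (only their combination is defined); a
    warning is logged and the standard atan2 values are returned.
    """
    roll, pitch, yaw, gimbal = _euler_array(np.asarray(R, dtype=float))
    if gimbal:
        logger.warning("Euler extraction near gimbal lock (|pitch| = %.3f°)", abs(pitch))
    return float(roll), float(pitch), float(yaw)


def unwrap_yaw(yaw_deg: np.ndarray) -> np.ndarray:
    """Remove ±180° seam jumps from a wrapped yaw series.

    Consecutive differences larger than 180° are corrected by ±360°, so the
    physical yaw rate is preserved and a turn crossing the seam stays one
    continuous excursion.
    """
    return np.unwrap(np.asarray(yaw_deg, dtype=float), period=360.0)


def estimate_attitude(rec: ImuRecording, cfg: DetectionConfig | None = None) -> AttitudeTrack:
    """Full attitude front-end: stable window → gravity init → propagation."""
    cfg = cfg or DetectionConfig()
    grav = find_stable_window(rec, cfg)
    R0 = init_orientation(grav)
    return propagate(rec, R0, start=grav.window_start)
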