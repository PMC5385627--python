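"""Data model and on-disk formats for IMU recordings and turn events.

Internal unit conventions, fixed package-wide:

* time — seconds from recording start
* accelerometer — m/s², sensor frame
* gyroscope — rad/s, sensor frame (converted from deg/s at the I/O boundary)
* angles exposed to users (yaw, turn magnitudes, thresholds) — degrees

The IMU CSV format is one metadata comment line followed by a 7-column table::

    # gyro_unit=deg_s fs=128
    t,ax,ay,az,gx,gy,gz
    0.0000000,0.012,-0.034,9.803,0.11,-0.02,0.35
    ...

Turn events are stored as a JSON array of objects (or an equivalent CSV) with
keys ``t_start, t_end, duration, magnitude_deg, direction, source``.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ImuRecording",
    "TurnEvent",
    "DetectionConfig",
    "FormatError",
    "NonUniformSamplingError",
    "read_imu_csv",
    "write_imu_csv",
    "read_turns",
    "write_turns",
]

IMU_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]
EVENT_FIELDS = ["t_start", "t_end", "duration", "magnitude_deg", "direction", "source"]

#: Allowed |Δt − 1/f_s| before a recording is rejected as non-uniform (s).
UNIFORMITY_TOL_S = 1e-6


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


class NonUniformSamplingError(FormatError):
    """Raised when timestamp spacing deviates from 1/f_s (resampling is out of scope)."""

    def __init__(self, index: int, dt: float, expected: float):
        self.index = index
        self.dt = dt
        self.expected = expected
        super().__init__(
            f"non-uniform sampling at sample index {index}: "
            f"spacing {dt:.9f} s, expected {expected:.9f} s"
        )


@dataclass(frozen=True)
class ImuRecording:
    """A uniformly sampled 6DOF IMU time series from a single body-worn sensor.

    Attributes
    ----------
    t : ndarray, shape (n,)
        Sample times in seconds, strictly increasing, uniform at rate ``fs``.
    accel : ndarray, shape (n, 3)
        Accelerometer output in m/s², sensor frame. A stationary, level sensor
        reads approximately ``[0, 0, +9.81]`` (reaction to gravity along +z).
    gyro : ndarray, shape (n, 3)
        Angular velocity in rad/s, sensor frame.
    fs : float
        Sampling rate in Hz (128 for the lower-back sensor this package targets).
    """

    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    fs: float = 128.0

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        accel = np.atleast_2d(np.asarray(self.accel, dtype=float))
        gyro = np.atleast_2d(np.asarray(self.gyro, dtype=float))
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "accel", accel)
        object.__setattr__(self, "gyro", gyro)
        if t.ndim != 1 or len(t) < 2:
            raise ValueError("recording needs at least 2 samples")
        if accel.shape != (len(t), 3) or gyro.shape != (len(t), 3):
            raise ValueError(
                f"channel shape mismatch: t has {len(t)} samples, "
                f"accel {accel.shape}, gyro {gyro.shape}"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        dt = np.diff(t)
        expected = 1.0 / self.fs
        bad = np.nonzero(np.abs(dt - expected) >= UNIFORMITY_TOL_S)[0]
        if bad.size:
            i = int(bad[0])
            raise NonUniformSamplingError(i + 1, float(dt[i]), expected)

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Recording span in seconds (last minus first timestamp)."""
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class TurnEvent:
    """One turn — detected by the algorithm or annotated from a reference.

    ``magnitude`` is the absolute yaw excursion in degrees; ``direction`` is
    the left/right label ("indeterminate" is only possible for events whose
    gyro integral is below 1°, which cannot happen for accepted turns).
    Duration/magnitude limits apply only to ``source="algorithm"`` events;
    reference annotations are preserved as given.
    """

    t_start: float
    t_end: float
    magnitude: float
    direction: str
    source: str = "algorithm"

    def __post_init__(self):
        if not self.t_end > self.t_start:
            raise ValueError(f"event must have positive duration, got "
                             f"[{self.t_start}, {self.t_end}]")
        if self.magnitude < 0:
            raise ValueError("magnitude is an absolute value, must be >= 0")
        if self.direction not in ("left", "right", "indeterminate"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.source not in ("algorithm", "reference"):
            raise ValueError(f"unknown source {self.source!r}")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.t_start + self.t_end)

    def to_dict(self) -> dict:
        return {
            "t_start": self.t_start,
            "t_end": self.t_end,
            "duration": self.duration,
            "magnitude_deg": self.magnitude,
            "direction": self.direction,
            "source": self.source,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TurnEvent":
        ev = cls(
            t_start=float(d["t_start"]),
            t_end=float(d["t_end"]),
            magnitude=float(d["magnitude_deg"]),
            direction=str(d["direction"]),
            source=str(d["source"]),
        )
        if "duration" in d and d["duration"] not in ("", None):
            stored = float(d["duration"])
            if not math.isclose(stored, ev.duration, rel_tol=1e-9, abs_tol=1e-9):
                raise FormatError(
                    f"stored duration {stored} inconsistent with interval "
                    f"[{ev.t_start}, {ev.t_end}]"
                )
        return ev


@dataclass(frozen=True)
class DetectionConfig:
    """All thresholds of the turning-detection algorithm.

    Defaults are the operating point of the validated lower-back algorithm:
    turns are yaw excursions ≥ ``magnitude_threshold`` (90°, sweepable over
    45°–110°) lasting 0.1–10 s; a hesitation is a sub-movement shorter than
    0.5 s and smaller than 10% of both neighbors (each > 10°, same direction).
    """

    magnitude_threshold: float = 90.0        # degrees
    duration_min: float = 0.1                # s
    duration_max: float = 10.0               # s
    hesitation_max_duration: float = 0.5     # s
    hesitation_max_fraction: float = 0.10    # of both neighbors' magnitude
    hesitation_min_neighbor: float = 10.0    # degrees
    stable_window_samples: int = 5           # accel samples for gravity init
    stable_pp_threshold: float = 0.2         # m/s² peak-to-peak
    match_tolerance: float = 2.5             # s, event matching (validation)
    plateau_split_s: float = 0.1             # s, exactly-flat yaw run that separates segments
    direction_convention: str = "positive_right"  # or "positive_left"

    def __post_init__(self):
        positives = {
            "magnitude_threshold": self.magnitude_threshold,
            "duration_min": self.duration_min,
            "duration_max": self.duration_max,
            "hesitation_max_duration": self.hesitation_max_duration,
            "hesitation_min_neighbor": self.hesitation_min_neighbor,
            "stable_window_samples": self.stable_window_samples,
            "stable_pp_threshold": self.stable_pp_threshold,
            "match_tolerance": self.match_tolerance,
            "plateau_split_s": self.plateau_split_s,
        }
        for name, v in positives.items():
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if not self.duration_min < self.duration_max:
            raise ValueError("duration_min must be < duration_max")
        if not 0 < self.hesitation_max_fraction < 1:
            raise ValueError("hesitation_max_fraction must lie in (0, 1)")
        if self.direction_convention not in ("positive_right", "positive_left"):
            raise ValueError(
                f"unknown direction_convention {self.direction_convention!r}"
            )

    def with_threshold(self, magnitude_threshold: float) -> "DetectionConfig":
        return replace(self, magnitude_threshold=magnitude_threshold)


# ---------------------------------------------------------------------------
# IMU CSV
# ---------------------------------------------------------------------------

def _parse_metadata_line(line: str) -> dict:
    meta = {}
    for token in line.lstrip("#").split():
        if "=" in token:
            k, v = token.split("=", 1)
            meta[k.strip()] = v.strip()
    return meta


def read_imu_csv(path, fs: float | None = None, gyro_unit: str | None = None) -> ImuRecording:
    """Read an IMU recording from CSV.

    Parameters
    ----------
    path : path-like
        CSV with header ``t,ax,ay,az,gx,gy,gz`` and an optional leading
        metadata comment ``# gyro_unit=deg_s|rad_s fs=<Hz>``.
    fs : float, optional
        Sampling rate override; inferred from metadata or timestamps if absent.
    gyro_unit : {"deg_s", "rad_s"}, optional
        Overrides the metadata gyro unit. deg/s values are converted to rad/s.

    Raises
    ------
    FormatError
        If required columns are missing.
    NonUniformSamplingError
        If timestamp spacing is non-uniform; names the offending sample index.
    """
    path = Path(path)
    meta: dict = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            meta = _parse_metadata_line(first)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in IMU_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s) {missing} in {path.name}; "
                          f"expected header {','.join(IMU_COLUMNS)}")
    if fs is None:
        if "fs" in meta:
            fs = float(meta["fs"])
        else:
            dt = np.diff(df["t"].to_numpy())
            fs = float(round(1.0 / np.median(dt), 6))
    unit = gyro_unit or meta.get("gyro_unit", "rad_s")
    if unit not in ("deg_s", "rad_s"):
        raise FormatError(f"unknown gyro unit {unit!r} (expected deg_s or rad_s)")
    gyro = df[["gx", "gy", "gz"]].to_numpy(dtype=float)
    if unit == "deg_s":
        gyro = np.deg2rad(gyro)
    return ImuRecording(
        t=df["t"].to_numpy(dtype=float),
        accel=df[["ax", "ay", "az"]].to_numpy(dtype=float),
        gyro=gyro,
        fs=fs,
    )


def write_imu_csv(rec: ImuRecording, path, gyro_unit: str = "rad_s") -> None:
    """Write a recording in the package CSV format (metadata line + 7 columns)."""
    gyro = rec.gyro if gyro_unit == "rad_s" else np.rad2deg(rec.gyro)
    df = pd.DataFrame(
        np.column_stack([rec.t, rec.accel, gyro]), columns=IMU_COLUMNS
    )
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# gyro_unit={gyro_unit} fs={rec.fs:g}\n")
        df.to_csv(fh, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# Turn-event files
# ---------------------------------------------------------------------------

def _check_sorted_nonoverlapping(events: Sequence[TurnEvent]) -> None:
    for a, b in zip(events, events[1:]):
        if b.t_start < a.t_start:
            raise ValueError("events must be sorted by t_start")
        if b.t_start < a.t_end and a.source == b.source:
            warnings.warn(
                f"overlapping events from source {a.source!r} at "
                f"t={b.t_start:.3f}s; preserved as-is",
                stacklevel=3,
            )


def write_turns(events: Sequence[TurnEvent], path) -> None:
    """Write turn events to JSON (``.json``) or CSV (anything else), losslessly."""
    events = list(events)
    _check_sorted_nonoverlapping(events)
    path = Path(path)
    rows = [ev.to_dict() for ev in events]
    if path.suffix.lower() == ".json":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=1)
            fh.write("\n")
    else:
        df = pd.DataFrame(rows, columns=EVENT_FIELDS)
        df.to_csv(path, index=False, float_format="%.12g")


def read_turns(path) -> list[TurnEvent]:
    """Read turn events written by :func:`write_turns` (JSON or CSV)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            rows = json.load(fh)
    else:
        if path.stat().st_size == 0:
            return []
        df = pd.read_csv(path)
        missing = [c for c in EVENT_FIELDS if c not in df.columns]
        if missing:
            raise FormatError(f"missing column(s) {missing} in {path.name}")
        rows = df.to_dict("records")
    events = [TurnEvent.from_dict(r) for r in rows]
    _check_sorted_nonoverlapping(events)
    return events
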