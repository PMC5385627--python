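"""Turn detection from the unwrapped yaw trace.

The yaw trace is cut into monotone pieces at direction reversals (local
extrema): the end of one piece is the start of the next, so pieces tile the
recording. Brief interruptions inside a turn — hesitations, common in
parkinsonian turning — are merged away: a piece shorter than 0.5 s and
smaller than 10% of both neighbours (each > 10°, same direction) joins its
neighbours into one turn. Pieces are then kept as turns if their absolute
magnitude reaches the detection threshold (default 90°) within 0.1–10 s.
Turn direction comes from the sign of the integrated vertical angular rate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .attitude import AttitudeTrack, estimate_attitude
from .imu_io import DetectionConfig, ImuRecording, TurnEvent

__all__ = [
    "YawSegment",
    "segment_yaw",
    "merge_hesitations",
    "filter_turns",
    "turn_direction",
    "detect_turns",
    "direction_label",
]


@dataclass(frozen=True)
class YawSegment:
    """One monotone piece of the unwrapped yaw trace.

    ``magnitude`` is signed (yaw at end − yaw at start); its sign is the
    piece's direction in the internal right-handed convention. Zero-magnitude
    pieces represent quiet plateaus that separate movements.
    """

    i_start: int
    i_end: int
    t_start: float
    t_end: float
    magnitude: float   # degrees, signed

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def sign(self) -> int:
        return 0 if self.magnitude == 0 else (1 if self.magnitude > 0 else -1)


def _make_segment(t: np.ndarray, yaw: np.ndarray, i0: int, i1: int) -> YawSegment:
    return YawSegment(
        i_start=i0, i_end=i1,
        t_start=float(t[i0]), t_end=float(t[i1]),
        magnitude=float(yaw[i1] - yaw[i0]),
    )


def segment_yaw(track: AttitudeTrack, cfg: DetectionConfig | None = None) -> list[YawSegment]:
    """Cut the unwrapped yaw trace into monotone pieces at direction reversals.

    Boundaries sit at local extrema of yaw. Exactly-flat runs lasting at
    least ``cfg.plateau_split_s`` (quiet standing) become zero-magnitude
    separator pieces with boundaries at both ends, so the adjoining turns
    keep their true start/end; shorter flat runs (isolated zero-rate samples)
    are attached to the preceding piece, breaking at the last flat sample
    when the direction reverses across them. Constant yaw yields no segments.
    """
    cfg = cfg or DetectionConfig()
    t = track.t
    yaw = track.yaw_unwrapped_deg
    n = len(yaw)
    d = np.diff(yaw)
    signs = np.sign(d).astype(int)
    nz = np.nonzero(signs)[0]
    if nz.size == 0:
        return []

    min_plateau = cfg.plateau_split_s
    # boundary sample indices, built left to right; always starts at 0
    bounds = [0]
    prev_sign = 0          # sign of the piece being grown
    run_start = None       # first diff index of the current zero run
    for i in range(len(d)):
        s = signs[i]
        if s == 0:
            if run_start is None:
                run_start = i
            continue
        if run_start is not None:
            # a zero run [run_start, i) just ended; i is the next moving diff
            run_dur = t[i] - t[run_start]
            if run_dur >= min_plateau:
                # long quiet plateau: its own zero piece
                if run_start != bounds[-1]:
                    bounds.append(run_start)
                bounds.append(i)
            elif prev_sign != 0 and s != prev_sign:
                # short flat run across a reversal: break at its last sample
                bounds.append(i)
            run_start = None
        elif prev_sign != 0 and s != prev_sign:
            bounds.append(i)
        prev_sign = s
    # trailing zero run: attach as separate piece if long enough
    if run_start is not None:
        run_dur = t[n - 1] - t[run_start]
        if run_dur >= min_plateau and run_start != bounds[-1]:
            bounds.append(run_start)
    if bounds[-1] != n - 1:
        bounds.append(n - 1)

    return [
        _make_segment(t, yaw, i0, i1) for i0, i1 in zip(bounds, bounds[1:])
    ]


def _is_hesitation(a: YawSegment, h: YawSegment, b: YawSegment,
                   cfg: DetectionConfig) -> bool:
    """All four conjuncts of the hesitation rule, boundaries strict."""
    return (
        h.duration < cfg.hesitation_max_duration
        and abs(h.magnitude) < cfg.hesitation_max_fraction * abs(a.magnitude)
        and abs(h.magnitude) < cfg.hesitation_max_fraction * abs(b.magnitude)
        and abs(a.magnitude) > cfg.hesitation_min_neighbor
        and abs(b.magnitude) > cfg.hesitation_min_neighbor
        and a.sign == b.sign and a.sign != 0
    )


def merge_hesitations(segments: list[YawSegment],
                      cfg: DetectionConfig | None = None) -> list[YawSegment]:
    """Merge hesitation pieces so an interrupted turn counts once.

    Scans triples (A, h, B) left to right; whenever h is a hesitation
    (duration < 0.5 s, |h| < 10% of |A| and of |B|, |A| and |B| > 10°, same
    direction), the triple collapses into one piece spanning A.start→B.end
    whose magnitude is the net yaw change. Repeats until a fixed point, so
    chains of hesitations collapse into a single turn. Tiling is preserved.
    """
    cfg = cfg or DetectionConfig()
    segs = list(segments)
    changed = True
    while changed:
        changed = False
        out: list[YawSegment] = []
        i = 0
        while i < len(segs):
            if i + 2 < len(segs) and _is_hesitation(segs[i], segs[i + 1], segs[i + 2], cfg):
                a, h, b = segs[i], segs[i + 1], segs[i + 2]
                out.append(YawSegment(
                    i_start=a.i_start, i_end=b.i_end,
                    t_start=a.t_start, t_end=b.t_end,
                    magnitude=a.magnitude + h.magnitude + b.magnitude,
                ))
                i += 3
                changed = True
            else:
                out.append(segs[i])
                i += 1
        segs = out
    return segs


def filter_turns(segments: list[YawSegment], cfg: DetectionConfig | None = None,
                 ) -> list[YawSegment]:
    """Keep pieces qualifying as turns: |magnitude| ≥ threshold (inclusive)
    and duration within [0.1 s, 10 s] (inclusive)."""
    cfg = cfg or DetectionConfig()
    return [
        s for s in segments
        if abs(s.magnitude) >= cfg.magnitude_threshold
        and cfg.duration_min <= s.duration <= cfg.duration_max
    ]


def direction_label(signed_value: float, convention: str = "positive_right") -> str:
    """Map a signed yaw change / gyro integral to a left/right label.

    The default convention follows the validated algorithm: a positive
    vertical-rate integral is a right turn, a negative one a left turn. The
    opposite mapping (``"positive_left"``) is provided because the absolute
    label depends on how the sensor is mounted.
    """
    if convention == "positive_right":
        return "right" if signed_value > 0 else "left"
    elif convention == "positive_left":
        return "left" if signed_value > 0 else "right"
    raise ValueError(f"unknown direction convention {convention!r}")


def turn_direction(rec: ImuRecording, track: AttitudeTrack,
                   i_start: int, i_end: int,
                   cfg: DetectionConfig | None = None) -> tuple[str, float]:
    """Direction of a turn from the integrated vertical angular rate.

    The gyroscope is rotated to the global frame per sample and its vertical
    component integrated over the turn interval by the trapezoid rule; the
    sign of the integral gives the label under the configured convention.
    Integrals below 1° are flagged ``"indeterminate"`` (cannot happen for
    accepted turns, whose yaw excursion is ≥ 45°).

    Returns
    -------
    (label, integral_deg)
    """
    cfg = cfg or DetectionConfig()
    # vertical (global-z) angular rate, rad/s: row 3 of R dotted with gyro
    wz = np.einsum("ij,ij->i", track.R[i_start:i_end + 1, 2, :],
                   rec.gyro[i_start:i_end + 1])
    integral_deg = float(np.degrees(np.trapezoid(wz, rec.t[i_start:i_end + 1])))
    if abs(integral_deg) < 1.0:
        return "indeterminate", integral_deg
    return direction_label(integral_deg, cfg.direction_convention), integral_deg


def detect_turns(rec: ImuRecording, cfg: DetectionConfig | None = None,
                 track: AttitudeTrack | None = None) -> list[TurnEvent]:
    """Run the full detection pipeline on a recording.

    stable window → gravity init → gyro propagation → yaw unwrap →
    segmentation → hesitation merging → magnitude/duration filtering →
    per-turn metrics. Returns events sorted by start time, non-overlapping.
    An ``AttitudeTrack`` computed earlier may be passed to skip re-estimation.
    """
    cfg = cfg or DetectionConfig()
    if track is None:
        track = estimate_attitude(rec, cfg)
    segments = merge_hesitations(segment_yaw(track, cfg), cfg)
    events = []
    for seg in filter_turns(segments, cfg):
        label, _ = turn_direction(rec, track, seg.i_start, seg.i_end, cfg)
        events.append(TurnEvent(
            t_start=seg.t_start,
            t_end=seg.t_end,
            magnitude=abs(seg.magnitude),
            direction=label,
            source="algorithm",
        ))
    return events
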