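"""Event-level validation of detected turns against reference annotations.

Detected and reference turns are paired one-to-one (greedy, nearest
midpoints; a pair is admissible if the intervals overlap or the midpoints
are within a tolerance, default 2.5 s). Matched pairs are true positives,
unmatched detected turns false positives, unmatched reference turns false
negatives. True negatives have no natural unit for event detection; here a
TN is a reference-quiet gap (between consecutive reference turns, plus the
two boundary gaps) that contains no false-positive midpoint — one of several
defensible definitions, isolated in :func:`count_true_negatives` so it can
be swapped.

From the confusion counts the usual agreement statistics follow
(sensitivity, specificity, accuracy, PPV, NPV, Cohen's kappa), and the
per-pair start-time differences feed a Bland–Altman analysis
(mean ± 1.96·SD limits of agreement).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .imu_io import DetectionConfig, ImuRecording, TurnEvent
from . import turning

__all__ = [
    "ConfusionCounts",
    "MatchResult",
    "BlandAltman",
    "ValidationReport",
    "match_events",
    "count_true_negatives",
    "confusion_stats",
    "cohens_kappa",
    "bland_altman",
    "validate_events",
    "threshold_sweep",
    "round2",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Event-level confusion counts; ``tn`` may be absent (None) before
    the gap-based TN definition has been applied."""

    tp: int
    fp: int
    fn: int
    tn: int | None = None

    def __post_init__(self):
        for name in ("tp", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tn is not None and self.tn < 0:
            raise ValueError("tn must be non-negative")

    @property
    def n_algorithm(self) -> int:
        return self.tp + self.fp

    @property
    def n_reference(self) -> int:
        return self.tp + self.fn


@dataclass(frozen=True)
class MatchResult:
    pairs: list[tuple[int, int]]          # (detected index, reference index)
    start_time_diffs: list[float]         # detected start − reference start, s
    counts: ConfusionCounts


@dataclass(frozen=True)
class BlandAltman:
    mean_diff: float
    sd: float
    sem: float
    loa_low: float
    loa_high: float
    n: int


@dataclass(frozen=True)
class ValidationReport:
    counts: ConfusionCounts
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    ppv: float | None
    npv: float | None
    kappa: float | None
    bland_altman: BlandAltman | None
    threshold: float | None = None

    def rounded(self) -> dict:
        """Statistics at 2 decimals (half away from zero), as printed in reports."""
        return {
            k: (None if v is None else round2(v))
            for k, v in {
                "kappa": self.kappa, "accuracy": self.accuracy,
                "sensitivity": self.sensitivity, "specificity": self.specificity,
                "ppv": self.ppv, "npv": self.npv,
            }.items()
        }


def round2(x: float) -> float:
    """Round to 2 decimals, halves away from zero (report convention)."""
    return math.floor(abs(x) * 100 + 0.5) / 100 * (1 if x >= 0 else -1)


def match_events(detected: Sequence[TurnEvent], reference: Sequence[TurnEvent],
                 tolerance: float = 2.5) -> MatchResult:
    """Pair detected and reference turns one-to-one.

    Candidate pairs are those whose intervals overlap or whose midpoints
    differ by at most ``tolerance`` seconds. Pairs are accepted greedily by
    increasing |midpoint difference|; ties break toward the earlier detected
    event (then the earlier reference event), so the result is deterministic.

    Returns matched pairs with their start-time differences (detected −
    reference, for Bland–Altman) and the TP/FP/FN counts.
    """
    if tolerance <= 0:
        raise ValueError("matching tolerance must be positive")
    candidates = []
    for i, d in enumerate(detected):
        for j, r in enumerate(reference):
            overlap = d.t_start < r.t_end and r.t_start < d.t_end
            mid_diff = abs(d.midpoint - r.midpoint)
            if overlap or mid_diff <= tolerance:
                candidates.append((mid_diff, d.t_start, r.t_start, i, j))
    candidates.sort()
    used_d: set[int] = set()
    used_r: set[int] = set()
    pairs: list[tuple[int, int]] = []
    diffs: list[float] = []
    for _, _, _, i, j in candidates:
        if i in used_d or j in used_r:
            continue
        used_d.add(i)
        used_r.add(j)
        pairs.append((i, j))
        diffs.append(detected[i].t_start - reference[j].t_start)
    pairs.sort()
    counts = ConfusionCounts(
        tp=len(pairs),
        fp=len(detected) - len(pairs),
        fn=len(reference) - len(pairs),
    )
    return MatchResult(pairs=pairs, start_time_diffs=diffs, counts=counts)


def count_true_negatives(detected: Sequence[TurnEvent],
                         reference: Sequence[TurnEvent],
                         span: tuple[float, float],
                         match: MatchResult | None = None,
                         duration_min: float = 0.1) -> int:
    """Count true negatives as undisturbed reference-quiet gaps.

    The recording span is divided into maximal gaps between consecutive
    reference turns (including the gap before the first and after the last
    turn). A gap of at least ``duration_min`` seconds counts as a true
    negative when no false-positive midpoint falls inside it.
    """
    t0, t1 = span
    ref = sorted(reference, key=lambda e: e.t_start)
    edges = [t0] + [x for e in ref for x in (e.t_start, e.t_end)] + [t1]
    gaps = [(edges[i], edges[i + 1]) for i in range(0, len(edges), 2)]
    if match is None:
        match = match_events(list(detected), list(ref))
    matched_d = {i for i, _ in match.pairs}
    fp_mid = [d.midpoint for i, d in enumerate(detected) if i not in matched_d]
    tn = 0
    for lo, hi in gaps:
        if hi - lo < duration_min:
            continue
        if any(lo <= m <= hi for m in fp_mid):
            continue
        tn += 1
    return tn


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def confusion_stats(c: ConfusionCounts) -> dict:
    """Sensitivity, specificity, accuracy, PPV, NPV from confusion counts.

    A statistic whose denominator is zero is returned as None (undefined),
    never coerced to 0. Specificity/accuracy/NPV require a TN count.
    """
    tn = c.tn if c.tn is not None else 0
    have_tn = c.tn is not None
    return {
        "sensitivity": _ratio(c.tp, c.tp + c.fn),
        "specificity": _ratio(tn, tn + c.fp) if have_tn else None,
        "accuracy": _ratio(c.tp + tn, c.tp + tn + c.fp + c.fn) if have_tn else None,
        "ppv": _ratio(c.tp, c.tp + c.fp),
        "npv": _ratio(tn, tn + c.fn) if have_tn else None,
    }


def cohens_kappa(c: ConfusionCounts) -> float | None:
    """Chance-corrected agreement between algorithm and reference.

    kappa = (p_o − p_e) / (1 − p_e) with observed agreement
    p_o = (TP + TN)/N and chance agreement
    p_e = [(TP+FP)(TP+FN) + (FN+TN)(FP+TN)] / N². Undefined (None) when
    p_e = 1 or the counts are empty.
    """
    if c.tn is None:
        raise ValueError("kappa needs a TN count")
    n = c.tp + c.fp + c.tn + c.fn
    if n == 0:
        return None
    p_o = (c.tp + c.tn) / n
    p_e = ((c.tp + c.fp) * (c.tp + c.fn) + (c.fn + c.tn) * (c.fp + c.tn)) / n**2
    if p_e == 1.0:
        return None
    return (p_o - p_e) / (1.0 - p_e)


def bland_altman(diffs: Sequence[float]) -> BlandAltman:
    """Bland–Altman summary of paired differences (seconds).

    Returns the mean difference, sample SD, SEM = SD/√n, and the limits of
    agreement mean ± 1.96·SD. Requires at least two pairs.
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size < 2:
        raise ValueError("Bland–Altman needs at least 2 paired differences")
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    sem = sd / math.sqrt(diffs.size)
    return BlandAltman(
        mean_diff=mean, sd=sd, sem=sem,
        loa_low=mean - 1.96 * sd, loa_high=mean + 1.96 * sd,
        n=int(diffs.size),
    )


def validate_events(detected: Sequence[TurnEvent], reference: Sequence[TurnEvent],
                    span: tuple[float, float],
                    cfg: DetectionConfig | None = None) -> ValidationReport:
    """Full event-level validation: matching, counts, statistics, Bland–Altman."""
    cfg = cfg or DetectionConfig()
    match = match_events(list(detected), list(reference), cfg.match_tolerance)
    tn = count_true_negatives(detected, reference, span, match, cfg.duration_min)
    counts = ConfusionCounts(tp=match.counts.tp, fp=match.counts.fp,
                             fn=match.counts.fn, tn=tn)
    stats = confusion_stats(counts)
    ba = bland_altman(match.start_time_diffs) if len(match.start_time_diffs) >= 2 else None
    return ValidationReport(
        counts=counts,
        kappa=cohens_kappa(counts),
        bland_altman=ba,
        threshold=cfg.magnitude_threshold,
        **stats,
    )


def threshold_sweep(rec: ImuRecording, reference: Sequence[TurnEvent],
                    thresholds: Sequence[float] = (45, 60, 70, 80, 90, 100, 110),
                    cfg: DetectionConfig | None = None) -> list[ValidationReport]:
    """Re-validate the same recording at ascending magnitude thresholds.

    The attitude track and merged segmentation are computed once; only the
    magnitude/duration filter, per-turn metrics and matching are re-run per
    threshold. Detected-turn counts are non-increasing in the threshold.
    """
    cfg = cfg or DetectionConfig()
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    from .attitude import estimate_attitude

    track = estimate_attitude(rec, cfg)
    span = (float(rec.t[0]), float(rec.t[-1]))
    reports = []
    for thr in thresholds:
        c = cfg.with_threshold(float(thr))
        detected = turning.detect_turns(rec, c, track=track)
        reports.append(validate_events(detected, reference, span, c))
    return reports
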