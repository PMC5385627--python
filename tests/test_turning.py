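import numpy as np
import pytest

import imuturn as it
from imuturn.turning import YawSegment

from conftest import make_track, piecewise_linear_yaw


def seg(t0, t1, mag, fs=100.0):
    return YawSegment(i_start=int(t0 * fs), i_end=int(t1 * fs),
                      t_start=t0, t_end=t1, magnitude=mag)


def brute_force_boundaries(yaw):
    """Independent extrema scan for traces without plateaus."""
    d = np.diff(yaw)
    return [0] + [i for i in range(1, len(yaw) - 1)
                  if d[i - 1] * d[i] < 0] + [len(yaw) - 1]


class TestSegmentYaw:
    def test_piecewise_linear_three_segments(self):
        yaw = piecewise_linear_yaw([0, 120, 30, 200])
        segments = it.segment_yaw(make_track(yaw))
        assert [round(s.magnitude) for s in segments] == [120, -90, 170]
        bounds = [segments[0].i_start] + [s.i_end for s in segments]
        assert bounds == brute_force_boundaries(yaw)

    def test_segments_tile_the_trace(self):
        yaw = piecewise_linear_yaw([0, 50, -40, 90, 10])
        segments = it.segment_yaw(make_track(yaw))
        for a, b in zip(segments, segments[1:]):
            assert a.i_end == b.i_start and a.t_end == b.t_start
        assert segments[0].i_start == 0
        assert segments[-1].i_end == len(yaw) - 1

    def test_nonzero_segments_alternate_sign(self):
        yaw = piecewise_linear_yaw([0, 80, 20, 150, 60, 200])
        signs = [s.sign for s in it.segment_yaw(make_track(yaw)) if s.sign != 0]
        assert all(a != b for a, b in zip(signs, signs[1:]))

    def test_strictly_monotone_is_one_segment(self):
        segments = it.segment_yaw(make_track(np.linspace(0, 150, 300)))
        assert len(segments) == 1
        assert segments[0].magnitude == pytest.approx(150.0)

    def test_constant_yaw_is_empty(self):
        assert it.segment_yaw(make_track(np.zeros(500))) == []

    def test_quiet_plateau_separates_and_keeps_turn_edges(self):
        """A long exactly-flat run becomes a zero piece so the adjoining
        turns keep their true start and end."""
        yaw = np.concatenate([
            np.zeros(100),                  # 1 s quiet
            np.linspace(0, 120, 200),       # 2 s turn
            np.full(100, 120.0),            # 1 s quiet
            np.linspace(120, 0, 200),       # 2 s turn back
            np.full(100, 0.0),
        ])
        segments = it.segment_yaw(make_track(yaw))
        nonzero = [s for s in segments if s.sign != 0]
        assert [round(s.magnitude) for s in nonzero] == [120, -120]
        assert nonzero[0].i_start == 100 and nonzero[0].i_end == pytest.approx(299, abs=1)
        assert nonzero[1].i_start == pytest.approx(400, abs=1)


class TestMergeHesitations:
    def test_textbook_hesitation_merges_to_net_magnitude(self):
        """+100° (2 s), −5° (0.3 s), +100° (2 s) is one 195° turn of 4.3 s."""
        segments = [seg(0, 2, 100.0), seg(2, 2.3, -5.0), seg(2.3, 4.3, 100.0)]
        merged = it.merge_hesitations(segments)
        assert len(merged) == 1
        assert merged[0].magnitude == pytest.approx(195.0)
        assert merged[0].duration == pytest.approx(4.3)

    def test_slow_interruption_not_merged(self):
        segments = [seg(0, 2, 100.0), seg(2, 2.6, -5.0), seg(2.6, 4.6, 100.0)]
        assert len(it.merge_hesitations(segments)) == 3

    def test_large_interruption_not_merged(self):
        segments = [seg(0, 2, 100.0), seg(2, 2.3, -15.0), seg(2.3, 4.3, 100.0)]
        assert len(it.merge_hesitations(segments)) == 3

    def test_chain_of_hesitations_collapses_to_one_turn(self):
        segments = [
            seg(0, 2, 80.0), seg(2, 2.2, -4.0), seg(2.2, 4.2, 80.0),
            seg(4.2, 4.4, -3.0), seg(4.4, 6.4, 80.0),
        ]
        merged = it.merge_hesitations(segments)
        assert len(merged) == 1
        assert merged[0].magnitude == pytest.approx(233.0)

    def test_tiling_preserved_after_merge(self):
        segments = [seg(0, 1, 30.0), seg(1, 3, 100.0), seg(3, 3.3, -5.0),
                    seg(3.3, 5.3, 100.0), seg(5.3, 6, -20.0)]
        merged = it.merge_hesitations(segments)
        for a, b in zip(merged, merged[1:]):
            assert a.t_end == b.t_start

    # Each rule conjunct flips merge/no-merge exactly at its boundary; the
    # duration and magnitude bounds are strict, the neighbour bound is strict.
    @pytest.mark.parametrize("h_dur,h_mag,a_mag,b_mag,merges", [
        (0.49, -5.0, 100.0, 100.0, True),    # all conjuncts hold
        (0.50, -5.0, 100.0, 100.0, False),   # duration not < 0.5 s
        (0.49, -9.99, 100.0, 100.0, True),   # just under 10% of both
        (0.49, -10.0, 100.0, 100.0, False),  # exactly 10% of both
        (0.49, -5.0, 100.0, 49.0, False),    # 10% of the smaller neighbour hit
        (0.49, -0.5, 10.0, 100.0, False),    # neighbour not > 10°
        (0.49, -0.5, 10.01, 100.0, True),    # neighbour just above 10°
        (0.49, -5.0, 100.0, -100.0, False),  # opposite neighbour directions
    ])
    def test_rule_conjunct_boundaries(self, h_dur, h_mag, a_mag, b_mag, merges):
        segments = [seg(0, 2, a_mag), seg(2, 2 + h_dur, h_mag),
                    seg(2 + h_dur, 4 + h_dur, b_mag)]
        merged = it.merge_hesitations(segments)
        assert (len(merged) == 1) == merges


class TestFilterTurns:
    @pytest.mark.parametrize("mag,dur,kept", [
        (90.0, 2.0, True),     # threshold is inclusive
        (89.9, 2.0, False),
        (-90.0, 2.0, True),    # sign-independent
        (95.0, 12.0, False),   # duration ceiling
        (95.0, 10.0, True),
        (95.0, 0.1, True),
        (95.0, 0.05, False),
    ])
    def test_magnitude_and_duration_window(self, mag, dur, kept):
        kept_segments = it.filter_turns([seg(0, dur, mag)])
        assert (len(kept_segments) == 1) == kept


class TestDirection:
    def test_mirrored_gyro_flips_every_direction(self, clean):
        rec = clean.recording
        events = it.detect_turns(rec)
        mirrored = it.ImuRecording(t=rec.t, accel=rec.accel, gyro=-rec.gyro,
                                   fs=rec.fs)
        flipped = it.detect_turns(mirrored)
        assert len(events) == len(flipped) > 0
        for a, b in zip(events, flipped):
            assert {a.direction, b.direction} == {"left", "right"}

    def test_scripted_left_turn_is_left(self):
        res = it.render(it.TurnScript(
            phases=(it.QuietPhase(3.0), it.TurnPhase(-180.0, 2.0),
                    it.QuietPhase(3.0)), seed=0))
        ev, = it.detect_turns(res.recording)
        assert ev.direction == "left" == res.truth[0].direction

    def test_gyro_integral_sign_matches_segment_sign(self, clean):
        """Internal consistency: the vertical gyro integral and the yaw
        excursion give the same direction for every accepted turn."""
        rec = clean.recording
        track = it.estimate_attitude(rec)
        segments = it.merge_hesitations(it.segment_yaw(track))
        for s in it.filter_turns(segments):
            label, integral = it.turn_direction(rec, track, s.i_start, s.i_end)
            assert label == it.direction_label(s.magnitude)
            assert np.sign(integral) == s.sign


class TestDetectTurns:
    def test_clean_scenario_exact_recovery(self, clean):
        """Noise-free scripted turns: every turn found, no extras, magnitude
        within 1° and boundaries within 2 samples."""
        events = it.detect_turns(clean.recording)
        truth = clean.truth
        assert len(events) == len(truth)
        two_samples = 2.0 / clean.recording.fs
        for d, t in zip(events, truth):
            assert d.direction == t.direction
            assert d.magnitude == pytest.approx(t.magnitude, abs=1.0)
            assert abs(d.t_start - t.t_start) <= two_samples
            assert abs(d.t_end - t.t_end) <= two_samples

    def test_stationary_recording_detects_nothing(self):
        res = it.render(it.TurnScript(phases=(it.QuietPhase(60.0),), seed=0))
        assert it.detect_turns(res.recording) == []

    def test_turn_count_monotone_in_threshold(self, suite):
        rec = suite["noisy"].recording
        track = it.estimate_attitude(rec)
        counts = [
            len(it.detect_turns(rec, it.DetectionConfig(magnitude_threshold=thr),
                                track=track))
            for thr in (45, 60, 70, 80, 90, 100, 110)
        ]
        assert counts == sorted(counts, reverse=True)
        assert counts[0] > 0

    def test_yaw_wrap_never_splits_a_turn(self, suite):
        """Turns that carry the wrapped yaw across ±180° stay single events
        with no boundary at the seam."""
        res = suite["wrap"]
        track = it.estimate_attitude(res.recording)
        assert np.abs(np.diff(track.yaw_deg)).max() > 180.0  # seam is crossed
        events = it.detect_turns(res.recording, track=track)
        assert len(events) == len(res.truth)
        for d, t in zip(events, res.truth):
            assert d.magnitude == pytest.approx(t.magnitude, abs=1.0)

    def test_hesitant_turns_counted_once(self, suite):
        res = suite["hesitant"]
        events = it.detect_turns(res.recording)
        assert len(events) == len(res.truth)
        for d, t in zip(events, res.truth):
            assert d.magnitude == pytest.approx(t.magnitude, abs=1.0)
            assert d.direction == t.direction

    def test_events_sorted_and_non_overlapping(self, suite):
        events = it.detect_turns(suite["noisy"].recording)
        for a, b in zip(events, events[1:]):
            assert a.t_end <= b.t_start
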