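"""Blink removal, I-VT classification and feature-series construction."""

import numpy as np
import pytest
from scipy import signal as sps

from eyesync import (GazeRecording, classify_ivt, extract_features,
                     fixation_distance_series, pupil_series, remove_blinks,
                     saccade_amplitude_series)
from eyesync.eye_features import GazeEvent
from helpers import make_gaze, scripted_jump_gaze


class TestRemoveBlinks:
    def test_blink_free_input_unchanged(self):
        gaze = make_gaze(np.zeros(600), np.zeros(600))
        clean, mask, intervals = remove_blinks(gaze)
        assert intervals == []
        assert not mask.any()
        np.testing.assert_array_equal(clean.pupil_left, gaze.pupil_left)

    def test_constant_pupil_interpolates_exactly(self):
        pupil = np.full(600, 3.0)
        pupil[100:110] = 0.0
        gaze = make_gaze(np.zeros(600), np.zeros(600), pupil=pupil)
        clean, mask, _ = remove_blinks(gaze)
        np.testing.assert_array_equal(clean.pupil_left, 3.0)
        assert mask[100:110].all()

    def test_detected_intervals_match_injection(self, small_session):
        # ground-truth intervals from the generator vs detected cores
        truth = small_session.truth.blink_intervals
        assert truth, "fixture should contain injected blinks"
        _, _, detected = remove_blinks(small_session.gaze)
        n = small_session.gaze.n_samples
        t = small_session.gaze.time

        def interval_mask(intervals):
            m = np.zeros(n, dtype=bool)
            for s, e in intervals:
                m |= (t >= s) & (t < e)
            return m
        mt, md = interval_mask(truth), interval_mask(detected)
        jaccard = (mt & md).sum() / (mt | md).sum()
        assert jaccard >= 0.9

    def test_unusable_session_rejected(self):
        pupil = np.full(600, 3.0)
        pupil[:400] = 0.0
        gaze = make_gaze(np.zeros(600), np.zeros(600), pupil=pupil)
        with pytest.raises(ValueError, match="unusable"):
            remove_blinks(gaze)


class TestClassifyIvt:
    def test_stationary_gaze_is_one_fixation(self):
        gaze = make_gaze(np.zeros(600), np.zeros(600))
        events = classify_ivt(gaze)
        assert [e.kind for e in events] == ["fixation"]

    def test_scripted_jumps_all_detected(self):
        gaze, _ = scripted_jump_gaze(n_jumps=20)
        events = classify_ivt(gaze, velocity_threshold=30.0)
        assert sum(e.kind == "saccade" for e in events) == 20

    def test_infinite_threshold_gives_one_fixation(self):
        gaze, _ = scripted_jump_gaze(n_jumps=20)
        events = classify_ivt(gaze, velocity_threshold=np.inf)
        assert [e.kind for e in events] == ["fixation"]

    def test_threshold_monotone(self, small_session):
        clean, _, _ = remove_blinks(small_session.gaze)
        counts = []
        for thr in [5.0, 15.0, 30.0, 60.0, 120.0, 500.0]:
            events = classify_ivt(clean, velocity_threshold=thr)
            counts.append(sum(e.kind == "saccade" for e in events))
        assert counts == sorted(counts, reverse=True)

    def test_events_partition_timeline(self, small_session):
        clean, _, _ = remove_blinks(small_session.gaze)
        events = classify_ivt(clean)
        total = sum(e.duration for e in events)
        assert total == pytest.approx(clean.duration, abs=1 / clean.rate)
        for prev, cur in zip(events[:-1], events[1:]):
            assert cur.start_s == pytest.approx(prev.end_s)

    def test_non_positive_threshold_rejected(self):
        gaze = make_gaze(np.zeros(60), np.zeros(60))
        with pytest.raises(ValueError):
            classify_ivt(gaze, velocity_threshold=0.0)


class TestFixationDistance:
    def fixation(self, t0, t1, cx, cy):
        return GazeEvent("fixation", t0, t1, centroid_x=cx, centroid_y=cy)

    def test_three_four_five(self):
        events = [self.fixation(0.0, 1.0, 0.0, 0.0),
                  self.fixation(1.0, 2.0, 3.0, 4.0)]
        series = fixation_distance_series(events, 60.0, 120)
        assert series.values[-1] == pytest.approx(5.0)
        assert np.all(series.values[:60] == 0.0)  # before second fixation

    def test_identical_centroids_give_zero(self):
        events = [self.fixation(0.0, 1.0, 2.0, 2.0),
                  self.fixation(1.0, 2.0, 2.0, 2.0)]
        series = fixation_distance_series(events, 60.0, 120)
        assert np.all(series.values == 0.0)

    def test_literal_norm_variant(self):
        events = [self.fixation(0.0, 1.0, 1.0, 1.0),
                  self.fixation(1.0, 2.0, 3.0, 4.0)]
        euclid = fixation_distance_series(events, 60.0, 120)
        literal = fixation_distance_series(events, 60.0, 120,
                                           literal_norm=True)
        assert euclid.values[-1] == pytest.approx(np.hypot(2.0, 3.0))
        assert literal.values[-1] == pytest.approx(np.sqrt(1 + 1 + 9 + 16))

    def test_single_fixation_warns_all_zero(self):
        events = [self.fixation(0.0, 2.0, 1.0, 1.0)]
        series = fixation_distance_series(events, 60.0, 120)
        assert np.all(series.values == 0.0)

    def test_matches_event_log_on_scripted_gaze(self):
        gaze, jump_idx = scripted_jump_gaze(n_jumps=5, jump=4.0)
        events = classify_ivt(gaze)
        series = fixation_distance_series(events, 60.0, gaze.n_samples)
        # every consecutive centroid pair is 4 apart by construction
        nonzero = series.values[series.values > 0]
        np.testing.assert_allclose(nonzero, 4.0, atol=1e-9)


class TestSaccadeAmplitude:
    def test_no_saccades_all_zero(self):
        events = [GazeEvent("fixation", 0.0, 2.0, centroid_x=0, centroid_y=0)]
        series = saccade_amplitude_series(events, 60.0, 120)
        assert np.all(series.values == 0.0)

    def test_single_saccade_three_samples(self):
        events = [
            GazeEvent("fixation", 0.0, 1.0, centroid_x=0, centroid_y=0),
            GazeEvent("saccade", 1.0, 1.05, amplitude=10.0),
            GazeEvent("fixation", 1.05, 2.0, centroid_x=10, centroid_y=0),
        ]
        series = saccade_amplitude_series(events, 60.0, 120)
        assert (series.values == 10.0).sum() == 3
        assert (series.values != 0.0).sum() == 3

    def test_event_velocity_is_amplitude_over_duration(self):
        e = GazeEvent("saccade", 1.0, 1.05, amplitude=10.0)
        assert e.velocity == pytest.approx(200.0)

    def test_velocity_variant(self):
        events = [GazeEvent("saccade", 0.0, 0.5, amplitude=5.0)]
        series = saccade_amplitude_series(events, 60.0, 60,
                                          use_velocity=True)
        assert series.values[0] == pytest.approx(10.0)


class TestPupilSeries:
    def test_constant_input_centers_to_zero(self):
        gaze = make_gaze(np.zeros(600), np.zeros(600), pupil=3.0)
        series = pupil_series(gaze, "left")
        assert np.all(series.values == 0.0)

    def test_left_right_symmetry(self):
        gaze = make_gaze(np.zeros(600), np.zeros(600), pupil=3.0)
        gaze.pupil_left = gaze.pupil_right = 3.0 + 0.1 * np.sin(
            np.arange(600) / 60)
        left = pupil_series(gaze, "left")
        right = pupil_series(gaze, "right")
        np.testing.assert_array_equal(left.values, right.values)

    def test_sinusoid_modulation_recovered(self):
        t = np.arange(3600) / 60.0
        pupil = 3.0 + 0.2 * np.sin(2 * np.pi * 0.3 * t)
        gaze = make_gaze(np.zeros(3600), np.zeros(3600), pupil=pupil)
        series = pupil_series(gaze, "right")
        f, p = sps.periodogram(series.values, fs=60.0)
        assert f[np.argmax(p)] == pytest.approx(0.3, abs=0.02)

    def test_unknown_side_rejected(self):
        gaze = make_gaze(np.zeros(60), np.zeros(60))
        with pytest.raises(ValueError):
            pupil_series(gaze, "middle")


def test_all_features_share_length_and_rate(small_session):
    feats = extract_features(small_session.gaze)
    lengths = {len(s.values) for s in feats.values()}
    rates = {s.rate for s in feats.values()}
    assert lengths == {small_session.gaze.n_samples}
    assert rates == {60.0}
    for s in feats.values():
        assert np.all(np.isfinite(s.values))
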