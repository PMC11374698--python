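"""Speed, shuttle detection, pseudoshuttles, windows, condition averages."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avoidspace.events import (
    AlignedTrialTensor,
    assign_pseudoshuttles,
    classify_shuttle,
    condition_averages,
    detect_shuttle_start,
    extract_windows,
    instantaneous_speed,
    per_point_speed,
    sample_pseudoshuttle,
)
from avoidspace.synthetic import POINT_LABELS


def _tracking_from_centroid(centroid):
    """5-point tracking whose stable-point centroid equals `centroid`."""
    return np.repeat(centroid[None, :, :], 5, axis=0)


class TestSpeed:
    def test_stationary_points_give_zero(self):
        centroid = np.tile([3.0, 4.0], (20, 1))
        speed = instantaneous_speed(_tracking_from_centroid(centroid), POINT_LABELS)
        np.testing.assert_allclose(speed, 0.0)

    def test_one_pixel_per_step_is_five_per_second(self):
        centroid = np.stack([np.arange(10.0), np.zeros(10)], axis=1)
        speed = instantaneous_speed(_tracking_from_centroid(centroid), POINT_LABELS)
        np.testing.assert_allclose(speed[1:], 5.0)

    def test_circular_motion_matches_chord_length(self):
        r, theta = 7.0, 0.3
        angles = np.arange(50) * theta
        centroid = r * np.stack([np.cos(angles), np.sin(angles)], axis=1)
        speed = instantaneous_speed(_tracking_from_centroid(centroid), POINT_LABELS)
        expected = 2 * r * np.sin(theta / 2) * 5.0
        np.testing.assert_allclose(speed[1:], expected, rtol=1e-12)

    def test_missing_point_label_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            instantaneous_speed(np.zeros((2, 5, 2)), ("nose", "tail base"))

    def test_per_point_speed_shape(self):
        rng = np.random.default_rng(0)
        tracking = rng.random((5, 30, 2))
        assert per_point_speed(tracking).shape == (5, 30)


class TestDetectShuttleStart:
    def test_single_jump_found(self):
        speed = np.zeros(50)
        speed[31:] = 10.0  # increase happens at step 30 -> 31
        t = detect_shuttle_start(speed, crossing_time=7.0)
        assert t == pytest.approx(30 / 5.0)

    def test_constant_speed_ties_to_earliest(self):
        speed = np.full(50, 2.0)
        t = detect_shuttle_start(speed, crossing_time=8.0)
        assert t == pytest.approx(8.0 - 2.0)

    def test_equal_maximal_jumps_resolve_to_earlier(self):
        speed = np.zeros(60)
        speed[26:] += 3.0
        speed[31:] += 3.0  # two equal +3 jumps inside the [5 s, 7 s] window
        t = detect_shuttle_start(speed, crossing_time=7.0)
        # brute-force stable argmax over the same window
        i_lo, i_cross = 7 * 5 - 10, 7 * 5
        inc = np.diff(speed[i_lo : i_cross + 1])
        best = min(np.flatnonzero(inc == inc.max()))
        assert t == pytest.approx((i_lo + best) / 5.0)
        assert t == pytest.approx(25 / 5.0)

    def test_window_before_trace_start_rejected(self):
        with pytest.raises(ValueError, match="2 s"):
            detect_shuttle_start(np.zeros(30), crossing_time=1.0)


class TestPseudoshuttle:
    def test_degenerate_distribution_reproduced(self):
        rng = np.random.default_rng(0)
        out = sample_pseudoshuttle(np.full(6, 5.0), 10, rng)
        np.testing.assert_allclose(out, 5.0)

    def test_out_of_bounds_latencies_excluded(self):
        rng = np.random.default_rng(1)
        out = sample_pseudoshuttle(np.array([2.0, 5.0, 7.0]), 500, rng)
        assert set(np.unique(out)) <= {5.0, 7.0}

    def test_large_sample_matches_source_proportions(self):
        rng = np.random.default_rng(2)
        out = sample_pseudoshuttle(np.array([4.0, 6.0]), 10_000, rng)
        assert abs(np.mean(out == 4.0) - 0.5) < 0.02

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="no avoid latencies"):
            sample_pseudoshuttle(np.array([1.0, 12.0]), 5, np.random.default_rng(0))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=100, max_value=2000))
    def test_sampled_distribution_converges_to_source(self, n):
        """KS distance to the clipped empirical distribution shrinks with n."""
        rng = np.random.default_rng(17)
        source = np.array([3.5, 4.0, 5.5, 8.0, 8.5])
        out = sample_pseudoshuttle(source, n, rng)
        # empirical CDFs agree on the support up to sampling error ~ 1/sqrt(n)
        for v in source:
            emp = np.mean(out <= v)
            true = np.mean(source <= v)
            assert abs(emp - true) < 4.0 / np.sqrt(n) + 0.05


def _trial_table(rows):
    return pd.DataFrame(rows)


class TestExtractWindows:
    fs = 5.0

    def _traces(self, n=600):
        return np.arange(2 * n, dtype=float).reshape(2, n)

    def test_short_latency_avoid_trial_discarded(self):
        trials = _trial_table(
            [
                {"type": "avoid", "tone_on": 20.0, "tone_off": 23.5, "align_time": 22.5},
                {"type": "avoid", "tone_on": 40.0, "tone_off": 46.0, "align_time": 45.0},
            ]
        )
        tensor = extract_windows(self._traces(), trials, "shuttle-start", (-3.0, 1.0))
        assert list(tensor.trial_ids) == [1]

    def test_window_geometry(self):
        trials = _trial_table(
            [{"type": "avoid", "tone_on": 40.0, "tone_off": 46.0, "align_time": 45.0}]
        )
        tensor = extract_windows(self._traces(), trials, "shuttle-start", (-3.0, 1.0))
        assert tensor.data.shape == (1, 2, 20)
        assert tensor.align_index == 15
        # the alignment sample is the trace value at the align time
        assert tensor.data[0, 0, tensor.align_index] == pytest.approx(45.0 * self.fs)

    def test_tone_alignment_applies_no_latency_filter(self):
        trials = _trial_table(
            [{"type": "avoid", "tone_on": 20.0, "tone_off": 23.5, "align_time": 22.5}]
        )
        tensor = extract_windows(self._traces(), trials, "tone-start", (-1.0, 3.0))
        assert len(tensor.trial_ids) == 1

    def test_out_of_bounds_trial_dropped(self):
        trials = _trial_table(
            [{"type": "avoid", "tone_on": 1.0, "tone_off": 7.0, "align_time": 6.0}]
        )
        tensor = extract_windows(self._traces(35), trials, "shuttle-start", (-3.0, 1.0))
        assert len(tensor.trial_ids) == 1  # window [3 s, 7 s) -> samples 15..35
        tensor = extract_windows(self._traces(34), trials, "shuttle-start", (-3.0, 1.0))
        assert len(tensor.trial_ids) == 0

    def test_alignment_index_uniform_across_trials(self):
        trials = _trial_table(
            [
                {"type": "avoid", "tone_on": 20.0, "tone_off": 27.0, "align_time": 26.0},
                {"type": "avoid", "tone_on": 60.0, "tone_off": 65.0, "align_time": 64.0},
            ]
        )
        tensor = extract_windows(self._traces(), trials, "shuttle-start", (-3.0, 1.0))
        for i, row in enumerate(tensor.trial_ids):
            t_align = trials.loc[row, "align_time"]
            assert tensor.data[i, 0, tensor.align_index] == pytest.approx(
                t_align * self.fs
            )


class TestConditionAverages:
    def test_single_trial_average_is_identity(self):
        x = np.random.default_rng(0).random((1, 4, 40))
        out = condition_averages({"avoid-task1": x})
        np.testing.assert_allclose(out["avoid-task1"], x[0])

    def test_opposite_trials_cancel(self):
        v = np.random.default_rng(1).random((4, 40))
        out = condition_averages({"c": np.stack([v, -v])})
        np.testing.assert_allclose(out["c"], 0.0, atol=1e-15)

    def test_empty_condition_rejected(self):
        with pytest.raises(ValueError, match="ITI-task2"):
            condition_averages({"ITI-task2": np.empty((0, 3, 40))})

    def test_average_commutes_with_trial_order(self):
        rng = np.random.default_rng(2)
        x = rng.random((7, 3, 40))
        a = condition_averages({"c": x})["c"]
        b = condition_averages({"c": x[::-1]})["c"]
        np.testing.assert_allclose(a, b)


class TestClassifyShuttle:
    fs = 5.0

    def _tracking(self, xs, ys):
        centroid = np.stack([xs, ys], axis=1)
        return _tracking_from_centroid(centroid)

    def test_straight_x_crossing(self):
        t = np.arange(50)
        xs = np.where(t < 25, 80.0, 120.0)
        ys = np.full(50, 60.0)
        assert classify_shuttle(self._tracking(xs, ys), POINT_LABELS, 5.0) == "X"

    def test_diagonal_crossing_is_xy(self):
        t = np.arange(50)
        xs = np.where(t < 25, 80.0, 120.0)
        ys = np.where(t < 25, 80.0, 120.0)
        assert classify_shuttle(self._tracking(xs, ys), POINT_LABELS, 5.0) == "XY"

    def test_double_y_crossing_counts_as_y(self):
        t = np.arange(50)
        xs = np.full(50, 80.0)
        ys = np.full(50, 90.0)
        ys[24:28] = 110.0  # crosses y midline and comes back
        # brute-force crossing count oracle
        sign_changes = np.diff(np.sign(ys - 100.0)) != 0
        assert sign_changes.sum() == 2
        assert classify_shuttle(self._tracking(xs, ys), POINT_LABELS, 5.0) == "Y"

    def test_no_crossing_rejected(self):
        tracking = self._tracking(np.full(50, 80.0), np.full(50, 80.0))
        with pytest.raises(ValueError, match="no midline crossing"):
            classify_shuttle(tracking, POINT_LABELS, 5.0)

    def test_generator_labels_match_classifier(self, default_cohort):
        cohort, _ = default_cohort
        s = cohort.subjects[0]
        avoid = s.trials[s.trials["type"] == "avoid"].head(20)
        for _, row in avoid.iterrows():
            got = classify_shuttle(s.tracking, s.point_labels, row["align_time"])
            assert got == row["shuttle_class"]


def test_assign_pseudoshuttles_fills_all_errors(default_cohort):
    cohort, _ = default_cohort
    trials = cohort.subjects[0].trials
    rng = np.random.default_rng(3)
    out = assign_pseudoshuttles(trials, rng)
    err = out[out["type"] == "error"]
    assert np.isfinite(err["align_time"]).all()
    latencies = err["align_time"] - err["tone_on"]
    assert latencies.between(3.0, 9.0).all()
    # avoid rows untouched
    pd.testing.assert_frame_equal(
        out[out["type"] == "avoid"], trials[trials["type"] == "avoid"]
    )
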