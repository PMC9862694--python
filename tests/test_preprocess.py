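"""Filtering, normalization and windowing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bandrep.datamodel_io import IMU_CHANNELS, JointTrack, align_streams
from bandrep.preprocess import (
    WindowBatch,
    assemble_features,
    fill_missing,
    moving_median_filter,
    position_normalize,
    remove_dc,
    scale_normalize,
    segment_windows,
    window_count,
)


def brute_force_mmf(series, window):
    """Independent reference: explicit centered median with edge shrink."""
    h = window // 2
    return np.array([np.median(series[max(0, t - h): t + h + 1])
                     for t in range(len(series))])


class TestMovingMedianFilter:
    def test_single_impulse_removed(self):
        out = moving_median_filter([0, 0, 0, 9, 0, 0, 0], window=3)
        np.testing.assert_array_equal(out, np.zeros(7))

    @pytest.mark.parametrize("window", [1, 3, 7, 15])
    def test_constant_series_unchanged(self, window):
        out = moving_median_filter(np.full(40, 3.5), window)
        np.testing.assert_array_equal(out, np.full(40, 3.5))

    def test_quarter_second_occlusion_spike_removed(self):
        # 7-sample spike (0.23 s at 30 fps) inside a steady segment
        x = np.full(60, 100.0)
        x[25:32] = 0.0
        out = moving_median_filter(x, window=15)
        np.testing.assert_array_equal(out, np.full(60, 100.0))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            moving_median_filter([1.0, 2.0], window=4)

    @pytest.mark.parametrize("n,window", [(5, 15), (30, 7), (100, 15)])
    def test_matches_brute_force_reference(self, rng, n, window):
        x = rng.normal(size=n)
        np.testing.assert_allclose(moving_median_filter(x, window),
                                   brute_force_mmf(x, window))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=60),
           st.sampled_from([1, 3, 5, 15]))
    def test_output_bounded_by_input_range(self, xs, window):
        out = moving_median_filter(xs, window)
        assert out.min() >= min(xs) and out.max() <= max(xs)

    def test_monotone_sequences_preserved(self, rng):
        x = np.cumsum(rng.uniform(0, 1, size=50))
        out = moving_median_filter(x, 15)
        assert np.all(np.diff(out) >= 0)


class TestPositionNormalize:
    def test_definitional_subtraction(self, static_track):
        t = static_track
        t.x[:, 1], t.y[:, 1] = 320.0, 100.0  # neck
        t.x[:, 7], t.y[:, 7] = 400.0, 250.0  # left wrist
        out = position_normalize(t)
        assert out.x[0, 7] == 80.0 and out.y[0, 7] == 150.0

    def test_neck_maps_to_origin_every_frame(self, static_track):
        out = position_normalize(static_track)
        assert np.all(out.x[:, 1] == 0) and np.all(out.y[:, 1] == 0)
        assert out.space == "position_normalized"

    def test_translation_invariance(self, static_track, rng):
        base = position_normalize(static_track.copy())
        shifted = static_track.copy()
        dx, dy = rng.uniform(-500, 500, 2)
        shifted.x += dx
        shifted.y += dy
        out = position_normalize(shifted)
        np.testing.assert_allclose(out.x, base.x, atol=1e-9)
        np.testing.assert_allclose(out.y, base.y, atol=1e-9)

    def test_neck_always_missing_rejected(self, static_track):
        static_track.conf[:, 1] = 0.0
        with pytest.raises(ValueError, match="neck"):
            position_normalize(static_track)

    def test_requires_pixel_space(self, static_track):
        once = position_normalize(static_track)
        with pytest.raises(ValueError, match="pixel"):
            position_normalize(once)


class TestScaleNormalize:
    def _normalized(self, static_track, hip=(0.0, 50.0), wrist=(80.0, 150.0)):
        t = position_normalize(static_track)
        t.x[:, 8], t.y[:, 8] = hip
        t.x[:, 7], t.y[:, 7] = wrist
        return t

    def test_forced_by_definition(self, static_track):
        out = scale_normalize(self._normalized(static_track))
        assert out.x[0, 7] == pytest.approx(160.0)
        assert out.y[0, 7] == pytest.approx(300.0)

    def test_torso_length_is_100_after(self, static_track):
        out = scale_normalize(position_normalize(static_track))
        torso = np.hypot(out.x[:, 8], out.y[:, 8])
        np.testing.assert_allclose(torso, 100.0)

    def test_torso_is_euclidean_neck_hip_distance(self, static_track):
        t = self._normalized(static_track, hip=(30.0, 40.0))
        # distance from the neck (origin) to the hip: hypot(30, 40) = 50
        out = scale_normalize(t)
        assert out.x[0, 7] == pytest.approx(80.0 * 100 / 50)

    def test_uniform_scaling_invariance(self, static_track, rng):
        t = position_normalize(static_track)
        base = scale_normalize(t.copy())
        s = float(rng.uniform(0.1, 8.0))
        scaled = t.copy()
        scaled.x *= s
        scaled.y *= s
        out = scale_normalize(scaled)
        np.testing.assert_allclose(out.x, base.x, atol=1e-9)

    def test_zero_torso_names_frame(self, static_track):
        t = position_normalize(static_track)
        t.x[3, 8] = 0.0
        t.y[3, 8] = 0.0
        with pytest.raises(ValueError, match="frame 3"):
            scale_normalize(t)


class TestRemoveDC:
    def test_constant_goes_to_zero(self):
        np.testing.assert_array_equal(remove_dc([1.0, 1, 1, 1]), np.zeros(4))

    def test_offset_sinusoid_recovers_shape(self):
        t = np.linspace(0, 4 * np.pi, 200)
        out = remove_dc(np.sin(t) + 5.0)
        np.testing.assert_allclose(out, np.sin(t) - np.sin(t).mean(),
                                   atol=1e-12)
        assert abs(out.mean()) < 1e-12

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e4, 1e4), min_size=1, max_size=100))
    def test_idempotent(self, xs):
        once = remove_dc(xs)
        np.testing.assert_allclose(remove_dc(once), once, atol=1e-9)


class TestSegmentWindows:
    def test_eleven_windows_for_120_frames(self, rng):
        batch = segment_windows(rng.normal(size=(10, 120)))
        assert len(batch) == 11  # floor((120-60)/6)+1

    def test_single_window_at_boundary(self, rng):
        assert len(segment_windows(rng.normal(size=(10, 60)))) == 1

    def test_hop_is_6_frames(self, rng):
        batch = segment_windows(rng.normal(size=(10, 200)))
        assert batch.hop == 6  # 0.2 s at 30 fps
        assert np.all(np.diff(batch.source_index) == 6)

    def test_window_k_covers_expected_frames(self, rng):
        x = np.arange(300, dtype=float)[None, :]
        x = np.vstack([x] * 10)
        batch = segment_windows(x)
        for k in [0, 3, len(batch) - 1]:
            np.testing.assert_array_equal(
                batch.windows[k, 0], np.arange(k * 6, k * 6 + 60))

    def test_count_matches_enumeration(self, rng):
        # oracle: enumerate starts s with s + size <= L
        for L in [60, 61, 100, 333]:
            expected = len([s for s in range(0, L, 6) if s + 60 <= L])
            assert window_count(L) == expected
            assert len(segment_windows(rng.normal(size=(10, L)))) == expected

    def test_short_recording_rejected(self, rng):
        with pytest.raises(ValueError, match="too short"):
            segment_windows(rng.normal(size=(10, 59)))


class TestAssembleFeatures:
    @pytest.mark.parametrize("variant,n", [("imu", 10), ("joints", 50),
                                           ("upper_joints", 16),
                                           ("imu_joints", 60)])
    def test_channel_counts(self, clean_session, variant, n):
        rec, _ = clean_session
        batch = assemble_features(rec, variant)
        assert batch.n_channels == n
        assert batch.windows.shape[2] == 60

    def test_imu_joints_layout_is_imu_then_joints(self, clean_session):
        rec, _ = clean_session
        batch = assemble_features(rec, "imu_joints")
        assert batch.channel_layout[:10] == IMU_CHANNELS
        assert batch.channel_layout[10:12] == ("x0", "y0")
        joints_only = assemble_features(rec, "joints")
        assert batch.channel_layout[10:] == joints_only.channel_layout

    def test_upper_joint_selection(self, clean_session):
        rec, _ = clean_session
        names = assemble_features(rec, "upper_joints").channel_layout
        got = {int(n[1:]) for n in names}
        assert got == {1, 2, 3, 4, 5, 6, 7, 8}  # neck..mid-hip, both arms

    def test_unknown_variant_rejected(self, clean_session):
        rec, _ = clean_session
        with pytest.raises(ValueError, match="variant"):
            assemble_features(rec, "everything")


class TestFillMissing:
    def test_interpolates_long_gap(self, static_track):
        t = static_track
        t.x[:, 7] = np.linspace(0, 299, 300) + 100
        t.conf[40:60, 7] = 0.0  # 20-frame dropout
        t.x[40:60, 7] = 0.0
        filled = fill_missing(t)
        np.testing.assert_allclose(filled.x[40:60, 7],
                                   np.linspace(0, 299, 300)[40:60] + 100)

    def test_untouched_joints_identical(self, static_track):
        static_track.conf[10:14, 3] = 0.0
        filled = fill_missing(static_track)
        np.testing.assert_array_equal(filled.x[:, 7], static_track.x[:, 7])
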