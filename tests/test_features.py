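import numpy as np
import pandas as pd
import pytest

from cowmotion import features as ft
from cowmotion.io_dataset import EventRecording
from cowmotion.synthetic import DEFAULT_PROFILES, generate_event


def exact_sine_1hz(n, fs=10.0):
    """Sampled 1 Hz sine with *exact* zeros at the crossing samples."""
    period = np.array([0.0,
                       np.sin(0.2 * np.pi), np.sin(0.4 * np.pi),
                       np.sin(0.4 * np.pi), np.sin(0.2 * np.pi),
                       0.0,
                       -np.sin(0.2 * np.pi), -np.sin(0.4 * np.pi),
                       -np.sin(0.4 * np.pi), -np.sin(0.2 * np.pi)])
    return np.tile(period, n // 10 + 1)[:n]


class TestSegmentation:
    def test_first_mode_single_window(self, mount_event):
        wins = ft.segment_windows(mount_event, "world", mode="first")
        assert len(wins) == 1
        assert wins[0].n == 70
        assert wins[0].index == 0

    def test_tiled_mode_counts_full_windows(self):
        rec = generate_event(DEFAULT_PROFILES["grazing"], seed=9,
                             duration_s=180.0)
        wins = ft.segment_windows(rec, "body", mode="tiled")
        assert len(wins) == 1800 // 70 == 25

    def test_short_event_skipped_with_warning(self, mount_event, caplog):
        short = EventRecording(behavior="walking", cow_id="c",
                               start=mount_event.start,
                               data=mount_event.data.iloc[:50].reset_index(drop=True))
        with caplog.at_level("WARNING"):
            assert ft.segment_windows(short, "world") == []
        assert "shorter" in caplog.text

    def test_magnitude_channels(self, mount_event):
        w = ft.segment_windows(mount_event, "body")[0]
        a = np.column_stack([w.channels["ax"], w.channels["ay"], w.channels["az"]])
        np.testing.assert_allclose(w.channels["amag"], np.linalg.norm(a, axis=1),
                                   atol=1e-12)


class TestFeatureBank:
    def test_basic_stats_alternating(self):
        mean, median, std, total, total_abs, ptp, rms = ft.basic_stats([1, -1, 1, -1])
        assert (mean, median, std) == (0, 0, 1)
        assert (total, total_abs, ptp, rms) == (0, 4, 2, 1)

    @pytest.mark.parametrize("c, n", [(3.0, 1), (-2.5, 7), (0.0, 4)])
    def test_basic_stats_constant(self, c, n):
        x = [c] * n
        mean, median, std, total, total_abs, ptp, rms = ft.basic_stats(x)
        assert (mean, median, std) == (c, c, 0)
        assert total == pytest.approx(n * c)
        assert total_abs == pytest.approx(n * abs(c))
        assert ptp == 0
        assert rms == pytest.approx(abs(c))

    def test_basic_stats_empty_rejected(self):
        with pytest.raises(ValueError):
            ft.basic_stats([])

    def test_zcr_alternating_and_constant(self):
        assert ft.zero_crossing_rate([1, -1, 1, -1]) == 1.0
        assert ft.zero_crossing_rate([5.0] * 10) == 0.0

    def test_zcr_sampled_sine(self):
        # 1 Hz sine over 7 s at 10 Hz crosses zero 13 times
        assert ft.zero_crossing_rate(exact_sine_1hz(70)) == pytest.approx(13 / 69)

    def test_avg_variation(self):
        assert ft.avg_variation([2.0] * 5) == 0.0
        assert ft.avg_variation([0, 1, 0, 1]) == 1.0
        ramp = 0.37 * np.arange(30)
        assert ft.avg_variation(ramp) == pytest.approx(0.37)

    def test_shape_moments(self):
        skew, _ = ft.shape_moments([-1.0, 0.0, 1.0])
        assert skew == pytest.approx(0.0, abs=1e-12)
        assert ft.shape_moments([4.0] * 6) == (0.0, 0.0)
        skew, kurt = ft.shape_moments([0.0, 0.0, 0.0, 1.0])
        # hand arithmetic: m2 = 3/16, m3 = 3/32, m4 = 21/256
        assert skew == pytest.approx((3 / 32) / (3 / 16) ** 1.5)  # ~1.1547
        assert kurt == pytest.approx((21 / 256) / (3 / 16) ** 2 - 3)  # -2/3

    def test_time_between_peaks(self):
        t = np.arange(70) / 10
        assert ft.time_between_peaks(np.sin(2 * np.pi * t), fs=10) == pytest.approx(
            1.0, abs=0.05)
        assert ft.time_between_peaks(np.arange(20.0), fs=10) == 0.0
        x = np.zeros(70)
        x[[10, 30, 60]] = 1.0
        assert ft.time_between_peaks(x, fs=10) == pytest.approx(2.5)

    def test_peak_plateau_takes_first_index(self):
        x = np.array([0, 1, 1, 1, 0, 0, 2, 0.0])
        assert list(ft._local_maxima(x)) == [1, 6]

    def test_spectral_pure_tone(self):
        t = np.arange(70) / 10
        f, d = ft.spectral_features(np.sin(2 * np.pi * 2 * t), fs=10)
        assert f == 2.0
        assert d > 0

    def test_spectral_constant_lowest_bin(self):
        f, d = ft.spectral_features(np.ones(70), fs=10)
        assert f == pytest.approx(10 / 70)
        assert d == 0.0

    def test_spectral_strongest_component_wins(self):
        t = np.arange(70) / 10
        x = np.sin(2 * np.pi * 1 * t) + 2 * np.sin(2 * np.pi * 3 * t)
        f, _ = ft.spectral_features(x, fs=10)
        assert f == 3.0


class TestExtractFeatures:
    def test_vector_length_and_names(self, mount_event):
        w = ft.segment_windows(mount_event, "world")[0]
        fv = ft.extract_features(w)
        assert len(fv) == 112
        assert list(fv.index) == list(ft.FEATURE_COLUMNS)
        assert np.all(np.isfinite(fv.to_numpy()))

    def test_deterministic(self, mount_event):
        w = ft.segment_windows(mount_event, "body")[0]
        pd.testing.assert_series_equal(ft.extract_features(w),
                                       ft.extract_features(w))

    def test_all_zero_window(self):
        w = ft.window_from_arrays(np.zeros((70, 3)), np.zeros((70, 3)))
        fv = ft.extract_features(w)
        # degenerate conventions zero everything except the dominant
        # frequency, pinned to the lowest non-DC bin (fs/N) on a flat spectrum
        dom_f = [c for c in fv.index if c.endswith("__dominant_frequency")]
        assert np.allclose(fv.drop(dom_f), 0.0)
        assert np.allclose(fv[dom_f], 10 / 70)

    def test_channel_values_follow_renaming(self, rng):
        a = rng.standard_normal((70, 3))
        g = rng.standard_normal((70, 3))
        fv = ft.extract_features(ft.window_from_arrays(a, g))
        swapped = ft.extract_features(
            ft.window_from_arrays(a[:, [1, 0, 2]], g))
        for feat in ft.FEATURE_NAMES:
            assert swapped[f"ay__{feat}"] == fv[f"ax__{feat}"]
            assert swapped[f"ax__{feat}"] == fv[f"ay__{feat}"]
            assert swapped[f"az__{feat}"] == fv[f"az__{feat}"]
            assert swapped[f"amag__{feat}"] == fv[f"amag__{feat}"]

    def test_rms_identity(self, rng):
        """rms^2 = mean^2 + std^2 under the population-std convention."""
        for _ in range(25):
            x = rng.standard_normal(70) * rng.uniform(0.1, 10)
            mean, _, std, _, _, _, rms = ft.basic_stats(x)
            assert rms ** 2 == pytest.approx(mean ** 2 + std ** 2, abs=1e-9)

    def test_stationary_world_window_sees_gravity(self, resting_event):
        w = ft.segment_windows(resting_event, "world")[0]
        fv = ft.extract_features(w)
        assert fv["az__mean"] == pytest.approx(9.807, abs=0.1)
        assert fv["ax__mean"] == pytest.approx(0.0, abs=0.1)
        assert fv["ay__mean"] == pytest.approx(0.0, abs=0.1)


class TestDesignMatrix:
    def test_shape_and_labels(self):
        db = ([generate_event(DEFAULT_PROFILES["active_mounting"], seed=s,
                              duration_s=9) for s in range(3)]
              + [generate_event(DEFAULT_PROFILES["walking"], seed=s,
                                duration_s=14) for s in range(5)])
        X, y, meta = ft.build_design_matrix(db, frame="world")
        assert X.shape == (8, 112)
        assert list(y) == [1, 1, 1, 0, 0, 0, 0, 0]
        assert list(meta["behavior"][:3]) == ["active_mounting"] * 3

    def test_gyro_columns_frame_invariant(self, small_db):
        Xb, _, _ = ft.build_design_matrix(small_db, frame="body")
        Xw, _, _ = ft.build_design_matrix(small_db, frame="world")
        gyro_cols = [c for c in ft.FEATURE_COLUMNS if c.split("__")[0]
                     in ("wx", "wy", "wz", "wmag")]
        accel_cols = [c for c in ft.FEATURE_COLUMNS if c.split("__")[0]
                      in ("ax", "ay", "az", "amag")]
        pd.testing.assert_frame_equal(Xb[gyro_cols], Xw[gyro_cols])
        assert not np.allclose(Xb[accel_cols], Xw[accel_cols])

    def test_identity_orientation_frames_agree(self):
        identity = np.tile([1.0, 0, 0, 0], (200, 1))
        db = [generate_event(DEFAULT_PROFILES["walking"], seed=s,
                             duration_s=14, orientation=identity)
              for s in range(3)]
        Xb, _, _ = ft.build_design_matrix(db, frame="body")
        Xw, _, _ = ft.build_design_matrix(db, frame="world")
        np.testing.assert_allclose(Xb.to_numpy(), Xw.to_numpy(), atol=1e-9)

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError):
            ft.build_design_matrix([], frame="world")
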