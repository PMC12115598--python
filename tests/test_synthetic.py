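import json

import numpy as np
import pytest

from cowmotion import synthetic as syn
from cowmotion.io_dataset import NUMERIC_COLUMNS, load_database, summarize_database
from cowmotion.preprocessing import BNO055, GRAVITY, raw_to_accel, raw_to_gyro, rotate_to_world


class TestOrientationTrace:
    def test_zero_wobble_constant(self):
        base = [0.5, 0.5, 0.5, 0.5]
        trace = syn.make_orientation_trace(50, base=base, wobble_deg_s=0, seed=1)
        np.testing.assert_allclose(trace, np.tile(base, (50, 1)), atol=1e-12)

    def test_unit_norm_everywhere(self):
        trace = syn.make_orientation_trace(300, wobble_deg_s=10, seed=2)
        np.testing.assert_allclose(np.linalg.norm(trace, axis=1), 1.0, atol=1e-9)

    def test_wobble_rate(self):
        """5 deg/s at 10 Hz: consecutive samples differ by 0.5 deg."""
        trace = syn.make_orientation_trace(400, wobble_deg_s=5, seed=3)
        angles = []
        for i in range(1, len(trace)):
            dot = abs(np.dot(trace[i - 1], trace[i]))
            angles.append(2 * np.degrees(np.arccos(min(dot, 1.0))))
        assert np.mean(angles) == pytest.approx(0.5, abs=0.01)


class TestGenerateEvent:
    def test_resting_world_frame_sees_gravity(self):
        rec = syn.generate_event(syn.DEFAULT_PROFILES["resting"], seed=21,
                                 duration_s=20)
        assert rec.data["bno_az_world"].mean() == pytest.approx(GRAVITY, abs=0.1)
        assert rec.data["bno_ax_world"].mean() == pytest.approx(0.0, abs=0.1)
        assert rec.data["bno_ay_world"].mean() == pytest.approx(0.0, abs=0.1)

    def test_mount_energy_profile_high_low_high(self):
        """Mount events carry two high-energy peaks straddling a quiet
        middle (the climb and the dismount)."""
        for seed in range(5):
            rec = syn.generate_event(syn.DEFAULT_PROFILES["active_mounting"],
                                     seed=seed, duration_s=9)
            a = rec.data[["bno_ax_world", "bno_ay_world", "bno_az_world"]].to_numpy()
            dev = np.abs(np.linalg.norm(a, axis=1) - GRAVITY)
            third = len(dev) // 3
            e1, e2, e3 = (np.mean(dev[:third] ** 2),
                          np.mean(dev[third:2 * third] ** 2),
                          np.mean(dev[2 * third:] ** 2))
            assert e1 > 2 * e2
            assert e3 > 2 * e2

    def test_frame_consistency(self, mount_event):
        """Stored world-frame channels equal R(q) applied to body-frame
        channels; norms match sample-by-sample."""
        bf = mount_event.data[["bno_ax_body", "bno_ay_body", "bno_az_body"]].to_numpy()
        wf = mount_event.data[["bno_ax_world", "bno_ay_world", "bno_az_world"]].to_numpy()
        q = mount_event.data[["q1", "q2", "q3", "q4"]].to_numpy()
        np.testing.assert_allclose(rotate_to_world(bf, q), wf, atol=1e-9)
        np.testing.assert_allclose(np.linalg.norm(bf, axis=1),
                                   np.linalg.norm(wf, axis=1), atol=1e-9)

    def test_same_seed_identical(self):
        p = syn.DEFAULT_PROFILES["walking"]
        a = syn.generate_event(p, seed=77)
        b = syn.generate_event(p, seed=77)
        assert a.data.equals(b.data)

    def test_duration_below_minimum_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_event(syn.DEFAULT_PROFILES["walking"], seed=0,
                               duration_s=5)

    def test_all_channels_populated(self, mount_event):
        assert not mount_event.data[list(NUMERIC_COLUMNS)].isna().any().any()


class TestDurations:
    def test_mean_durations_match_field_averages(self):
        """Per-class mean durations within 20% of the study averages."""
        targets = {"active_mounting": 9, "walking": 14, "resting": 20,
                   "head_nodding": 8, "grazing": 71}
        events = syn.generate_events({b: 30 for b in targets}, seed=5)
        for b, target in targets.items():
            durs = [e.duration_s for e in events if e.behavior == b]
            assert np.mean(durs) == pytest.approx(target, rel=0.2)


class TestRawCounts:
    def test_gravity_encodes_to_2048(self, resting_event):
        counts = syn.encode_raw_counts(resting_event, BNO055)
        back = raw_to_accel(counts["bno_az_body"].to_numpy(), BNO055)
        np.testing.assert_allclose(back, resting_event.data["bno_az_body"],
                                   atol=BNO055.accel_lsb / 2 + 1e-12)

    def test_roundtrip_within_half_lsb(self, mount_event):
        counts = syn.encode_raw_counts(mount_event, BNO055)
        for c in ("bno_ax_body", "bno_ay_body", "bno_az_body"):
            back = raw_to_accel(counts[c].to_numpy(), BNO055)
            assert np.max(np.abs(back - mount_event.data[c])) <= \
                BNO055.accel_lsb / 2 + 1e-12
        for c in ("bno_gx", "bno_gy", "bno_gz"):
            back = raw_to_gyro(counts[c].to_numpy(), BNO055)
            assert np.max(np.abs(back - mount_event.data[c])) <= \
                BNO055.gyro_lsb / 2 + 1e-12


class TestGenerateDatabase:
    def test_layout_counts_and_manifest(self, tmp_path):
        counts = {"active_mounting": 3, "walking": 2, "grazing": 1}
        root = syn.generate_database(tmp_path / "db", counts, seed=9)
        s = summarize_database(root)
        assert s.counts["active_mounting"] == 3
        assert s.counts["walking"] == 2
        manifest = json.loads((root / "manifest.json").read_text())
        assert len(manifest["events"]) == 6
        db = load_database(root)
        assert len(db) == 6

    def test_zero_counts_empty_layout(self, tmp_path):
        root = syn.generate_database(tmp_path / "db", {}, seed=1)
        assert summarize_database(root).grand_total_s == 0

    def test_fixed_seed_byte_identical(self, tmp_path):
        counts = {"active_mounting": 2, "resting": 1}
        r1 = syn.generate_database(tmp_path / "a", counts, seed=4)
        r2 = syn.generate_database(tmp_path / "b", counts, seed=4)
        files1 = sorted(p.relative_to(r1) for p in r1.rglob("*.csv"))
        files2 = sorted(p.relative_to(r2) for p in r2.rglob("*.csv"))
        assert files1 == files2
        for f in files1:
            assert (r1 / f).read_bytes() == (r2 / f).read_bytes()


class TestProfileInterpolation:
    def test_endpoints(self):
        m = syn.DEFAULT_PROFILES["active_mounting"]
        n = syn.DEFAULT_PROFILES["head_nodding"]
        assert syn.interpolate_profiles(m, n, 0.0) == m
        p1 = syn.interpolate_profiles(m, n, 1.0)
        assert p1.peak_amp == n.peak_amp
        assert p1.osc_amp == n.osc_amp
        assert p1.name == "active_mounting"  # class identity stays the source

    def test_midpoint_linear(self):
        m = syn.DEFAULT_PROFILES["active_mounting"]
        n = syn.DEFAULT_PROFILES["head_nodding"]
        mid = syn.interpolate_profiles(m, n, 0.5)
        assert mid.peak_amp == pytest.approx((m.peak_amp + n.peak_amp) / 2)
        assert mid.gyro_scale_dps == pytest.approx(
            (m.gyro_scale_dps + n.gyro_scale_dps) / 2)

    def test_out_of_range_rejected(self):
        m = syn.DEFAULT_PROFILES["active_mounting"]
        with pytest.raises(ValueError):
            syn.interpolate_profiles(m, m, 1.5)
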