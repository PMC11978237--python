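import dataclasses
import itertools

import numpy as np
import pytest

import pelvikin as pk
from pelvikin.mocap import MARKER_LABELS, orientation_from_markers
from pelvikin.simulate import MarkerGeometry


class TestSchedule:
    def test_last_repetition_end_time(self, clean_config):
        """5 s quiet + 5 reps x 4 s + 4 rests x 2 s -> last end at 33 s."""
        assert clean_config.rep_windows()[-1][1] == pytest.approx(33.0)

    def test_rep_windows_disjoint_with_rest(self, clean_config):
        windows = clean_config.rep_windows()
        for (_, e0), (s1, _) in zip(windows, windows[1:]):
            assert s1 - e0 >= clean_config.rest_s - 1e-12

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            pk.SimulationConfig(rep_duration_s=0.0)
        with pytest.raises(ValueError):
            pk.SimulationConfig(plateau_s=5.0, rep_duration_s=4.0)
        with pytest.raises(ValueError):
            pk.SimulationConfig(depth_mean_m={"SLS": -0.1, "SD15": 0.18, "SD20": 0.2})
        with pytest.raises(ValueError):
            pk.SimulationConfig(master_rate_hz=300.0)


class TestGeneratePose:
    def test_null_motion(self, clean_config):
        pose = pk.generate_pose(
            clean_config, pk.TaskLabel.SLS,
            amplitudes=pk.PelvicAngles(0, 0, 0), depth_m=0.0, sway_accel_sd=0.0,
        )
        for name in ("transverse", "frontal", "sagittal", "vertical_disp", "ml_disp"):
            assert np.all(pose[name] == 0.0)
        assert all(a.as_array().sum() == 0 for a in pose.peak_angles)

    def test_quiet_and_rest_at_baseline(self, clean_pose, clean_config):
        t = clean_pose.series.times()
        quiet = t < clean_config.quiet_pre_s - 1e-9
        assert np.all(clean_pose["vertical_disp"][quiet] == 0.0)
        rest = (t > 9.0 + 1e-9) & (t < 11.0 - 1e-9)
        assert np.all(clean_pose["frontal"][rest] == 0.0)

    def test_vertical_displacement_never_positive(self, clean_pose):
        assert np.all(clean_pose["vertical_disp"] <= 1e-15)

    def test_peak_vertical_velocity_of_raised_cosine(self, clean_config):
        """depth 0.10 m over 4 s: peak speed = pi*0.10/4 = 0.0785 m/s."""
        pose = pk.generate_pose(
            clean_config, pk.TaskLabel.SLS,
            amplitudes=pk.PelvicAngles(0, 0, 0), depth_m=0.10, sway_accel_sd=0.0,
        )
        v = np.gradient(pose["vertical_disp"], 1.0 / pose.rate)
        assert np.abs(v).max() == pytest.approx(np.pi * 0.10 / 4.0, rel=1e-4)

    def test_plateau_holds_depth(self, clean_config):
        cfg = dataclasses.replace(clean_config, plateau_s=1.0)
        pose = pk.generate_pose(
            cfg, pk.TaskLabel.SLS,
            amplitudes=pk.PelvicAngles(0, 0, 0), depth_m=0.10, sway_accel_sd=0.0,
        )
        t = pose.series.times()
        mid = (t > 6.6) & (t < 7.4)  # plateau of the first rep (5..9 s)
        assert np.allclose(pose["vertical_disp"][mid], -0.10, atol=1e-12)


class TestRenderMocap:
    def test_zero_pose_markers_constant(self, clean_config):
        pose = pk.generate_pose(
            clean_config, pk.TaskLabel.SLS,
            amplitudes=pk.PelvicAngles(0, 0, 0), depth_m=0.0, sway_accel_sd=0.0,
        )
        markers = pk.render_mocap(pose)
        ref = MarkerGeometry.default().array()
        for i, label in enumerate(MARKER_LABELS):
            assert np.allclose(markers.positions(label), ref[i], atol=1e-12)

    def test_pure_frontal_rotation_asis_height_difference(self, clean_config):
        """+10 deg frontal: LASIS sits 240*sin(10 deg) = 41.67 mm below RASIS."""
        pose = pk.generate_pose(
            clean_config, pk.TaskLabel.SLS,
            amplitudes=pk.PelvicAngles(0, 10.0, 0), depth_m=0.0, sway_accel_sd=0.0,
        )
        markers = pk.render_mocap(pose)
        t = markers.series.times()
        at_peak = np.argmin(np.abs(t - 7.0))  # mid-rep, profile = 1
        dv = markers.positions("LASIS")[at_peak, 0] - markers.positions("RASIS")[at_peak, 0]
        assert dv == pytest.approx(-0.240 * np.sin(np.deg2rad(10.0)), abs=1e-9)

    def test_rigidity_zero_noise(self, clean_pose):
        markers = pk.render_mocap(clean_pose)
        stacked = markers.stacked()
        for i, j in itertools.combinations(range(4), 2):
            d = np.linalg.norm(stacked[:, i] - stacked[:, j], axis=1)
            assert d.max() - d.min() < 1e-9

    def test_noise_requires_rng(self, clean_pose):
        with pytest.raises(ValueError):
            pk.render_mocap(clean_pose, marker_noise_sd_m=0.001, rng=None)


class TestRenderPhone:
    def test_static_pose_gravity_only(self, clean_gravity_config):
        pose = pk.generate_pose(
            clean_gravity_config, pk.TaskLabel.SLS,
            amplitudes=pk.PelvicAngles(0, 0, 0), depth_m=0.0, sway_accel_sd=0.0,
        )
        phone = pk.render_phone(pose, clean_gravity_config)
        assert np.allclose(phone["ax"], 9.81, atol=1e-9)
        assert np.allclose(phone["ay"], 0.0, atol=1e-9)
        assert np.allclose(phone["az"], 0.0, atol=1e-9)

    def test_mounting_offset_passthrough(self, clean_config):
        cfg = dataclasses.replace(clean_config, mounting_offset_deg=(0.0, 0.0, 5.0))
        pose = pk.generate_pose(
            cfg, pk.TaskLabel.SLS,
            amplitudes=pk.PelvicAngles(0, 0, 0), depth_m=0.0, sway_accel_sd=0.0,
        )
        phone = pk.render_phone(pose, cfg)
        assert np.allclose(phone["roll"], 5.0, atol=1e-12)
        assert np.allclose(phone["pitch"], 0.0, atol=1e-12)

    def test_heading_drift_accumulates(self, clean_config):
        cfg = dataclasses.replace(clean_config, heading_drift_rate_deg_s=0.05)
        pose = pk.generate_pose(
            cfg, pk.TaskLabel.SLS,
            amplitudes=pk.PelvicAngles(0, 0, 0), depth_m=0.0, sway_accel_sd=0.0,
        )
        phone = pk.render_phone(pose, cfg)
        expected = 0.05 * pose.series.duration
        assert phone["azimuth"][-1] - phone["azimuth"][0] == pytest.approx(
            expected, abs=1e-6
        )

    def test_azimuth_wrapped_to_device_range(self, clean_config):
        cfg = dataclasses.replace(clean_config, mounting_offset_deg=(175.0, 0.0, 0.0))
        pose = pk.generate_pose(
            cfg, pk.TaskLabel.SLS,
            amplitudes=pk.PelvicAngles(10.0, 0, 0), depth_m=0.1, sway_accel_sd=0.0,
        )
        phone = pk.render_phone(pose, cfg)
        az = phone["azimuth"]
        assert az.min() > -180.0 - 1e-9 and az.max() <= 180.0 + 1e-9
        # the +10 deg excursion on top of 175 deg must cross the seam
        assert np.any(az < -170.0) and np.any(az > 170.0)


class TestCrossRenderingConsistency:
    def test_marker_orientation_matches_phone_orientation(self, clean_config):
        """Both renderings decode to the same angles (shared Euler convention)."""
        pose = pk.generate_pose(
            clean_config, pk.TaskLabel.SD20,
            amplitudes=pk.PelvicAngles(-4.0, 7.0, -9.0), depth_m=0.2, sway_accel_sd=0.0,
        )
        markers = pk.render_mocap(pose)
        angles_mocap = orientation_from_markers(markers, reference=np.eye(3))
        phone = pk.render_phone(pose, clean_config)
        angles_phone = pk.to_pelvic_angles(phone)
        # compare on the common 50 Hz grid (mocap ::5, phone ::2)
        for plane in pk.PLANES:
            assert np.allclose(
                angles_mocap[plane][::5], angles_phone[plane][::2], atol=1e-6
            )


class TestCohort:
    def test_counting(self, clean_config):
        recs = pk.simulate_cohort(clean_config)
        assert len(recs) == 2 * 3
        assert {(r.participant, r.task.value) for r in recs} == {
            (p, t) for p in (0, 1) for t in ("SLS", "SD15", "SD20")
        }

    def test_determinism_in_memory_and_on_disk(self, tmp_path):
        cfg = pk.SimulationConfig(n_participants=1, tasks=(pk.TaskLabel.SLS,), seed=5)
        a = pk.simulate_cohort(cfg, out_dir=tmp_path / "a")
        b = pk.simulate_cohort(cfg, out_dir=tmp_path / "b")
        assert np.array_equal(a[0].phone["ax"], b[0].phone["ax"])
        assert np.array_equal(a[0].markers["LASIS_x"], b[0].markers["LASIS_x"])
        for name in ("p000_SLS_markers.csv", "p000_SLS_phone.csv", "p000_SLS_truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_amplitude_calibration_is_a_sampling_property(self):
        """Cohort medians of true peak angles land near the configured
        per-task centers (within sampling error of the random effects)."""
        cfg = pk.SimulationConfig(n_participants=40, seed=21)
        recs = pk.simulate_cohort(cfg)
        for task in pk.TASKS:
            amps = [
                r.pose.peak_angles[0] for r in recs if r.task == task
            ]
            for plane in pk.PLANES:
                center = cfg.angle_center_deg[task][plane]
                med = np.median([getattr(a, plane) for a in amps])
                # between-sd 3.5 -> median se ~ 1.25*3.64/sqrt(40) ~ 0.7
                assert abs(med - center) < 2.0

    def test_noise_scale_leaves_latent_truth_unchanged(self, clean_gravity_config):
        cfg = dataclasses.replace(
            clean_gravity_config, marker_noise_sd_m=0.001,
            phone_accel_noise_sd=0.05, phone_orient_noise_sd_deg=0.3,
        )
        a = pk.simulate_cohort(cfg, noise_scale=1.0)
        b = pk.simulate_cohort(cfg, noise_scale=2.0)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.pose["vertical_disp"], rb.pose["vertical_disp"])
            assert ra.pose.peak_angles[0] == rb.pose.peak_angles[0]


class TestGeometry:
    def test_default_is_mirror_symmetric(self):
        geo = MarkerGeometry.default()
        assert np.allclose(geo.local["LASIS"], (0.0, 0.120, 0.090))

    def test_asymmetric_geometry_rejected(self):
        with pytest.raises(ValueError):
            MarkerGeometry(
                {
                    "LASIS": (0.0, 0.120, 0.090),
                    "RASIS": (0.0, -0.110, 0.090),
                    "LPSIS": (0.0, 0.060, -0.090),
                    "RPSIS": (0.0, -0.060, -0.090),
                }
            )
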