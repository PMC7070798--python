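"""Acquisition simulator: trajectories, ray casting, NMEA generation."""

import numpy as np
import pytest

import vinescan as vs
from vinescan.nmea import parse_gga
from vinescan.scene import Batch, Segment, VineScene


def _cylinder_scene(y=1.0, radius=0.05, x=0.0, height=1.8, ground=None):
    seg = Segment(np.array([x, y, 0.0]), np.array([x, y, height]),
                  radius, radius, tag="post")
    return VineScene(segments=[seg], markers=[], batches=[Batch("T", 1, -5, 5)],
                    wood_density=450.0, seed=0, row_y=y,
                    ground_z=-100.0 if ground is None else ground)


class TestTrajectory:
    def test_slice_spacing_at_quarter_speed(self):
        traj = vs.TrajectorySpec(speed=0.25, row_length=2.0,
                                 attitude_amp_rad=(0, 0, 0),
                                 attitude_jitter_rad=0.0,
                                 lateral_wobble_amp=0.0, seed=1)
        poses = vs.simulate_trajectory(traj, scan_rate_hz=25.0)
        dx = np.diff([p.position[0] for p in poses])
        np.testing.assert_allclose(dx, 0.010, rtol=1e-9)

    def test_zero_perturbation_zero_attitude(self):
        traj = vs.TrajectorySpec(speed=0.5, row_length=1.0,
                                 attitude_amp_rad=(0, 0, 0),
                                 attitude_jitter_rad=0.0,
                                 lateral_wobble_amp=0.0, seed=1)
        for p in vs.simulate_trajectory(traj, 50.0):
            assert p.roll == p.pitch == p.yaw == 0.0
            assert p.position[1] == 0.0

    def test_final_position(self):
        traj = vs.TrajectorySpec(speed=0.5, row_length=5.0,
                                 attitude_amp_rad=(0, 0, 0),
                                 attitude_jitter_rad=0.0,
                                 lateral_wobble_amp=0.0, seed=1)
        poses = vs.simulate_trajectory(traj, 50.0)
        assert poses[-1].position[0] == pytest.approx(5.0)
        ts = np.array([p.timestamp for p in poses])
        assert np.all(np.diff(ts) > 0)

    def test_nonpositive_speed_rejected(self):
        with pytest.raises(ValueError):
            vs.TrajectorySpec(speed=0.0, row_length=1.0)
        with pytest.raises(ValueError):
            vs.TrajectorySpec(speed=1.0, row_length=1.0)  # above 3 km/h


class TestCastBeam:
    def test_cylinder_closed_form(self):
        scene = _cylinder_scene(y=1.0, radius=0.05)
        r = vs.cast_beam(np.array([0.0, 0.0, 1.2]), np.array([0.0, 1.0, 0.0]), scene)
        assert r == pytest.approx(0.95, abs=1e-9)

    def test_miss_is_no_return(self):
        scene = _cylinder_scene()
        r = vs.cast_beam(np.array([0.0, 0.0, 1.2]), np.array([0.0, -1.0, 0.0]), scene)
        assert np.isnan(r)

    def test_beyond_range_window_is_no_return(self):
        scene = _cylinder_scene(y=25.0)
        sensor = vs.SensorConfig()
        r = vs.cast_beam(np.array([0.0, 0.0, 1.2]), np.array([0.0, 1.0, 0.0]),
                         scene, sensor)
        assert np.isnan(r)


class TestCastScan:
    def test_beam_count_matches_fov(self):
        sensor = vs.SensorConfig()  # 270 deg at 0.5 deg
        assert sensor.n_beams == 541
        pose = vs.PlatformPose(0.0, np.zeros(3))
        frame, tags = vs.cast_scan(pose, sensor, _cylinder_scene(), rng=None)
        assert len(frame.ranges) == 541 and len(tags) == 541

    def test_noiseless_scan_matches_closed_form(self):
        """Each valid return equals the independent 2D ray-circle distance."""
        scene = _cylinder_scene(y=1.0, radius=0.05, x=0.0)
        sensor = vs.SensorConfig(range_noise_sd=0.0, systematic_error_bound=0.0,
                                 quantization=0.0)
        pose = vs.PlatformPose(0.0, np.zeros(3))
        frame, tags = vs.cast_scan(pose, sensor, scene, rng=None)
        th = np.radians(frame.angles)
        oy, oz = 0.0, sensor.mount_height
        dy, dz = np.cos(th), np.sin(th)
        # ray (oy + t dy, oz + t dz) against circle (y-1)^2 <= r^2 in the plane,
        # cylinder occupying z in [0, 1.8]
        a = dy**2 + 0.0
        b = 2 * dy * (oy - 1.0)
        c = (oy - 1.0) ** 2 - 0.05**2
        disc = b * b - 4 * a * c
        for i in np.flatnonzero(frame.valid):
            assert tags[i] == "post"
            t = (-b[i] - np.sqrt(disc[i])) / (2 * a[i])
            assert 0.0 <= oz + t * dz[i] <= 1.8
            assert frame.ranges[i] == pytest.approx(t, abs=1e-9)

    def test_empty_scene_all_no_return_above_ground(self):
        scene = VineScene(segments=[], markers=[], batches=[Batch("T", 1, -5, 5)],
                         wood_density=450.0, seed=0, ground_z=0.0)
        sensor = vs.SensorConfig(range_noise_sd=0.0, systematic_error_bound=0.0)
        frame, tags = vs.cast_scan(vs.PlatformPose(0.0, np.zeros(3)), sensor,
                                   scene, rng=None)
        hit = np.isfinite(frame.ranges)
        assert np.all(tags[hit] == "ground")
        assert np.all(frame.angles[hit] < 0)  # only downward beams reach soil

    def test_quantization_grid(self):
        scene = _cylinder_scene()
        sensor = vs.SensorConfig(range_noise_sd=0.0, systematic_error_bound=0.0)
        frame, _ = vs.cast_scan(vs.PlatformPose(0.0, np.zeros(3)), sensor, scene,
                                rng=None)
        r = frame.ranges[frame.valid]
        np.testing.assert_allclose(r, np.round(r / 0.001) * 0.001, atol=1e-12)


class TestNmea:
    CANONICAL = "$GPGGA,123519,4807.038,N,01131.000,E,1,08,0.9,545.4,M,46.9,M,,*47"

    def test_canonical_sentence_decodes(self):
        rec = parse_gga(self.CANONICAL)
        assert rec["lat"] == pytest.approx(48.1173, abs=1e-6)
        assert rec["lon"] == pytest.approx(11.516667, abs=1e-6)
        assert rec["quality"] == 1
        assert rec["alt"] == pytest.approx(545.4)

    def test_corrupted_checksum_rejected(self):
        with pytest.raises(ValueError, match="checksum"):
            parse_gga(self.CANONICAL[:-2] + "00")

    def test_generated_checksums_verify_by_xor(self):
        traj = vs.TrajectorySpec(speed=0.5, row_length=1.0, seed=3)
        poses = vs.simulate_trajectory(traj, 50.0)
        sentences, fixes = vs.generate_nmea(poses, 10.0, 0.0,
                                            np.random.default_rng(0))
        for s in sentences:
            body, _, cs = s[1:].partition("*")
            xor = 0
            for ch in body:
                xor ^= ord(ch)
            assert f"{xor:02X}" == cs

    def test_zero_noise_fixes_on_trajectory(self):
        traj = vs.TrajectorySpec(speed=0.5, row_length=2.0,
                                 attitude_amp_rad=(0, 0, 0),
                                 attitude_jitter_rad=0.0,
                                 lateral_wobble_amp=0.0, seed=3)
        poses = vs.simulate_trajectory(traj, 50.0)
        _, fixes = vs.generate_nmea(poses, 10.0, 0.0, np.random.default_rng(0))
        ts = np.array([f.timestamp for f in fixes])
        assert np.all(np.diff(ts) > 0)
        for f in fixes:
            x_true = 0.5 * (f.timestamp - traj.start_t)
            assert f.east == pytest.approx(x_true, abs=2e-3)  # minute rounding
            assert f.north == pytest.approx(0.0, abs=2e-3)

    def test_roundtrip_position_recovery(self):
        from vinescan.nmea import enu_to_lla, format_gga, lla_to_enu
        origin = (40.1333, -3.3667, 750.0)
        lat, lon, alt = enu_to_lla(12.345, -6.789, 0.4, origin)
        rec = parse_gga(format_gga(3600.5, float(lat), float(lon), float(alt)))
        assert rec["lat"] == pytest.approx(float(lat), abs=1e-6)
        assert rec["lon"] == pytest.approx(float(lon), abs=1e-6)
        e, n, u = lla_to_enu(rec["lat"], rec["lon"], rec["alt"], origin)
        assert float(e) == pytest.approx(12.345, abs=5e-4)
        assert float(n) == pytest.approx(-6.789, abs=5e-4)


def test_simulation_run_is_deterministic(cylinder_scene, quiet_sensor,
                                         quiet_trajectory):
    a = vs.simulate_run(cylinder_scene, quiet_sensor, quiet_trajectory)
    b = vs.simulate_run(cylinder_scene, quiet_sensor, quiet_trajectory)
    assert len(a.frames) == len(b.frames)
    for fa, fb in zip(a.frames, b.frames):
        np.testing.assert_array_equal(fa.ranges, fb.ranges)
    assert a.sentences == b.sentences


def test_mean_slice_spacing_tracks_speed_over_rate(quiet_run):
    xs = np.array([p.position[0] for p in quiet_run.poses])
    assert np.mean(np.diff(xs)) == pytest.approx(0.25 / 25.0, rel=0.01)
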