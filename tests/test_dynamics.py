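"""Track ingestion, speeds, angular MSDs, feature tracking, mean flow."""

import numpy as np
import pandas as pd
import pytest

from glidesphere.dynamics import (FeatureTrack, SpeedSeries, TrackerParams,
                                  angular_msd, ingest_track,
                                  instantaneous_speeds, mean_speed,
                                  msd_scaling_exponent, time_averaged_flow,
                                  track_features)
from glidesphere.geometry import (Trajectory, rotation_about_axis,
                                  rotate_points, spherical_to_cartesian)
from glidesphere.projection import EquirectMap
from glidesphere.synthetic import (SceneSpec, StructureSpec,
                                   make_structure_trajectory)


def _blob_maps(geometry, positions_px, n_theta=120, n_phi=240, sigma=2.5,
               amp=1.0):
    """Map sequence with Gaussian blobs at given per-frame (row, col) lists."""
    rows = np.arange(n_theta)[:, None]
    cols = np.arange(n_phi)[None, :]
    maps = []
    for t, frame_positions in enumerate(positions_px):
        data = np.zeros((n_theta, n_phi))
        for r0, c0 in frame_positions:
            dc = (cols - c0 + n_phi / 2) % n_phi - n_phi / 2  # periodic phi
            data += amp * np.exp(-((rows - r0) ** 2 + dc ** 2) / (2 * sigma ** 2))
        maps.append(EquirectMap(data, geometry, time_s=float(t)))
    return maps


class TestIngestTrack:
    def test_equirect_equatorial_rows(self, vesicle):
        df = pd.DataFrame({"time_s": [0.0, 10.0, 20.0],
                           "theta_rad": np.pi / 2,
                           "phi_rad": [0.0, 0.1, 0.2]})
        tr = ingest_track(df, "equirect", vesicle)
        np.testing.assert_allclose(tr.positions[:, 2], 0.0, atol=1e-12)

    def test_confocal_center_is_pole(self, vesicle):
        df = pd.DataFrame({"time_s": [0.0, 5.0], "x_um": 0.0, "y_um": 0.0,
                           "hemisphere": "upper"})
        tr = ingest_track(df, "confocal", vesicle)
        np.testing.assert_allclose(tr.positions, [[0, 0, 18]] * 2, atol=1e-12)

    def test_confocal_outside_disk_names_row(self, vesicle):
        df = pd.DataFrame({"time_s": [0.0, 5.0], "x_um": [0.0, 13.0],
                           "y_um": [0.0, 13.0], "hemisphere": "upper"})
        with pytest.raises(ValueError, match="row 1"):
            ingest_track(df, "confocal", vesicle)

    def test_generator_track_round_trips(self, vesicle):
        scene = SceneSpec(geometry=vesicle, dt_s=10.0, n_frames=20, seed=0,
                          noise_intensity_sd=0.0)
        spec = StructureSpec(kind="vortex", theta0_rad=1.0, speed_nm_s=45.0)
        traj, _ = make_structure_trajectory(spec, scene)
        theta, phi = traj.angles()
        df = pd.DataFrame({"time_s": traj.times, "theta_rad": theta,
                           "phi_rad": phi})
        back = ingest_track(df, "equirect", vesicle)
        np.testing.assert_allclose(back.positions, traj.positions, atol=1e-6)


class TestSpeeds:
    def test_vortex_at_45_nm_s(self, vesicle):
        """Colatitude-60 circle at 2.8868e-3 rad/s: mean arc speed 45 nm/s."""
        scene = SceneSpec(geometry=vesicle, dt_s=10.0, n_frames=180, seed=0,
                          noise_intensity_sd=0.0)
        omega = 2.8868e-3
        v_truth = omega * 18.0 * np.sin(np.radians(60)) * 1e3
        spec = StructureSpec(kind="vortex", theta0_rad=np.radians(60),
                             speed_nm_s=v_truth)
        traj, _ = make_structure_trajectory(spec, scene)
        m, _ = mean_speed(instantaneous_speeds(traj))
        assert m == pytest.approx(45.0, rel=0.01)

    def test_static_trajectory_zero(self, vesicle):
        pos = np.tile([0, 0, 18.0], (5, 1))
        tr = Trajectory(np.arange(5) * 1.0, pos, vesicle)
        assert np.all(instantaneous_speeds(tr).speeds == 0.0)

    def test_quarter_great_circle_closed_form(self, vesicle):
        tr = Trajectory(np.array([0.0, 60.0]),
                        np.array([[18, 0, 0], [0, 18, 0.0]]), vesicle)
        v = instantaneous_speeds(tr).speeds[0]
        assert v == pytest.approx(18e3 * np.pi / 2 / 60, rel=1e-9)  # 471.2 nm/s

    def test_mean_speed_constant_and_alternating(self):
        s = SpeedSeries(np.arange(4) * 1.0, np.full(4, 46.0))
        assert mean_speed(s) == (46.0, 0.0)
        s2 = SpeedSeries(np.arange(4) * 1.0, np.array([40.0, 50, 40, 50]))
        assert mean_speed(s2) == (45.0, 5.0)

    def test_empty_window_raises(self):
        s = SpeedSeries(np.arange(4) * 1.0, np.full(4, 46.0))
        with pytest.raises(ValueError, match="empty"):
            mean_speed(s, window=(100.0, 200.0))

    def test_noisy_stream_recovery(self, vesicle):
        scene = SceneSpec(geometry=vesicle, dt_s=30.0, n_frames=60, seed=42,
                          noise_intensity_sd=0.0,
                          angular_jitter_sd_rad=0.0)
        spec = StructureSpec(kind="stream", theta0_rad=np.radians(80),
                             speed_nm_s=46.0, arc_length_um=20.0)
        traj, _ = make_structure_trajectory(spec, scene)
        m, _ = mean_speed(instantaneous_speeds(traj))
        assert m == pytest.approx(46.0, rel=0.02)


class TestAngularMSD:
    def test_uniform_rotation_is_exactly_ballistic(self, vesicle):
        t = np.arange(100) * 10.0
        omega = 1.5e-3
        tr = Trajectory(t, spherical_to_cartesian(np.full(100, np.pi / 3),
                                                  omega * t, vesicle), vesicle)
        m = angular_msd(tr)
        np.testing.assert_allclose(m.msd_phi, (omega * m.lags) ** 2, rtol=1e-9)
        np.testing.assert_allclose(m.msd_theta, 0.0, atol=1e-12)
        assert msd_scaling_exponent(m, "phi") == pytest.approx(2.0, abs=0.01)

    def test_static_trajectory_zero(self, vesicle):
        pos = np.tile([18.0, 0, 0], (10, 1))
        m = angular_msd(Trajectory(np.arange(10) * 1.0, pos, vesicle))
        assert np.all(m.msd_theta == 0) and np.all(m.msd_phi == 0)

    def test_irregular_sampling_rejected(self, vesicle):
        pos = np.tile([18.0, 0, 0], (4, 1))
        tr = Trajectory(np.array([0.0, 1.0, 3.0, 4.0]), pos, vesicle)
        with pytest.raises(ValueError, match="regular"):
            angular_msd(tr)

    def test_random_walk_msd_matches_k_sigma2(self, vesicle):
        """<dphi^2>(k dt) = k sigma^2 for an isotropic angular walk,
        verified against the closed form over 50 seeded walks."""
        sigma = 0.01
        n, kmax, n_walks = 200, 10, 50
        acc = np.zeros(kmax)
        rng = np.random.default_rng(7)
        for _ in range(n_walks):
            th = np.pi / 2 + np.cumsum(rng.normal(0, sigma, n))
            ph = np.cumsum(rng.normal(0, sigma, n))
            tr = Trajectory.from_angles(np.arange(n) * 1.0, th,
                                        np.mod(ph, 2 * np.pi), vesicle)
            acc += angular_msd(tr, max_lag=kmax).msd_phi
        acc /= n_walks
        ks = np.arange(1, kmax + 1)
        expected = ks * sigma ** 2
        # SE of a time-averaged MSD at lag k is ~ sigma^2*k*sqrt(2k/(n*n_walks))
        se = expected * np.sqrt(2 * ks / (n * n_walks))
        assert np.all(np.abs(acc - expected) < 3 * se + 1e-12)

    def test_random_walk_exponent_is_diffusive(self, vesicle):
        rng = np.random.default_rng(0)
        n = 2000
        th = np.pi / 2 + np.cumsum(rng.normal(0, 0.01, n))
        ph = np.cumsum(rng.normal(0, 0.01, n))
        tr = Trajectory.from_angles(np.arange(n) * 10.0, th,
                                    np.mod(ph, 2 * np.pi), vesicle)
        m = angular_msd(tr, max_lag=100)
        assert msd_scaling_exponent(m, "phi") == pytest.approx(1.0, abs=0.1)

    def test_tilted_circulation_saturates_beyond_half_period(self, vesicle):
        """A circulating trajectory whose circle does not enclose the pole:
        ballistic at short lags, saturated azimuth MSD at long lags."""
        omega, dt, n = 2e-3, 10.0, 800
        t = np.arange(n) * dt
        pts = spherical_to_cartesian(np.full(n, np.radians(60)), omega * t,
                                     vesicle)
        pts = rotate_points(pts, rotation_about_axis([0, 1, 0],
                                                     np.radians(80)))
        m = angular_msd(Trajectory(t, pts, vesicle))
        period = 2 * np.pi / omega
        short = msd_scaling_exponent(m, "phi", lag_range=(dt, 5 * dt))
        long = msd_scaling_exponent(m, "phi",
                                    lag_range=(period / 2, m.lags[-1]))
        assert short == pytest.approx(2.0, abs=0.02)
        assert long < 1.0

    def test_phi_msd_invariant_under_z_rotation_and_time_reversal(self, vesicle):
        rng = np.random.default_rng(3)
        n = 50
        th = np.pi / 2 + 0.3 * np.sin(np.linspace(0, 3, n))
        ph = np.cumsum(rng.uniform(0, 0.3, n))
        t = np.arange(n) * 5.0
        tr = Trajectory.from_angles(t, th, np.mod(ph, 2 * np.pi), vesicle)
        m0 = angular_msd(tr)
        rot = rotation_about_axis([0, 0, 1], 1.7)
        m_rot = angular_msd(Trajectory(t, rotate_points(tr.positions, rot),
                                       vesicle))
        np.testing.assert_allclose(m_rot.msd_phi, m0.msd_phi, atol=1e-12)
        m_rev = angular_msd(Trajectory(t, tr.positions[::-1], vesicle))
        np.testing.assert_allclose(m_rev.msd_phi, m0.msd_phi, atol=1e-12)
        np.testing.assert_allclose(m_rev.msd_theta, m0.msd_theta, atol=1e-12)

    def test_zero_msd_in_range_rejected(self, vesicle):
        pos = np.tile([18.0, 0, 0], (10, 1))
        m = angular_msd(Trajectory(np.arange(10) * 1.0, pos, vesicle))
        with pytest.raises(ValueError, match="log-log"):
            msd_scaling_exponent(m, "phi")


class TestTrackFeatures:
    def test_translating_blob_displacement(self, vesicle):
        n = 8
        positions = [[(60.0, 40.0 + 3 * t)] for t in range(n)]
        maps = _blob_maps(vesicle, positions)
        tracks = track_features(maps, TrackerParams(min_response=0.5))
        assert len(tracks) == 1
        steps = np.diff(tracks[0].phi) * 240 / (2 * np.pi)  # px/frame in phi
        np.testing.assert_allclose(steps, 3.0, atol=0.5)

    def test_seam_crossing_stays_continuous(self, vesicle):
        n = 10
        positions = [[(60.0, (232.0 + 3 * t) % 240)] for t in range(n)]
        maps = _blob_maps(vesicle, positions)
        tracks = track_features(maps, TrackerParams(min_response=0.5))
        assert len(tracks) == 1
        assert len(tracks[0]) == n
        assert np.all(np.abs(np.diff(tracks[0].phi)) < np.pi)

    def test_two_separated_blobs_two_tracks(self, vesicle):
        positions = [[(40.0, 60.0 + 2 * t), (80.0, 180.0 - 2 * t)]
                     for t in range(6)]
        maps = _blob_maps(vesicle, positions)
        tracks = track_features(maps, TrackerParams(min_response=0.5))
        assert len(tracks) == 2

    def test_featureless_frames_give_no_tracks(self, vesicle):
        maps = [EquirectMap(np.zeros((60, 120)), vesicle, time_s=float(t))
                for t in range(3)]
        assert track_features(maps) == []

    def test_single_frame_rejected(self, vesicle):
        maps = [EquirectMap(np.zeros((60, 120)), vesicle)]
        with pytest.raises(ValueError, match="2 frames"):
            track_features(maps)


class TestTimeAveragedFlow:
    def _track_from_angles(self, times, theta, phi):
        return FeatureTrack(track_id=0, frames=np.arange(len(times)),
                            times=np.asarray(times), theta=np.asarray(theta),
                            phi=np.asarray(phi))

    def test_constant_equatorial_track_gives_azimuthal_arrows(self, vesicle):
        omega = 2.5e-3
        t = np.arange(20) * 10.0
        tr = self._track_from_angles(t, np.full(20, np.pi / 2), omega * t)
        maps = [EquirectMap(np.ones((30, 60)), vesicle, time_s=tt) for tt in t]
        flow = time_averaged_flow(maps, [tr], vesicle)
        truth = omega * 18.0 * 1e3  # nm/s
        ok = flow.counts > 0
        assert np.all(np.abs(flow.v_phi[ok] - truth) / truth < 0.01)
        assert np.all(np.abs(flow.v_theta[ok]) < 0.01 * truth)

    def test_static_track_zero_field(self, vesicle):
        t = np.arange(5) * 10.0
        tr = self._track_from_angles(t, np.full(5, 1.0), np.full(5, 2.0))
        maps = [EquirectMap(np.ones((30, 60)), vesicle, time_s=tt) for tt in t]
        flow = time_averaged_flow(maps, [tr], vesicle)
        ok = flow.counts > 0
        assert np.all(flow.speed[ok] == 0.0)

    def test_counter_rotating_vortices_oppose(self, vesicle):
        t = np.arange(15) * 10.0
        omega = 2e-3
        up = self._track_from_angles(t, np.full(15, np.radians(55)), omega * t)
        down = self._track_from_angles(t, np.full(15, np.radians(125)),
                                       1.0 - omega * t)
        maps = [EquirectMap(np.ones((30, 60)), vesicle, time_s=tt) for tt in t]
        flow = time_averaged_flow(maps, [up, down], vesicle, grid_shape=(4, 1))
        band_up = np.nanmean(flow.v_phi[1])
        band_down = np.nanmean(flow.v_phi[2])
        assert band_up > 0 > band_down

    def test_no_tracks_rejected(self, vesicle):
        maps = [EquirectMap(np.ones((30, 60)), vesicle, time_s=0.0)]
        with pytest.raises(ValueError, match="no tracks"):
            time_averaged_flow(maps, [], vesicle)
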