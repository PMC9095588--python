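"""Scene generators: lengths, trajectories, jammed defects, renderers."""

import numpy as np
import pytest

from glidesphere.defects import (configuration_series, mean_pair_angle,
                                 validate_poincare_hopf)
from glidesphere.dynamics import instantaneous_speeds, mean_speed
from glidesphere.projection import (latitude_intensity_profile,
                                    project_equirectangular)
from glidesphere.synthetic import (SceneSpec, StructureSpec,
                                   fixture_suite, make_jammed_scene,
                                   make_structure_trajectory, render_equirect,
                                   render_stack, sample_filament_lengths)


class TestFilamentLengths:
    def test_positive_and_reproducible(self):
        a = sample_filament_lengths(1000, seed=3)
        b = sample_filament_lengths(1000, seed=3)
        assert np.all(a > 0)
        np.testing.assert_array_equal(a, b)

    def test_mode_matches_request(self):
        """Histogram mode of 1e5 samples sits at the requested 0.6 um."""
        x = sample_filament_lengths(100_000, mode_um=0.6, sigma_log=0.5,
                                    seed=0)
        hist, edges = np.histogram(x, bins=np.arange(0.0, 5.0, 0.02))
        mode = edges[np.argmax(hist)] + 0.01
        assert 0.55 <= mode <= 0.65

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            sample_filament_lengths(0)
        with pytest.raises(ValueError):
            sample_filament_lengths(10, mode_um=-1.0)


class TestStructureTrajectory:
    def test_azimuthal_rate_closed_form(self, vesicle):
        scene = SceneSpec(geometry=vesicle, n_frames=5, seed=0)
        spec = StructureSpec(kind="vortex", theta0_rad=np.pi / 2,
                             speed_nm_s=45.0)
        _, truth = make_structure_trajectory(spec, scene)
        assert truth["omega_rad_s"] == pytest.approx(45e-3 / 18.0)  # 2.5e-3

    def test_zero_speed_is_static(self, vesicle):
        scene = SceneSpec(geometry=vesicle, n_frames=5, seed=0)
        spec = StructureSpec(kind="stream", theta0_rad=1.0, speed_nm_s=0.0,
                             arc_length_um=10.0)
        traj, _ = make_structure_trajectory(spec, scene)
        assert np.ptp(traj.positions, axis=0).max() == 0.0

    def test_pipeline_identity_recovers_speed(self, vesicle):
        scene = SceneSpec(geometry=vesicle, dt_s=10.0, n_frames=100, seed=0,
                          noise_intensity_sd=0.0)
        spec = StructureSpec(kind="vortex", theta0_rad=np.radians(75),
                             speed_nm_s=46.0)
        traj, _ = make_structure_trajectory(spec, scene)
        m, _ = mean_speed(instantaneous_speeds(traj))
        assert m == pytest.approx(46.0, rel=1e-3)

    def test_polar_circle_with_speed_rejected(self, vesicle):
        scene = SceneSpec(geometry=vesicle, n_frames=5, seed=0)
        spec = StructureSpec(kind="vortex", theta0_rad=0.0, speed_nm_s=45.0)
        with pytest.raises(ValueError, match="degenerate"):
            make_structure_trajectory(spec, scene)


class TestJammedScene:
    def test_zero_diffusion_is_frozen(self, vesicle):
        scene = SceneSpec(geometry=vesicle, dt_s=60.0, n_frames=10, seed=2)
        jam = make_jammed_scene(scene, D_um2_s=0.0)
        for tr in jam.trajectories:
            assert np.all(instantaneous_speeds(tr).speeds == 0.0)
        series = configuration_series(list(jam.trajectories))
        assert series.temporal_std_deg == 0.0

    def test_tetrahedral_initialization_exact(self, vesicle):
        scene = SceneSpec(geometry=vesicle, dt_s=60.0, n_frames=3, seed=4)
        jam = make_jammed_scene(scene)
        assert round(mean_pair_angle(jam.configuration_at(0)), 1) == 109.5

    def test_default_diffusion_speed_scale(self, vesicle):
        """D = 1e-4 um^2/s at dt = 60 s gives ~sqrt(pi D dt)/dt ~ 2.3 nm/s."""
        scene = SceneSpec(geometry=vesicle, dt_s=60.0, n_frames=30, seed=1)
        jam = make_jammed_scene(scene, D_um2_s=1e-4)
        speeds = [mean_speed(instantaneous_speeds(tr))[0]
                  for tr in jam.trajectories]
        expected = np.sqrt(np.pi * 1e-4 * 60) / 60 * 1e3
        assert np.mean(speeds) == pytest.approx(expected, rel=0.25)
        assert np.mean(speeds) <= 5.0

    def test_bad_charge_sum_flagged_downstream(self, vesicle):
        scene = SceneSpec(geometry=vesicle, dt_s=60.0, n_frames=3, seed=0)
        jam = make_jammed_scene(scene, charges=("+1/2",) * 3 + ("-1/2",))
        res = validate_poincare_hopf(jam.configuration_at(0))
        assert not res.ok

    def test_wrong_defect_count_rejected(self, vesicle):
        scene = SceneSpec(geometry=vesicle, n_frames=3, seed=0)
        with pytest.raises(ValueError, match="4 defects"):
            make_jammed_scene(scene, charges=("+1", "+1"))


class TestRenderEquirect:
    def test_point_structure_max_at_its_pixel(self, vesicle):
        theta0, phi0 = np.radians(55), np.radians(123)
        scene = SceneSpec(geometry=vesicle, n_frames=1, seed=0,
                          noise_intensity_sd=0.0,
                          structures=(StructureSpec(
                              kind="stream", theta0_rad=theta0,
                              speed_nm_s=0.0, arc_length_um=0.01,
                              phase0_rad=phi0, modulation_depth=0.0),))
        emap = render_equirect(scene, 0, 90, 180)
        i, j = np.unravel_index(np.argmax(emap.data), emap.data.shape)
        assert emap.theta_centers[i] == pytest.approx(theta0, abs=np.pi / 90)
        assert emap.phi_centers[j] == pytest.approx(phi0, abs=np.pi / 90)

    def test_band_profile_peaks_at_equator(self, vesicle):
        scene = SceneSpec(geometry=vesicle, n_frames=1, seed=0,
                          noise_intensity_sd=0.0,
                          structures=(StructureSpec(kind="band",
                                                    speed_nm_s=40.0),))
        emap = render_equirect(scene, 0, 90, 180)
        prof = latitude_intensity_profile(emap)
        assert abs(prof.peak_theta() - np.pi / 2) <= np.pi / 90

    def test_fixed_seed_is_bitwise_reproducible(self, vesicle):
        scene = SceneSpec(geometry=vesicle, n_frames=2, seed=9,
                          noise_intensity_sd=0.05,
                          structures=(StructureSpec(kind="vortex",
                                                    theta0_rad=1.0,
                                                    speed_nm_s=45.0),))
        a = render_equirect(scene, 1, 60, 120)
        b = render_equirect(scene, 1, 60, 120)
        np.testing.assert_array_equal(a.data, b.data)


class TestRenderStack:
    def test_plain_shell_fit_recovery(self, vesicle):
        from glidesphere.projection import fit_sphere
        scene = SceneSpec(geometry=vesicle, n_frames=1, seed=0,
                          noise_intensity_sd=0.0)
        stack = render_stack(scene, 0, voxel_um=0.6)
        fit = fit_sphere(stack)
        assert abs(fit.geometry.radius - 18.0) < 0.6

    def test_blob_brightest_voxel_near_truth(self, vesicle):
        theta0, phi0 = np.radians(90), 0.0
        scene = SceneSpec(geometry=vesicle, n_frames=1, seed=0,
                          noise_intensity_sd=0.0,
                          structures=(StructureSpec(
                              kind="stream", theta0_rad=theta0,
                              speed_nm_s=0.0, arc_length_um=0.01,
                              phase0_rad=phi0, modulation_depth=0.0,
                              amplitude=5.0),))
        stack = render_stack(scene, 0, voxel_um=0.6)
        k, j, i = np.unravel_index(np.argmax(stack.data), stack.data.shape)
        pos = stack.index_to_world(np.array([k, j, i], dtype=float))
        np.testing.assert_allclose(pos, [18.0, 0.0, 0.0], atol=0.9)

    def test_stack_projection_matches_direct_render(self, vesicle):
        """Voxelize-then-project agrees with the direct map renderer."""
        scene = SceneSpec(geometry=vesicle, n_frames=1, seed=6,
                          noise_intensity_sd=0.0,
                          structures=(StructureSpec(kind="vortex",
                                                    theta0_rad=np.radians(60),
                                                    speed_nm_s=45.0),))
        stack = render_stack(scene, 0, voxel_um=0.5, background=0.0)
        via_stack = project_equirectangular(stack, vesicle, n_theta=60,
                                            n_phi=120)
        direct = render_equirect(scene, 0, 60, 120)
        r = np.corrcoef(via_stack.data.ravel(), direct.data.ravel())[0, 1]
        assert r > 0.9

    def test_undersized_bounds_rejected(self, vesicle):
        scene = SceneSpec(geometry=vesicle, n_frames=1, seed=0)
        with pytest.raises(ValueError, match="bounds"):
            render_stack(scene, 0, voxel_um=1.0, shape=(10, 10, 10),
                         origin=np.array([-5.0, -5.0, -5.0]))


class TestFixtureSuite:
    def test_contains_all_five_labels(self):
        suite = fixture_suite(seed=0, n_per_class=1, n_frames=4)
        assert {f.label for f in suite} == {
            "stream", "vortex", "band", "partially_jammed", "globally_jammed"}

    def test_band_defects_satisfy_poincare_hopf(self):
        suite = fixture_suite(seed=0, n_per_class=1, n_frames=4)
        band = next(f for f in suite if f.label == "band")
        assert validate_poincare_hopf(band.defect_configuration(0)).ok

    def test_jammed_pair_angles_stable_over_30_frames(self):
        suite = fixture_suite(seed=0, n_per_class=1, n_frames=30)
        jam = next(f for f in suite if f.label == "globally_jammed")
        series = configuration_series(list(jam.defect_tracks))
        assert series.temporal_std_deg < 2.0

    def test_suite_is_deterministic(self):
        a = fixture_suite(seed=3, n_per_class=1, n_frames=4)
        b = fixture_suite(seed=3, n_per_class=1, n_frames=4)
        for fa, fb in zip(a, b):
            assert fa.label == fb.label
            for ta, tb in zip(fa.trajectories, fb.trajectories):
                np.testing.assert_array_equal(ta.positions, tb.positions)
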