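"""Generator contracts: geometry oracles, ground-truth consistency,
determinism, and the noise model."""

import numpy as np
import pytest

from limbquant import SceneConfig, synth
from limbquant.synth import _render


class TestRenderTube:
    def test_straight_cylinder_volume_matches_analytic(self):
        # diameter 20 µm, length 100 µm, isotropic 1 µm voxels
        grid = synth.render_tube(
            (120, 40, 40), (1.0, 1.0, 1.0), [(20, 20, 10), (20, 20, 110)], 20.0
        )
        expected = np.pi * 10.0**2 * 100.0
        assert abs(grid.sum() - expected) / expected < 0.02

    def test_bent_tube_has_no_groove_at_the_joint(self):
        # the inscribed-sphere diameter at a gentle bend must stay ~ d
        from limbquant.vessels import VesselMask, local_diameter

        poly = [(10, 30, 30), (60, 30, 30), (105, 45, 30)]
        grid = synth.render_tube((60, 60, 120), (1.0, 1.0, 1.0), poly, 20.0)
        dmap = local_diameter(VesselMask(grid, (1.0, 1.0, 1.0)))
        assert np.nanmedian(dmap) > 17.0

    def test_invalid_polyline_rejected(self):
        with pytest.raises(ValueError):
            synth.render_tube((10, 10, 10), (1, 1, 1), [(1, 1, 1)], 5.0)


class TestVesselScene:
    def test_class_means_ordered_with_default_rates(self, validation_scene):
        _, truth = synth.generate_vessel_scene(validation_scene)
        means = truth.class_mean_delta()
        assert means["small"] > means["mid"] > means["large"]

    def test_zero_rates_give_identical_sessions(self, validation_scene):
        _, truth = synth.generate_vessel_scene(
            validation_scene, remodel_rates={"small": 0.0, "mid": 0.0, "large": 0.0}
        )
        np.testing.assert_array_equal(truth.label_fields[0], truth.label_fields[1])
        assert all(v.true_delta_norm == 0.0 for v in truth.vessels)

    def test_ground_truth_matches_recount_from_masks(self, validation_scene):
        # single vessel: union label field is the vessel's own mask
        _, truth = synth.generate_vessel_scene(
            validation_scene, n_per_class={"small": 0, "mid": 1, "large": 0}
        )
        m0, m1 = truth.label_fields
        recount = np.logical_xor(m0, m1).sum() / m1.sum()
        assert recount == pytest.approx(truth.vessels[0].true_delta_norm, abs=1e-12)

    def test_calibration_recovers_rates_at_default_scale(self):
        # generator truth, default acquisition geometry, 10 seeds
        rates = {"small": 0.4, "mid": 0.15, "large": 0.05}
        sums = {k: [] for k in rates}
        for seed in range(10):
            _, truth = synth.generate_vessel_scene(SceneConfig(seed=seed), rates)
            for v in truth.vessels:
                sums[v.class_label].append(v.true_delta_norm)
        for cls, rate in rates.items():
            mean = np.mean(sums[cls])
            assert abs(mean - rate) / rate < 0.25, (cls, mean)

    def test_deterministic_given_seed(self, validation_scene):
        s1, t1 = synth.generate_vessel_scene(validation_scene)
        s2, t2 = synth.generate_vessel_scene(validation_scene)
        np.testing.assert_array_equal(s1.data, s2.data)
        np.testing.assert_array_equal(t1.label_fields[0], t2.label_fields[0])
        assert [v.true_delta_norm for v in t1.vessels] == [
            v.true_delta_norm for v in t2.vessels
        ]

    def test_undersampled_scene_refused(self):
        cfg = SceneConfig(
            volume_extent=(100, 100, 60),
            fov_diameter=100,
            voxel_size=(1, 1, 12),
            seed=0,
        )
        with pytest.raises(ValueError, match="undersampled"):
            synth.generate_vessel_scene(
                cfg, diameter_ranges={"small": (9, 14), "mid": (19, 31), "large": (39, 49)}
            )


class TestNoiseModel:
    def test_poisson_plus_read_noise_variance(self, rng):
        lam, read_sd, n = 40.0, 2.0, 10_000
        field = np.full(n, lam)
        out = _render.apply_noise(field, rng, read_sd)
        expected = lam + read_sd**2
        assert abs(out.var() - expected) / expected < 0.10

    def test_signal_amplitude_hits_snr_target(self):
        cfg = SceneConfig(seed=0)
        amp = _render.signal_amplitude(cfg)
        bg_sd = np.sqrt(cfg.background + cfg.read_noise_sd**2)
        assert (amp + cfg.background) / bg_sd == pytest.approx(cfg.snr_target)


class TestCellScene:
    def test_counts_and_volume_classes(self, small_scene):
        cfg = SceneConfig(**{**small_scene.to_dict(), "seed": 7})
        _, truth = synth.generate_cell_scene(cfg, n_b=20, n_pc=10)
        assert len(truth.cells) == 30
        assert sum(c.volume < 500.0 for c in truth.cells) == 20
        assert truth.n_b == 20 and truth.n_pc == 10

    def test_zero_speed_means_zero_displacement(self, small_scene):
        motion = synth.MotionParams(b_speed=0.0, pc_jitter_sd=0.0)
        _, truth = synth.generate_cell_scene(small_scene, n_b=5, n_pc=3, motion=motion)
        for c in truth.cells:
            assert np.linalg.norm(c.trajectory[-1] - c.trajectory[0]) == 0.0

    def test_b_cell_step_length_matches_speed(self):
        # 4 µm/min at 30 s frames -> 2 µm per frame
        cfg = SceneConfig(
            volume_extent=(200, 200, 60),
            fov_diameter=200,
            voxel_size=(1, 1, 3),
            n_frames=90,
            frame_interval=30.0,
            seed=5,
        )
        _, truth = synth.generate_cell_scene(
            cfg, n_b=10, n_pc=0, motion=synth.MotionParams(b_speed=4.0)
        )
        steps = np.concatenate(
            [
                np.linalg.norm(np.diff(c.trajectory, axis=0), axis=1)
                for c in truth.cells
            ]
        )
        assert steps.mean() == pytest.approx(2.0, rel=0.05)

    def test_trajectories_stay_inside_volume(self, small_scene):
        _, truth = synth.generate_cell_scene(small_scene, n_b=10, n_pc=5)
        ex, ey, ez = small_scene.volume_extent
        for c in truth.cells:
            assert (c.trajectory >= 0).all()
            assert (c.trajectory <= [ex, ey, ez]).all()

    def test_excessive_step_refused(self, small_scene):
        with pytest.raises(ValueError, match="step"):
            synth.generate_cell_scene(
                small_scene, n_b=1, n_pc=0, motion=synth.MotionParams(b_speed=1e5)
            )


class TestPhotoactivationScene:
    def _config(self, seed=2):
        return SceneConfig(
            volume_extent=(120, 120, 60),
            fov_diameter=120,
            voxel_size=(1, 1, 3),
            seed=seed,
        )

    def test_noiseless_fold_increase_is_exact(self):
        stack, truth = synth.generate_photoactivation_scene(
            self._config(), roi_extent=(75, 75, 30), degrade=False
        )
        pre = stack.frame(0)[truth.roi_slices].mean()
        post = stack.frame(1)[truth.roi_slices].mean()
        assert post / pre == pytest.approx(100.0)

    def test_zero_decay_keeps_roi_constant(self):
        stack, truth = synth.generate_photoactivation_scene(
            self._config(), turnover_rate=0.0, emigration_rate=0.0, degrade=False
        )
        means = [stack.frame(t)[truth.roi_slices].mean() for t in range(1, stack.n_frames)]
        assert np.ptp(means) == 0.0

    def test_half_life_twelve_hours_leaves_an_eighth_at_36h(self):
        stack, truth = synth.generate_photoactivation_scene(
            self._config(),
            turnover_rate=np.log(2) / 12.0,
            session_hours=(0.0, 12.0, 24.0, 36.0),
            degrade=False,
        )
        first = stack.frame(1)[truth.roi_slices].mean()
        last = stack.frame(4)[truth.roi_slices].mean()
        assert last / first == pytest.approx(0.125)

    def test_fold_below_one_refused(self):
        with pytest.raises(ValueError):
            synth.generate_photoactivation_scene(self._config(), fold_increase=0.5)

    def test_oversized_roi_refused(self):
        with pytest.raises(ValueError):
            synth.generate_photoactivation_scene(self._config(), roi_extent=(200, 75, 30))


class TestCTPhantom:
    def test_noiseless_profile_is_sum_of_two_gaussians(self):
        grid, truth = synth.generate_ct_phantom((200.0, 250.0), 1500.0, 10.5, 0.0)
        x = (np.arange(grid.shape[2]) + 0.5) * truth.voxel
        s1 = truth.wall_fwhm[0] / (2 * np.sqrt(2 * np.log(2)))
        s2 = truth.wall_fwhm[1] / (2 * np.sqrt(2 * np.log(2)))
        expected = truth.amplitudes[0] * np.exp(
            -((x - truth.wall_centers[0]) ** 2) / (2 * s1**2)
        ) + truth.amplitudes[1] * np.exp(-((x - truth.wall_centers[1]) ** 2) / (2 * s2**2))
        np.testing.assert_allclose(grid[0, 0, :], expected, rtol=1e-12)

    def test_equal_walls_give_symmetric_profile(self):
        grid, truth = synth.generate_ct_phantom(
            (200.0, 200.0), 1500.0, 10.5, 0.0, amplitudes=(1000.0, 1000.0)
        )
        profile = grid[0, 0, :]
        mid = (truth.wall_centers[0] + truth.wall_centers[1]) / 2.0
        x = (np.arange(len(profile)) + 0.5) * truth.voxel
        # mirror the sample positions about the midpoint and interpolate;
        # linear interpolation on the 10.5 µm grid limits the agreement
        mirrored = np.interp(2 * mid - x, x, profile)
        sel = profile > 1.0  # ignore far tails (pure interpolation noise)
        np.testing.assert_allclose(profile[sel], mirrored[sel], atol=6.0)

    def test_coarse_voxel_refused(self):
        with pytest.raises(ValueError, match="voxel"):
            synth.generate_ct_phantom((100.0, 250.0), 1500.0, 60.0, 0.0)

    def test_touching_walls_refused(self):
        with pytest.raises(ValueError, match="separation"):
            synth.generate_ct_phantom((200.0, 250.0), 400.0, 10.5, 0.0)


class TestBeadStack:
    def test_bead_count_and_separation(self):
        stack, truth = synth.generate_bead_stack(23, seed=3, min_separation=8.0)
        assert len(truth.centroids) == 23
        d = truth.centroids[:, None, :] - truth.centroids[None, :, :]
        dist = np.sqrt((d**2).sum(axis=2))
        np.fill_diagonal(dist, np.inf)
        assert dist.min() >= 8.0

    def test_deterministic(self):
        s1, t1 = synth.generate_bead_stack(5, seed=9, noise=True)
        s2, t2 = synth.generate_bead_stack(5, seed=9, noise=True)
        np.testing.assert_array_equal(s1.data, s2.data)
        np.testing.assert_array_equal(t1.centroids, t2.centroids)
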