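"""Segmentation, local diameter, and the remodeling statistic."""

import numpy as np
import pytest

from limbquant import SceneConfig, synth, vessels
from limbquant.containers import TimeLapseVolume
from limbquant.synth import _render
from limbquant.vessels import (
    VesselMask,
    compare_classes,
    local_diameter,
    pair_sessions,
    remodeling_statistic,
    segment_vessels,
)


def _mask(arr, voxel=(1.0, 1.0, 1.0)):
    return VesselMask(mask=np.asarray(arr, dtype=bool), voxel_size=voxel)


def brute_force_delta(m0, m1):
    """Independent oracle: voxel-by-voxel count of the toy statistic."""
    appear = disappear = v_t1 = 0
    for idx in np.ndindex(m0.shape):
        a, b = bool(m0[idx]), bool(m1[idx])
        if b:
            v_t1 += 1
        if b and not a:
            appear += 1
        if a and not b:
            disappear += 1
    return (appear + disappear) / v_t1


class TestRemodelingStatistic:
    def test_toy_fixture_matches_hand_count(self):
        # 100 voxels at t0, 120 at t1, 90 shared -> delta = 40/120
        m0 = np.zeros((1, 10, 20), dtype=bool)
        m1 = np.zeros((1, 10, 20), dtype=bool)
        m0.flat[:100] = True
        m1.flat[10:130] = True  # shares 90 of t0's voxels
        assert (m0 & m1).sum() == 90 and m0.sum() == 100 and m1.sum() == 120
        pair = pair_sessions(_mask(m0), _mask(m1))
        records, _ = remodeling_statistic(pair, dmap_t1=np.full(m0.shape, 10.0))
        (rec,) = records
        assert rec.volume_appear == 30.0
        assert rec.volume_disappear == 10.0
        assert rec.delta_norm == pytest.approx(40.0 / 120.0)
        assert rec.delta_norm == pytest.approx(brute_force_delta(m0, m1))

    def test_matches_brute_force_on_random_masks(self, rng):
        for _ in range(5):
            m0 = rng.random((6, 8, 8)) < 0.4
            m1 = rng.random((6, 8, 8)) < 0.4
            m0[0, 0, 0] = m1[0, 0, 0] = True  # keep t1 non-empty
            pair = pair_sessions(_mask(m0), _mask(m1))
            records, _ = remodeling_statistic(pair, dmap_t1=np.full(m0.shape, 10.0))
            union_total = sum(r.volume_appear + r.volume_disappear for r in records)
            v1_total = sum(r.volume_t1 for r in records)
            assert union_total / v1_total == pytest.approx(brute_force_delta(m0, m1))

    def test_identical_masks_give_zero_change(self, rng):
        m = rng.random((5, 10, 10)) < 0.3
        m[2, 5, 5] = True
        pair = pair_sessions(_mask(m), _mask(m))
        assert not pair.appearance.any() and not pair.disappearance.any()
        records, _ = remodeling_statistic(pair, dmap_t1=np.full(m.shape, 10.0))
        assert all(r.delta_norm == 0.0 for r in records)

    def test_disjoint_masks_split_into_appearance_and_disappearance(self):
        m0 = np.zeros((3, 6, 6), dtype=bool)
        m1 = np.zeros((3, 6, 6), dtype=bool)
        m0[0, :2, :2] = True
        m1[2, 4:, 4:] = True
        pair = pair_sessions(_mask(m0), _mask(m1))
        np.testing.assert_array_equal(pair.appearance, m1)
        np.testing.assert_array_equal(pair.disappearance, m0)

    def test_symmetric_difference_invariant_under_session_swap(self, rng):
        m0 = rng.random((5, 9, 9)) < 0.35
        m1 = rng.random((5, 9, 9)) < 0.35
        p_fwd = pair_sessions(_mask(m0), _mask(m1))
        p_rev = pair_sessions(_mask(m1), _mask(m0))
        sym_fwd = (p_fwd.appearance | p_fwd.disappearance).sum()
        sym_rev = (p_rev.appearance | p_rev.disappearance).sum()
        assert sym_fwd == sym_rev

    def test_delta_invariant_under_uniform_voxel_rescale(self, rng):
        m0 = rng.random((5, 9, 9)) < 0.35
        m1 = rng.random((5, 9, 9)) < 0.35
        m1[0, 0, 0] = True
        dmap = np.full(m0.shape, 10.0)
        r1, _ = remodeling_statistic(pair_sessions(_mask(m0), _mask(m1)), dmap)
        r2, _ = remodeling_statistic(
            pair_sessions(_mask(m0, (3, 3, 3)), _mask(m1, (3, 3, 3))), dmap
        )
        d1 = [r.delta_norm for r in r1]
        d2 = [r.delta_norm for r in r2]
        np.testing.assert_allclose(d1, d2)

    def test_fully_disappeared_component_is_tallied_not_averaged(self):
        m0 = np.zeros((3, 8, 8), dtype=bool)
        m0[1, 1:3, 1:3] = True
        m1 = np.zeros_like(m0)
        m1[1, 6:8, 6:8] = True
        pair = pair_sessions(_mask(m0), _mask(m1))
        records, summary = remodeling_statistic(pair, np.full(m0.shape, 10.0))
        gone = [r for r in records if r.fully_disappeared]
        assert len(gone) == 1
        assert np.isnan(gone[0].delta_norm)
        assert summary.loc[summary["class"] == "small", "n"].item() == 1

    def test_signed_variant_tracks_net_change(self):
        m0 = np.zeros((1, 4, 10), dtype=bool)
        m1 = np.zeros_like(m0)
        m0[0, :, :6] = True
        m1[0, :, :8] = True  # pure growth
        pair = pair_sessions(_mask(m0), _mask(m1))
        records, _ = remodeling_statistic(pair, np.full(m0.shape, 10.0))
        (rec,) = records
        assert rec.delta_signed == pytest.approx(rec.delta_norm)
        pair_rev = pair_sessions(_mask(m1), _mask(m0))
        records_rev, _ = remodeling_statistic(pair_rev, np.full(m0.shape, 10.0))
        assert records_rev[0].delta_signed < 0


class TestPairSessions:
    def test_translation_registration_recovers_constructed_shift(self):
        m0 = np.zeros((8, 24, 24), dtype=bool)
        m0[2:6, 4:12, 4:12] = True
        m1 = np.roll(m0, 3, axis=2)  # shift +3 voxels in x
        pair = pair_sessions(_mask(m0), _mask(m1), registration="translation")
        assert pair.shift_voxels == (0, 0, -3)
        assert not pair.appearance.any() and not pair.disappearance.any()

    def test_shape_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="shape"):
            pair_sessions(_mask(np.zeros((2, 3, 3))), _mask(np.zeros((2, 4, 4))))

    def test_unknown_registration_rejected(self):
        m = _mask(np.ones((2, 3, 3)))
        with pytest.raises(ValueError, match="registration"):
            pair_sessions(m, m, registration="affine")


class TestLocalDiameter:
    def test_cylinder_median_matches_diameter(self):
        grid = synth.render_tube(
            (40, 40, 120), (1.0, 1.0, 1.0), [(10, 20, 20), (110, 20, 20)], 20.0
        )
        dmap = local_diameter(_mask(grid))
        assert np.nanmedian(dmap) == pytest.approx(20.0, abs=1.0)

    def test_single_voxel_clamped_to_voxel_size(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[2, 2, 2] = True
        dmap = local_diameter(_mask(m, (0.7, 0.7, 6.0)))
        assert dmap[2, 2, 2] == pytest.approx(0.7)

    def test_dilation_never_shrinks_diameters(self):
        from scipy import ndimage

        grid = synth.render_tube(
            (30, 30, 80), (1.0, 1.0, 1.0), [(10, 15, 15), (70, 15, 15)], 12.0
        )
        d0 = local_diameter(_mask(grid))
        dilated = ndimage.binary_dilation(grid)
        d1 = local_diameter(_mask(dilated))
        inner = grid & ~np.isnan(d0)
        diff = d1[inner] - d0[inner]
        assert np.nanmin(diff) >= -1e-9
        assert np.nanmax(diff) <= 2.0 + 1e-9

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            local_diameter(_mask(np.zeros((3, 3, 3))))


class TestSegmentation:
    def test_noiseless_scene_recovers_truth_mask(self, validation_scene):
        stack, truth = synth.generate_vessel_scene(validation_scene, degrade=False)
        got = segment_vessels(stack, frame=0, smoothing_fwhm=0.0)
        fov = _render.fov_mask(
            truth.label_fields[0].shape,
            validation_scene.voxel_size,
            validation_scene.fov_diameter,
        )
        want = truth.label_fields[0] & fov[None, :, :]
        jacc = (got.mask & want).sum() / (got.mask | want).sum()
        assert jacc >= 0.9

    def test_all_zero_stack_gives_empty_mask(self):
        stack = TimeLapseVolume(data=np.zeros((4, 20, 20)), voxel_size=(1, 1, 2))
        assert not segment_vessels(stack).mask.any()

    def test_robust_to_noise_realization(self, validation_scene):
        _, truth = synth.generate_vessel_scene(validation_scene, degrade=False)
        masks = []
        for noise_seed in (101, 202):
            rng = np.random.default_rng(noise_seed)
            img = _render.form_image(truth.label_fields[0], validation_scene, rng)
            stack = TimeLapseVolume(data=img[None], voxel_size=validation_scene.voxel_size)
            masks.append(segment_vessels(stack, frame=0).mask)
        jacc = (masks[0] & masks[1]).sum() / (masks[0] | masks[1]).sum()
        assert jacc >= 0.8


class TestCompareClasses:
    def _records(self, values_by_class):
        out = []
        i = 0
        for cls, vals in values_by_class.items():
            for v in vals:
                out.append(
                    vessels.RemodelingRecord(
                        component_id=i,
                        class_label=cls,
                        median_diameter={"small": 10, "mid": 25, "large": 40}[cls],
                        volume_t1=100.0,
                        volume_appear=v * 100.0,
                        volume_disappear=0.0,
                    )
                )
                i += 1
        return out

    def test_identical_groups_do_not_reject(self):
        recs = self._records({"small": [0.1, 0.2, 0.3], "mid": [0.1, 0.2, 0.3]})
        cmp_ = compare_classes(recs)
        assert cmp_.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert cmp_.p_value == pytest.approx(1.0)

    def test_separated_groups_reject_strongly(self, rng):
        rejections = 0
        for _ in range(50):
            recs = self._records(
                {
                    "small": rng.normal(0.4, 0.05, 20),
                    "mid": rng.normal(0.15, 0.05, 20),
                    "large": rng.normal(0.05, 0.05, 20),
                }
            )
            if compare_classes(recs).p_value < 0.001:
                rejections += 1
        assert rejections >= 48

    def test_pairwise_bonferroni_reported(self, rng):
        recs = self._records(
            {
                "small": rng.normal(0.4, 0.05, 10),
                "mid": rng.normal(0.15, 0.05, 10),
                "large": rng.normal(0.05, 0.05, 10),
            }
        )
        cmp_ = compare_classes(recs)
        assert len(cmp_.pairwise) == 3
        assert (cmp_.pairwise["p_bonferroni"] >= cmp_.pairwise["p_raw"] - 1e-15).all()

    def test_single_usable_class_is_an_error(self):
        recs = self._records({"small": [0.1, 0.2], "mid": [0.3]})
        with pytest.raises(ValueError):
            compare_classes(recs)
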