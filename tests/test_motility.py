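"""Cell detection, classification, linking, filtering, and motility."""

import itertools

import numpy as np
import pytest

from limbquant import SceneConfig, motility, synth
from limbquant.containers import TimeLapseVolume
from limbquant.motility import (
    B_CELL,
    PLASMA_CELL,
    CellDetection,
    Track,
    classify_cell,
    compare_groups,
    detect_cells,
    filter_tracks,
    link_tracks,
    motility_metrics,
)


def _det(frame, x, y=0.0, z=0.0, volume=100.0):
    return CellDetection(frame=frame, centroid=(x, y, z), volume=volume, mean_intensity=1.0)


class TestDetectCells:
    def test_recovers_sphere_count_and_volumes(self):
        cfg = SceneConfig(
            volume_extent=(200, 200, 60),
            fov_diameter=200,
            voxel_size=(1, 1, 2),
            n_frames=1,
            seed=13,
        )
        stack, truth = synth.generate_cell_scene(cfg, n_b=20, n_pc=10, degrade=False)
        dets = detect_cells(stack, frame=0, smoothing_fwhm=0.0, threshold=0.5)
        assert len(dets) == 30
        got = np.sort([d.volume for d in dets])
        want = np.sort([c.volume for c in truth.cells])
        np.testing.assert_allclose(got, want, rtol=0.10)

    def test_empty_frame_yields_no_detections(self):
        stack = TimeLapseVolume(data=np.zeros((10, 30, 30)), voxel_size=(1, 1, 2))
        assert detect_cells(stack) == []

    def test_touching_spheres_split_by_watershed(self):
        shape = (24, 40, 60)
        labels = np.zeros(shape, dtype=bool)
        synth.render_ball(labels, (1.0, 1.0, 1.0), (22.0, 20.0, 12.0), 6.0)
        synth.render_ball(labels, (1.0, 1.0, 1.0), (33.0, 20.0, 12.0), 6.0)
        # overlap by ~1 voxel layer; give the pair a two-peaked intensity
        data = np.zeros(shape)
        data[labels] = 50.0
        for cx in (22.0, 33.0):
            k, j, i = 12, 20, int(cx)
            data[k - 2 : k + 3, j - 2 : j + 3, i - 2 : i + 3] += 30.0
        stack = TimeLapseVolume(data=data, voxel_size=(1.0, 1.0, 1.0))
        dets = detect_cells(
            stack, smoothing_fwhm=1.0, threshold=10.0, peak_min_distance=6.0
        )
        assert len(dets) == 2


class TestClassifyCell:
    @pytest.mark.parametrize(
        "volume,label",
        [(400.0, B_CELL), (600.0, PLASMA_CELL), (500.0, B_CELL), (1e-6, B_CELL)],
    )
    def test_boundary(self, volume, label):
        assert classify_cell(volume) == label

    def test_ten_micron_sphere_sits_at_the_boundary(self):
        volume = 4.0 / 3.0 * np.pi * 5.0**3
        assert volume == pytest.approx(523.6, abs=0.05)
        assert round(volume, -2) == 500.0  # ~500 µm³ to the nearest hundred

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            classify_cell(0.0)


class TestLinkTracks:
    def test_two_stationary_cells_give_two_full_tracks(self):
        frames = [[_det(t, 0.0), _det(t, 50.0)] for t in range(10)]
        tracks = link_tracks(frames)
        assert len(tracks) == 2
        assert all(t.n_timepoints == 10 for t in tracks)

    def test_matches_exhaustive_assignment_on_small_instance(self, rng):
        # 3 well-separated drifting cells over 4 frames
        base = np.array([[0.0, 0, 0], [40.0, 0, 0], [0.0, 40, 0]])
        frames = []
        for t in range(4):
            pos = base + t * np.array([1.5, -1.0, 0.5]) + rng.normal(0, 0.3, base.shape)
            frames.append(
                [_det(t, *p) for p in pos]
            )
        tracks = link_tracks(frames, max_step=10.0, max_gap=0)
        assert len(tracks) == 3
        # oracle: per-frame minimal-total-distance assignment
        oracle_paths = [[d] for d in frames[0]]
        for t in range(1, 4):
            prev = [p[-1] for p in oracle_paths]
            best, best_cost = None, np.inf
            for perm in itertools.permutations(range(3)):
                cost = sum(
                    np.linalg.norm(
                        np.array(prev[i].centroid) - np.array(frames[t][perm[i]].centroid)
                    )
                    for i in range(3)
                )
                if cost < best_cost:
                    best, best_cost = perm, cost
            for i in range(3):
                oracle_paths[i].append(frames[t][best[i]])
        got = {tuple(round(d.centroid[0], 3) for d in t.detections) for t in tracks}
        want = {tuple(round(d.centroid[0], 3) for d in p) for p in oracle_paths}
        assert got == want

    def test_invariant_to_detection_input_order(self, rng):
        frames = []
        for t in range(6):
            dets = [_det(t, x + 0.3 * t, y) for x, y in [(0, 0), (30, 0), (0, 30), (30, 30)]]
            frames.append(dets)
        tracks_a = link_tracks(frames)
        shuffled = [list(rng.permutation(len(f))) for f in frames]
        frames_b = [[f[i] for i in idx] for f, idx in zip(frames, shuffled)]
        tracks_b = link_tracks(frames_b)
        key = lambda tr: sorted((d.frame, d.centroid) for d in tr.detections)
        assert sorted(map(key, tracks_a)) == sorted(map(key, tracks_b))

    def test_gap_bridging(self):
        frames = [[_det(0, 0.0)], [], [_det(2, 2.0)]]
        tracks = link_tracks(frames, max_step=5.0, max_gap=1)
        assert len(tracks) == 1 and tracks[0].n_timepoints == 2
        tracks = link_tracks(frames, max_step=5.0, max_gap=0)
        assert len(tracks) == 2

    def test_ground_truth_identity_agreement(self):
        cfg = SceneConfig(
            volume_extent=(150, 150, 48),
            fov_diameter=150,
            voxel_size=(1, 1, 2),
            n_frames=12,
            seed=7,
        )
        stack, truth = synth.generate_cell_scene(cfg, n_b=8, n_pc=4, degrade=False)
        per_frame = [
            detect_cells(stack, frame=t, smoothing_fwhm=0.0, threshold=0.5)
            for t in range(stack.n_frames)
        ]
        tracks = link_tracks(per_frame)
        # match each track to a ground-truth cell by its start position
        correct = total = 0
        for tr in tracks:
            if tr.n_timepoints < 2:
                continue
            d0 = np.array(tr.detections[0].centroid)
            t0 = tr.detections[0].frame
            cell = min(
                truth.cells, key=lambda c: np.linalg.norm(c.trajectory[t0] - d0)
            )
            for det in tr.detections[1:]:
                total += 1
                if np.linalg.norm(
                    np.array(det.centroid) - cell.trajectory[det.frame]
                ) < 5.0:
                    correct += 1
        assert total > 0 and correct / total >= 0.9


class TestFilterTracks:
    def _track(self, n, tid=0):
        return Track(track_id=tid, detections=[_det(t, float(t)) for t in range(n)])

    def test_ten_timepoints_excluded_eleven_included(self):
        kept = filter_tracks([self._track(10), self._track(11, 1)])
        assert [t.n_timepoints for t in kept] == [11]
        assert kept[0].duration_min(30.0) == pytest.approx(5.0)

    def test_all_retained_tracks_span_at_least_five_minutes(self):
        tracks = [self._track(n, n) for n in range(2, 30)]
        for t in filter_tracks(tracks):
            assert t.duration_min(30.0) >= 5.0

    def test_idempotent(self):
        tracks = [self._track(n, n) for n in (5, 11, 20)]
        once = filter_tracks(tracks)
        assert filter_tracks(once) == once

    def test_empty_input(self):
        assert filter_tracks([]) == []


class TestMotilityMetrics:
    def test_straight_track_velocity_equals_displacement_rate(self):
        # 5 µm per 30 s step -> 10 µm/min, collinear so equality holds
        tr = Track(0, [_det(t, 5.0 * t) for t in range(11)])
        row = motility_metrics(tr, frame_interval=30.0)
        assert row.mean_velocity == pytest.approx(10.0)
        assert row.displacement_rate == pytest.approx(10.0)

    def test_back_and_forth_track_has_zero_displacement_rate(self):
        xs = [0.0, 5.0, 0.0, 5.0, 0.0]
        tr = Track(0, [_det(t, x) for t, x in enumerate(xs)])
        row = motility_metrics(tr, frame_interval=30.0)
        assert row.displacement_rate == pytest.approx(0.0)
        assert row.mean_velocity > 0

    def test_single_point_track_rejected(self):
        with pytest.raises(ValueError):
            motility_metrics(Track(0, [_det(0, 1.0)]), 30.0)

    def test_displacement_rate_never_exceeds_mean_velocity(self, rng):
        for _ in range(50):
            n = rng.integers(2, 15)
            pts = rng.uniform(0, 100, size=(n, 3))
            tr = Track(0, [_det(t, *p) for t, p in enumerate(pts)])
            row = motility_metrics(tr, 30.0)
            assert row.displacement_rate <= row.mean_velocity + 1e-9

    def test_recovers_generator_walk_speed(self):
        cfg = SceneConfig(
            volume_extent=(250, 250, 60),
            fov_diameter=250,
            voxel_size=(1, 1, 3),
            n_frames=50,
            seed=3,
        )
        _, truth = synth.generate_cell_scene(
            cfg, n_b=50, n_pc=0, motion=synth.MotionParams(b_speed=4.0)
        )
        speeds = []
        for c in truth.cells:
            tr = Track(
                c.cell_id,
                [
                    CellDetection(frame=t, centroid=tuple(p), volume=c.volume, mean_intensity=1.0)
                    for t, p in enumerate(c.trajectory)
                ],
            )
            speeds.append(motility_metrics(tr, cfg.frame_interval).mean_velocity)
        assert np.mean(speeds) == pytest.approx(4.0, rel=0.15)


class TestCompareGroups:
    def test_identical_groups_do_not_differ(self):
        g = [1.0, 2.0, 3.0, 4.0]
        cmp_ = compare_groups(g, g)
        assert cmp_.p_value == pytest.approx(1.0)
        assert cmp_.stars == "ns"

    def test_well_separated_groups_reject(self, rng):
        a = rng.normal(4.0, 1.0, 20)
        b = rng.normal(8.0, 1.0, 20)
        cmp_ = compare_groups(a, b)
        assert cmp_.p_value < 0.001
        assert cmp_.stars == "***"

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])
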