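"""Marker tracking: reference color, k-means segmentation, cluster selection,
centroids, and the full per-frame pipeline against synthetic ground truth."""

import numpy as np
import pytest

from oralpdt import (
    ClusterMap,
    DegenerateClusteringWarning,
    FrameSequence,
    InvalidFrameError,
    InvalidRoiError,
    MarkerMask,
    MotionParams,
    ReferenceColor,
    RoiSeed,
    SceneParams,
    TrackingConfig,
    TrackingFailureError,
    Trajectory,
    centroid_of_mask,
    extract_reference_color,
    render_frames,
    segment_frame_kmeans,
    select_marker_cluster,
    simulate_trajectory,
    track_sequence,
)
from oralpdt.tracking import kmeans_plusplus_init, _unique_colors

from conftest import make_video, roi_around
from oracles import brute_force_lloyd, disc_pixel_centroid


def _as_sequence(frame_stack):
    return FrameSequence(np.asarray(frame_stack, dtype=np.uint8), frame_rate=15.0)


class TestReferenceColor:
    def test_uniform_roi(self):
        frame = np.full((20, 20, 3), (30, 30, 120), dtype=np.uint8)
        ref = extract_reference_color(_as_sequence([frame]), RoiSeed(rect=(2, 2, 6, 6)))
        assert ref.rgb == (30.0, 30.0, 120.0)
        assert ref.n_pixels == 36

    def test_two_pixel_average(self):
        frame = np.zeros((1, 2, 3), dtype=np.uint8)
        frame[0, 1] = (60, 60, 240)
        ref = extract_reference_color(_as_sequence([frame]), RoiSeed(rect=(0, 0, 2, 1)))
        assert ref.rgb == (30.0, 30.0, 120.0)

    def test_noisy_roi_mean_converges(self, rng):
        base = np.array([30, 30, 120], dtype=float)
        frame = np.clip(rng.normal(base, 5, size=(100, 100, 3)), 0, 255).astype(np.uint8)
        ref = extract_reference_color(_as_sequence([frame]), RoiSeed(rect=(0, 0, 100, 100)))
        assert np.allclose(ref.rgb, base, atol=1.0)

    def test_out_of_bounds_roi_rejected(self):
        frame = np.zeros((10, 10, 3), dtype=np.uint8)
        with pytest.raises(InvalidRoiError):
            extract_reference_color(_as_sequence([frame]), RoiSeed(rect=(8, 8, 5, 5)))

    def test_empty_mask_roi_rejected(self):
        frame = np.zeros((10, 10, 3), dtype=np.uint8)
        with pytest.raises(InvalidRoiError):
            extract_reference_color(
                _as_sequence([frame]), RoiSeed(mask=np.zeros((10, 10), dtype=bool)))


class TestSegmentFrameKmeans:
    def test_two_exact_colors_separate_perfectly(self):
        frame = np.full((10, 12, 3), (200, 50, 50), dtype=np.uint8)
        frame[:, 6:] = (20, 20, 200)
        cmap = segment_frame_kmeans(frame, k=2, seed=0)
        assert sorted(map(tuple, cmap.means.round(6))) == [
            (20.0, 20.0, 200.0), (200.0, 50.0, 50.0)]
        assert cmap.inertia == pytest.approx(0.0, abs=1e-9)
        # one label per half, exactly
        assert len(np.unique(cmap.labels[:, :6])) == 1
        assert len(np.unique(cmap.labels[:, 6:])) == 1

    def test_uniform_frame_is_degenerate(self):
        frame = np.full((5, 5, 3), 77, dtype=np.uint8)
        with pytest.warns(DegenerateClusteringWarning):
            cmap = segment_frame_kmeans(frame, k=2, seed=0)
        assert cmap.degenerate
        assert cmap.sizes[0] == 25 and cmap.sizes[1] == 0
        assert np.isnan(cmap.means[1]).all()

    def test_three_color_palette_recovery(self, rng):
        palette = np.array([(30, 30, 120), (225, 160, 160), (245, 245, 245)], float)
        labels_true = rng.integers(0, 3, size=(40, 40))
        frame = np.clip(palette[labels_true] + rng.normal(0, 5, (40, 40, 3)),
                        0, 255).astype(np.uint8)
        cmap = segment_frame_kmeans(frame, k=3, seed=1)
        for color in palette:
            d = np.linalg.norm(cmap.means - color, axis=1).min()
            assert d < 3.0

    def test_labels_ordered_by_decreasing_size(self):
        frame = np.full((10, 10, 3), (200, 50, 50), dtype=np.uint8)
        frame[:2, :2] = (20, 20, 200)    # minority color
        cmap = segment_frame_kmeans(frame, k=2, seed=0)
        assert cmap.sizes[0] >= cmap.sizes[1]
        assert tuple(cmap.means[1].round(6)) == (20.0, 20.0, 200.0)

    def test_matches_brute_force_lloyd_on_small_crop(self, rng):
        """Converged inertia equals an independent plain-loop Lloyd oracle's."""
        palette = np.array([(30, 30, 120), (225, 160, 160), (245, 245, 245)], float)
        labels_true = rng.integers(0, 3, size=(20, 20))
        frame = np.clip(palette[labels_true] + rng.normal(0, 5, (20, 20, 3)),
                        0, 255).astype(np.uint8)
        cmap = segment_frame_kmeans(frame, k=3, seed=3, tol=1e-8)

        colors, counts, _ = _unique_colors(frame)
        init = kmeans_plusplus_init(colors, 3, np.random.default_rng([3, 0xC01]),
                                    weights=counts)
        _, _, oracle_inertia = brute_force_lloyd(frame.reshape(-1, 3), init)
        assert cmap.inertia == pytest.approx(oracle_inertia, rel=1e-6)

    def test_deterministic_given_seed(self, rng):
        frame = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
        a = segment_frame_kmeans(frame, k=3, seed=5)
        b = segment_frame_kmeans(frame, k=3, seed=5)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.means, b.means)


def _cluster_map(means, label_img, k=None):
    means = np.asarray(means, dtype=float)
    label_img = np.asarray(label_img)
    k = k or len(means)
    sizes = np.array([(label_img == j).sum() for j in range(k)])
    return ClusterMap(labels=label_img, means=means, k=k, inertia=0.0, sizes=sizes)


class TestSelectMarkerCluster:
    MEANS = [(200, 150, 140), (30, 30, 120), (90, 60, 55)]

    def _map(self):
        labels = np.repeat(np.arange(3), 12).reshape(6, 6)
        return _cluster_map(self.MEANS, labels)

    def test_unique_nearest_color_selected(self):
        mm = select_marker_cluster(self._map(), ReferenceColor((28, 32, 118), 10))
        assert mm.matched_cluster == 1
        assert mm.valid
        assert mm.color_distance == pytest.approx(np.sqrt(4 + 4 + 4))

    def test_tie_breaks_to_larger_cluster(self):
        labels = np.zeros((4, 4), dtype=int)
        labels[3, 3] = 1
        cmap = _cluster_map([(10, 0, 0), (30, 0, 0)], labels)
        mm = select_marker_cluster(cmap, ReferenceColor((20, 0, 0), 1))
        assert mm.matched_cluster == 0

    def test_distance_threshold_invalidates(self):
        mm = select_marker_cluster(self._map(), ReferenceColor((30, 30, 170), 10),
                                   max_distance=10)
        assert not mm.valid

    def test_keeps_largest_connected_component(self):
        labels = np.zeros((5, 7), dtype=int)
        labels[1:4, 1:3] = 1          # 6-pixel component
        labels[2, 5] = 1              # isolated pixel, same cluster
        cmap = _cluster_map([(200, 200, 200), (0, 0, 0)], labels)
        mm = select_marker_cluster(cmap, ReferenceColor((0, 0, 0), 1))
        assert mm.mask.sum() == 6
        assert not mm.mask[2, 5]

    def test_invariant_under_cluster_relabelling(self):
        labels = np.repeat(np.arange(3), 12).reshape(6, 6)
        ref = ReferenceColor((28, 32, 118), 10)
        base = select_marker_cluster(_cluster_map(self.MEANS, labels), ref)
        perm = [2, 0, 1]
        permuted_labels = np.asarray(perm)[labels]
        permuted_means = np.empty((3, 3))
        for old, new in enumerate(perm):
            permuted_means[new] = self.MEANS[old]
        shuffled = select_marker_cluster(_cluster_map(permuted_means, permuted_labels), ref)
        assert np.array_equal(base.mask, shuffled.mask)
        assert base.color_distance == pytest.approx(shuffled.color_distance)


class TestCentroid:
    def test_symmetric_four_pixels(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[[0, 0, 2, 2], [0, 2, 0, 2]] = True
        assert centroid_of_mask(MarkerMask(mask, 0, 0.0, True)) == (1.0, 1.0)

    def test_single_pixel(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[7, 5] = True            # row 7, column 5 -> (x=5, y=7)
        assert centroid_of_mask(MarkerMask(mask, 0, 0.0, True)) == (5.0, 7.0)

    def test_disc_centroid_matches_enumeration_oracle(self):
        cx, cy, r = 100.3, 80.0, 20.0
        ox, oy, n = disc_pixel_centroid(cx, cy, r)
        mask = np.zeros((160, 200), dtype=bool)
        yy, xx = np.mgrid[0:160, 0:200]
        mask[(xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2] = True
        assert mask.sum() == n
        got = centroid_of_mask(MarkerMask(mask, 0, 0.0, True))
        assert got == pytest.approx((ox, oy), abs=1e-9)
        assert got == pytest.approx((cx, cy), abs=0.1)

    def test_empty_mask_signals_invalid_frame(self):
        with pytest.raises(InvalidFrameError):
            centroid_of_mask(MarkerMask(np.zeros((4, 4), dtype=bool), 0, 0.0, False))


class TestTrackSequence:
    def test_static_marker_recovered_exactly(self):
        frames, truth, roi = make_video(jitter_sd=0.0, n_frames=6, noise_sd=0.0)
        traj = track_sequence(frames, roi)
        assert traj.valid.all()
        assert np.allclose(traj.centroids, traj.centroids[0])
        assert np.allclose(traj.centroids[0], truth.positions[0], atol=0.5)

    def test_square_wave_motion_rmse_below_1px(self):
        params = MotionParams(jitter_sd=0, swallow_rate=0, n_frames=12)
        truth = simulate_trajectory(params)
        truth.positions[:, 0] += 3.0 * (np.arange(12) % 2)   # 3 px horizontal square wave
        frames = render_frames(truth, SceneParams(color_noise_sd=4))
        traj = track_sequence(frames, roi_around(truth.positions[0]))
        err = np.linalg.norm(traj.centroids - truth.positions, axis=1)
        assert traj.valid.all()
        assert np.sqrt((err ** 2).mean()) <= 1.0

    def test_occluded_frames_flagged_not_interpolated(self):
        frames, truth, roi = make_video(jitter_sd=0.5, n_frames=16, seed=5)
        scene_tissue = SceneParams().tissue_color
        for i in (10, 11, 12):
            x, y = truth.positions[i]
            ys, xs = int(y), int(x)
            frames.pixels[i, ys - 15:ys + 15, xs - 15:xs + 15] = scene_tissue
        traj = track_sequence(frames, roi)
        assert not traj.valid[[10, 11, 12]].any()
        assert traj.valid.sum() == 13
        assert np.isnan(traj.centroids[10]).all()

    def test_majority_invalid_raises_tracking_failure(self):
        frames, truth, roi = make_video(jitter_sd=0.0, n_frames=8, seed=5)
        tissue = SceneParams().tissue_color
        for i in range(1, 8):    # occlude 7 of 8 frames
            x, y = truth.positions[i]
            ys, xs = int(y), int(x)
            frames.pixels[i, ys - 15:ys + 15, xs - 15:xs + 15] = tissue
        with pytest.raises(TrackingFailureError):
            track_sequence(frames, roi)

    def test_translation_equivariance(self):
        frames, truth, roi = make_video(jitter_sd=0.5, n_frames=4, seed=3)
        dx, dy = 9, -6
        rolled = FrameSequence(np.roll(frames.pixels, (dy, dx), axis=(1, 2)),
                               frames.frame_rate)
        x, y, w, h = roi.rect
        roi_rolled = RoiSeed(rect=(x + dx, y + dy, w, h))
        a = track_sequence(frames, roi)
        b = track_sequence(rolled, roi_rolled)
        assert a.valid.all() and b.valid.all()
        assert np.allclose(b.centroids - a.centroids, (dx, dy), atol=1e-9)

    def test_deterministic(self, small_video):
        frames, _, roi = small_video
        a = track_sequence(frames, roi, TrackingConfig(seed=2))
        b = track_sequence(frames, roi, TrackingConfig(seed=2))
        assert np.array_equal(a.centroids, b.centroids)
        assert np.array_equal(a.match_distance, b.match_distance)

    def test_stride_skips_frames(self, small_video):
        frames, _, roi = small_video
        traj = track_sequence(frames, roi, TrackingConfig(stride=2))
        assert list(traj.frame_indices) == [0, 2, 4, 6]

    @pytest.mark.parametrize("jitter_sd", [0.0, 1.0, 2.0, 4.0])
    def test_parameter_recovery_across_jitter_levels(self, jitter_sd):
        frames, truth, roi = make_video(jitter_sd=jitter_sd, n_frames=15, seed=17,
                                        noise_sd=6.0)
        traj = track_sequence(frames, roi)
        err = np.linalg.norm(traj.centroids[traj.valid]
                             - truth.positions[traj.valid], axis=1)
        assert np.sqrt((err ** 2).mean()) <= max(1.0, 0.5 * jitter_sd)

    def test_csv_roundtrip(self, small_video, tmp_path):
        frames, _, roi = small_video
        traj = track_sequence(frames, roi)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = Trajectory.from_csv(path)
        assert np.allclose(back.centroids, traj.centroids, equal_nan=True)
        assert np.array_equal(back.valid, traj.valid)
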