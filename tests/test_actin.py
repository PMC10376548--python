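"""Filament segmentation, skeleton handling, bridging and morphometry."""

import numpy as np
import pytest

from mechanovibe import actin
from mechanovibe.actin import SegmentationParams
from mechanovibe.synth import (
    FilamentSceneSpec,
    make_filament_image,
    random_filament_scene,
)
from tests.conftest import match_filaments


def bar_image(shape=(64, 64), row=32, c0=10, c1=50, width=3, intensity=100.0):
    img = np.zeros(shape)
    half = width // 2
    img[row - half : row + half + 1, c0:c1] = intensity
    return img


class TestSegment:
    def test_constant_image_warns_and_empty(self):
        img = actin.CalibratedImage(np.full((32, 32), 5.0), 0.1)
        with pytest.warns(UserWarning):
            mask = actin.segment_filaments(img)
        assert not mask.any()

    def test_bright_ridge_mostly_captured(self):
        img = actin.CalibratedImage(bar_image(), 0.1)
        mask = actin.segment_filaments(img)
        ridge = np.zeros((64, 64), dtype=bool)
        ridge[31:34, 10:50] = True
        assert (mask & ridge).sum() / ridge.sum() >= 0.9

    def test_uniform_offset_invariance_of_laplacian_mask(self):
        base = bar_image()
        p = SegmentationParams(foreground_guard=False)
        m1 = actin.segment_filaments(actin.CalibratedImage(base, 0.1), p)
        m2 = actin.segment_filaments(actin.CalibratedImage(base + 37.0, 0.1), p)
        np.testing.assert_array_equal(m1, m2)

    def test_nonfinite_rejected(self):
        img = actin.CalibratedImage(np.full((8, 8), np.nan), 0.1)
        with pytest.raises(ValueError):
            actin.segment_filaments(img)


class TestSkeletonize:
    def test_straight_bar_single_axial_path(self):
        mask = bar_image() > 0
        paths = actin.skeletonize_and_filter(mask)
        assert len(paths) == 1
        rows = [r for r, _ in paths[0]]
        # interior runs along the bar axis; thinning may step at the ends
        assert np.mean(np.asarray(rows) == 32) >= 0.9

    def test_small_blob_removed(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[10:12, 10] = True
        assert actin.skeletonize_and_filter(
            mask, SegmentationParams(min_skeleton_px=5)
        ) == []

    def test_x_junction_decomposed_into_paths(self):
        mask = np.zeros((41, 41), dtype=bool)
        for i in range(41):
            mask[i, i] = True
            mask[i, 40 - i] = True
        paths = actin.skeletonize_and_filter(mask)
        # two long arms are joined through the junction; remaining arms split
        assert 2 <= len(paths) <= 4
        assert sum(len(p) for p in paths) >= 70

    def test_count_monotone_in_min_skeleton(self, filament_scene):
        img, _ = filament_scene
        mask = actin.segment_filaments(img)
        counts = []
        for m in (3, 5, 10, 20):
            paths = actin.skeletonize_and_filter(
                mask, SegmentationParams(min_skeleton_px=m)
            )
            counts.append(len(paths))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestBridge:
    def _segment(self, r, c0, c1):
        return [(r, c) for c in range(c0, c1)]

    def test_collinear_close_segments_merged(self):
        paths = [self._segment(10, 0, 20), self._segment(10, 23, 43)]
        out = actin.bridge_gaps(paths)
        assert len(out) == 1
        cols = {c for _, c in out[0]}
        assert {20, 21, 22} <= cols  # gap interpolated

    def test_perpendicular_segments_not_merged(self):
        vert = [(r, 25) for r in range(12, 32)]
        out = actin.bridge_gaps([self._segment(10, 0, 20), vert])
        assert len(out) == 2

    def test_distant_segments_not_merged(self):
        out = actin.bridge_gaps(
            [self._segment(10, 0, 20), self._segment(10, 70, 90)]
        )
        assert len(out) == 2

    def test_idempotent(self):
        paths = [
            self._segment(10, 0, 20),
            self._segment(10, 23, 43),
            self._segment(40, 0, 20),
        ]
        once = actin.bridge_gaps(paths)
        twice = actin.bridge_gaps(once)
        assert sorted(map(tuple, once)) == sorted(map(tuple, twice))


class TestMeasure:
    def test_horizontal_path_closed_form(self):
        path = [(5, c) for c in range(101)]
        mask = np.zeros((11, 101), dtype=bool)
        mask[4:7, :] = True
        f = actin.measure_filament(path, mask, 0.1)
        assert f.length_um == pytest.approx(10.0)
        assert f.angle_deg == pytest.approx(0.0)

    def test_diagonal_path_closed_form(self):
        path = [(i, i) for i in range(101)]
        mask = np.zeros((101, 101), dtype=bool)
        for i in range(101):
            mask[i, max(0, i - 1) : i + 2] = True
        f = actin.measure_filament(path, mask, 0.1)
        assert f.length_um == pytest.approx(100 * np.sqrt(2) * 0.1)
        assert f.angle_deg == pytest.approx(-45.0)  # row increases downward

    def test_thickness_of_five_px_bar(self):
        img = bar_image(width=5)
        mask = img > 0
        path = [(32, c) for c in range(12, 48)]
        f = actin.measure_filament(path, mask, 0.02)
        assert f.thickness_um == pytest.approx(0.10, abs=0.02)

    def test_single_pixel_path_rejected(self):
        with pytest.raises(ValueError):
            actin.measure_filament([(3, 3)], np.ones((8, 8), bool), 0.1)

    def test_angle_wrapping_convention(self):
        mask = np.ones((64, 64), dtype=bool)
        vertical = [(r, 10) for r in range(40)]
        f = actin.measure_filament(vertical, mask, 0.1)
        assert f.angle_deg == 90.0


class TestOutlierFilter:
    def _mk(self, length):
        return actin.Filament(((0, 0), (0, 1)), length, 0.1, 0.0)

    def test_over_100um_removed(self):
        fils = [self._mk(5.0), self._mk(50.0), self._mk(120.0)]
        out = actin.apply_outlier_filter(fils)
        assert [f.length_um for f in out] == [5.0, 50.0]

    def test_exactly_100um_retained(self):
        out = actin.apply_outlier_filter([self._mk(100.0)])
        assert len(out) == 1

    def test_empty_input(self):
        assert actin.apply_outlier_filter([]) == []


class TestRecovery:
    def test_planted_filaments_recovered(self, filament_scene):
        img, truth = filament_scene
        fils = actin.analyze_image(img)
        h = img.pixels.shape[0]
        ps = img.pixel_size_um
        ok = 0
        for row, f, dist in match_filaments(truth, fils, h):
            len_ok = abs(f.length_um - row.length_um) <= max(
                0.05 * row.length_um, 2 * ps
            )
            ang_ok = abs(((f.angle_deg - row.angle_deg) + 90) % 180 - 90) <= 3
            thick_ok = abs(f.thickness_um - row.width_um) <= 0.25 * row.width_um
            ok += len_ok and ang_ok and thick_ok
        assert ok >= 0.9 * len(truth)

    def test_rotation_by_90_degrees_consistent(self):
        spec = random_filament_scene(n_filaments=8, seed=3)
        img, truth = make_filament_image(spec)
        fils = actin.analyze_image(img)
        rot = actin.CalibratedImage(np.rot90(img.pixels), img.pixel_size_um)
        fils_r = actin.analyze_image(rot)
        assert len(fils) == len(fils_r)
        h, w = img.pixels.shape
        for f in fils:
            p = np.asarray(f.skeleton_path, dtype=float)
            # rot90 (CCW) maps (row, col) -> (w-1-col, row)
            target = (w - 1 - p[:, 1].mean(), p[:, 0].mean())
            g = min(
                fils_r,
                key=lambda g_: np.hypot(
                    np.asarray(g_.skeleton_path, float)[:, 0].mean() - target[0],
                    np.asarray(g_.skeleton_path, float)[:, 1].mean() - target[1],
                ),
            )
            # thinning is not exactly rotation-equivariant: allow 5% per
            # filament; angles must map theta -> theta +/- 90 (wrapped)
            assert abs(g.length_um / f.length_um - 1) <= 0.05
            d = abs((f.angle_deg + 90.0) - g.angle_deg)
            d = min(d % 180, 180 - d % 180)
            assert d <= 3.0
        mean_l = np.mean([f.length_um for f in fils])
        mean_r = np.mean([f.length_um for f in fils_r])
        assert abs(mean_r / mean_l - 1) <= 0.02

    def test_all_lengths_below_cutoff_after_filter(self, filament_scene):
        img, _ = filament_scene
        fils = actin.analyze_image(img)
        assert all(f.length_um <= 100.0 for f in fils)


class TestBatch:
    def _images(self, n_cond=2, n_rep=2, n_field=2):
        imgs = []
        k = 0
        for c in range(n_cond):
            for r in range(n_rep):
                for f in range(n_field):
                    spec = random_filament_scene(
                        n_filaments=4, image_shape=(128, 128),
                        length_range_um=(0.8, 1.6), seed=k,
                    )
                    img, _ = make_filament_image(spec)
                    imgs.append(
                        actin.CalibratedImage(
                            img.pixels, img.pixel_size_um,
                            condition=f"C{c}", replicate=f"R{r}",
                            field_label=f"F{f}",
                        )
                    )
                    k += 1
        return imgs

    def test_batch_bookkeeping(self):
        imgs = self._images()
        features, log = actin.batch_analyze(imgs)
        assert len(log) == 8
        assert set(features["condition"]) == {"C0", "C1"}
        assert (log["n_filaments"] > 0).all()

    def test_corrupt_image_reported_not_fatal(self):
        imgs = self._images(n_cond=1, n_rep=1, n_field=2)
        bad = actin.CalibratedImage(
            np.full((32, 32), np.nan), 0.04, condition="C0", replicate="R0",
            field_label="BAD",
        )
        features, log = actin.batch_analyze(imgs + [bad])
        assert (log["error"] != "").sum() == 1
        assert len(log) == 3

    def test_all_unreadable_raises(self):
        bad = actin.CalibratedImage(np.full((16, 16), np.nan), 0.04)
        with pytest.raises(RuntimeError):
            actin.batch_analyze([bad])

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            actin.batch_analyze([])
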