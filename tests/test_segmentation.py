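"""Thresholding, primary/secondary/tertiary identification, label expansion."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from skimage.draw import disk as draw_disk

from orgprof.core import ChannelRole, IntensityImage, LabelImage, LabelKind
from orgprof.segmentation import (
    SegmentationParams,
    expand_labels,
    identify_primary,
    identify_secondary_propagation,
    identify_tertiary_membrane,
    threshold_global,
)
from oracles import dijkstra_propagate, enumerate_expansion, exhaustive_otsu


def _img(px, size=0.1, role=ChannelRole.NUCLEI):
    return IntensityImage(pixels=np.asarray(px, float), pixel_size_um=size, role=role)


def _labels(arr, kind=LabelKind.NUCLEUS):
    return LabelImage(labels=np.asarray(arr, np.int32), kind=kind)


class TestThresholdGlobal:
    def test_otsu_selects_bright_half_and_matches_exhaustive_scan(self, rng):
        px = np.where(rng.random((32, 32)) < 0.5, 0.1, 0.9)
        px += rng.normal(0, 0.005, px.shape)
        px = np.clip(px, 0, 1)
        mask = threshold_global(_img(px), method="otsu")
        t_oracle = exhaustive_otsu(px)
        assert np.array_equal(mask, px > t_oracle)
        assert np.array_equal(mask, px > 0.5)  # bright half selected

    def test_correction_clipped_to_bounds(self):
        px = np.linspace(0, 1, 64).reshape(8, 8)
        mask = threshold_global(_img(px), method="otsu", correction=10.0, bounds=(0.0, 0.5))
        assert np.array_equal(mask, px > 0.5)

    def test_all_zero_image_gives_empty_mask(self):
        assert not threshold_global(_img(np.zeros((10, 10)))).any()

    def test_manual_requires_value(self):
        with pytest.raises(ValueError):
            threshold_global(_img(np.zeros((4, 4))), method="manual")


class TestIdentifyPrimary:
    def _disk_image(self, centers, radius=10, shape=(64, 64)):
        px = np.zeros(shape)
        for c in centers:
            rr, cc = draw_disk(c, radius, shape=shape)
            px[rr, cc] = 0.9
        return _img(px)

    def test_two_separated_disks(self):
        img = self._disk_image([(16, 16), (46, 46)])
        lab = identify_primary(img, SegmentationParams(diameter_range_px=(10, 40)))
        assert lab.n_objects == 2

    def test_declump_splits_overlapping_disks(self):
        # two diameter-20 disks overlapping by 4 px along the row axis
        img = self._disk_image([(32, 22), (32, 38)], radius=10)
        merged = identify_primary(img, SegmentationParams(diameter_range_px=(10, 40)))
        assert merged.n_objects == 1  # without declumping they fuse
        split = identify_primary(
            img, SegmentationParams(diameter_range_px=(10, 40), declump="shape")
        )
        assert split.n_objects == 2
        areas = np.bincount(split.labels.ravel())[1:]
        assert areas.min() > 0.3 * areas.sum()  # roughly even split

    def test_small_speck_removed_by_size_filter(self):
        px = np.zeros((32, 32))
        px[5:8, 5:8] = 1.0  # ~3-px speck
        lab = identify_primary(_img(px), SegmentationParams(diameter_range_px=(10, 40)))
        assert lab.n_objects == 0

    def test_border_policy_and_raster_numbering(self):
        px = np.zeros((40, 40))
        px[0:12, 15:27] = 1.0   # touches top border
        px[25:37, 4:16] = 1.0
        px[25:37, 24:36] = 1.0
        keep = identify_primary(_img(px), SegmentationParams(diameter_range_px=(5, 30)))
        assert keep.n_objects == 3
        # raster order: first pixel of label k precedes that of label k+1
        firsts = [np.argwhere(keep.labels == i)[0] for i in (1, 2, 3)]
        flat = [r * 40 + c for r, c in firsts]
        assert flat == sorted(flat)
        dropped = identify_primary(
            _img(px), SegmentationParams(diameter_range_px=(5, 30), discard_border=True)
        )
        assert dropped.n_objects == 2

    def test_holes_filled(self):
        px = np.zeros((40, 40))
        px[10:30, 10:30] = 1.0
        px[18:22, 18:22] = 0.0  # hole
        lab = identify_primary(_img(px), SegmentationParams(diameter_range_px=(10, 40)))
        assert (lab.labels > 0).sum() == 400

    def test_deterministic(self, rng):
        px = np.clip(rng.random((48, 48)), 0, 1)
        p = SegmentationParams(diameter_range_px=(2, 40))
        a = identify_primary(_img(px), p)
        b = identify_primary(_img(px), p)
        assert np.array_equal(a.labels, b.labels)


class TestPropagation:
    def _seeds(self, shape, points):
        arr = np.zeros(shape, np.int32)
        for lab, (r, c) in points.items():
            arr[r, c] = lab
        return _labels(arr)

    def test_single_seed_fills_everything(self):
        seeds = self._seeds((16, 16), {1: (8, 8)})
        out = identify_secondary_propagation(seeds, _img(np.zeros((16, 16))), lam=0.05)
        assert np.all(out.labels == 1)

    def test_constant_guide_is_voronoi_with_lower_label_ties(self):
        seeds = self._seeds((21, 32), {1: (10, 8), 2: (10, 23)})
        guide = _img(np.full((21, 32), 0.5))
        out = identify_secondary_propagation(seeds, guide, lam=0.05)
        oracle = dijkstra_propagate(seeds.labels, guide.pixels, 0.05)
        assert np.array_equal(out.labels, oracle)
        # clear-margin pixels follow the Euclidean Voronoi diagram
        rr, cc = np.mgrid[0:21, 0:32]
        d1 = np.hypot(rr - 10, cc - 8)
        d2 = np.hypot(rr - 10, cc - 23)
        margin = np.abs(d1 - d2) > 0.1 * np.maximum(d1, d2)
        assert np.array_equal((out.labels == 1)[margin], (d1 < d2)[margin])
        # the equidistant column goes to the lower seed label
        assert np.all(out.labels[:, 15] <= 1 + (np.abs(d1 - d2) > 0)[:, 15])

    def test_matches_dijkstra_oracle_on_random_guides(self, rng):
        for _ in range(10):
            H, W = rng.integers(12, 40, 2)
            guide = rng.random((H, W))
            n_seeds = int(rng.integers(2, 5))
            seed_arr = np.zeros((H, W), np.int32)
            pts = rng.choice(H * W, size=n_seeds, replace=False)
            for lab, p in enumerate(pts, start=1):
                seed_arr[p // W, p % W] = lab
            got = identify_secondary_propagation(
                _labels(seed_arr), _img(guide), lam=0.05
            )
            expect = dijkstra_propagate(seed_arr, guide, 0.05)
            assert np.array_equal(got.labels, expect)

    def test_boundary_lies_on_bright_ridge(self):
        H, W = 24, 41
        guide = np.zeros((H, W))
        guide[:, 20] = 1.0  # bright ridge between the seeds
        seeds = self._seeds((H, W), {1: (12, 5), 2: (12, 35)})
        out = identify_secondary_propagation(seeds, _img(guide), lam=0.01)
        oracle = dijkstra_propagate(seeds.labels, guide, 0.01)
        assert np.array_equal(out.labels, oracle)
        boundary_cols = [
            int(np.max(np.where(out.labels[r] == 1))) for r in range(H)
        ]
        assert all(abs(c - 20) <= 1 for c in boundary_cols)

    def test_foreground_mask_and_errors(self):
        seeds = self._seeds((10, 10), {1: (5, 5)})
        fg = np.zeros((10, 10), bool)
        fg[3:8, 3:8] = True
        out = identify_secondary_propagation(seeds, _img(np.zeros((10, 10))), 0.05, foreground=fg)
        assert set(np.unique(out.labels[fg])) == {1}
        assert np.all(out.labels[~fg] == 0)
        with pytest.raises(ValueError):
            identify_secondary_propagation(
                _labels(np.zeros((10, 10))), _img(np.zeros((10, 10)))
            )
        with pytest.raises(ValueError):
            identify_secondary_propagation(seeds, _img(np.zeros((10, 10))), lam=-1)

    def test_cells_partition_foreground(self, rng):
        seeds = self._seeds((30, 30), {1: (6, 6), 2: (20, 22), 3: (25, 5)})
        out = identify_secondary_propagation(seeds, _img(rng.random((30, 30))), lam=0.05)
        assert np.all(out.labels > 0)
        assert set(np.unique(out.labels)) == {1, 2, 3}


class TestTertiaryMembrane:
    def test_square_cell_width1_is_76px_frame(self):
        lab = np.zeros((30, 30), np.int32)
        lab[5:25, 5:25] = 1  # 20x20 cell
        mem = identify_tertiary_membrane(_labels(lab, LabelKind.CELL), width_px=1)
        assert (mem.labels == 1).sum() == 76

    def test_width_at_least_inradius_covers_whole_cell(self):
        lab = np.zeros((20, 20), np.int32)
        lab[5:15, 5:15] = 1
        mem = identify_tertiary_membrane(_labels(lab, LabelKind.CELL), width_px=5)
        assert np.array_equal(mem.labels, lab)

    def test_membrane_subset_and_interior_identity(self):
        lab = np.zeros((40, 40), np.int32)
        lab[4:20, 6:30] = 1
        lab[20:36, 6:30] = 2  # adjacent cells share an interface
        cells = _labels(lab, LabelKind.CELL)
        mem = identify_tertiary_membrane(cells, width_px=2)
        assert np.all((mem.labels == 0) | (mem.labels == lab))
        # interface pixels belong to the band of both adjacent cells
        assert np.all(mem.labels[19, 10:25] == 1)
        assert np.all(mem.labels[20, 10:25] == 2)


class TestExpandLabels:
    def test_single_pixel_expands_to_13px_diamond_disk(self):
        lab = np.zeros((9, 9), np.int32)
        lab[4, 4] = 1
        out = expand_labels(_labels(lab), 2)
        assert (out.labels == 1).sum() == 13  # lattice points with r^2 <= 4

    def test_zero_expansion_is_identity(self, rng):
        lab = (rng.random((12, 12)) < 0.2).astype(np.int32)
        out = expand_labels(_labels(lab), 0)
        assert np.array_equal(out.labels, lab)

    def test_close_objects_abut_without_merging(self):
        lab = np.zeros((9, 12), np.int32)
        lab[4, 3] = 1
        lab[4, 7] = 2  # 4 px apart; n=2 halos touch
        out = expand_labels(_labels(lab), 2)
        assert np.array_equal(out.labels, enumerate_expansion(lab, 2))
        assert set(np.unique(out.labels)) == {0, 1, 2}
        assert out.labels[4, 5] == 1  # equidistant tie -> lower label

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(5):
            lab = np.where(rng.random((16, 16)) < 0.08,
                           rng.integers(1, 6, (16, 16)), 0).astype(np.int32)
            for n in (1, 2, 3):
                got = expand_labels(_labels(lab), n)
                assert np.array_equal(got.labels, enumerate_expansion(lab, n))

    def test_existing_labels_never_overwritten(self, rng):
        lab = np.where(rng.random((20, 20)) < 0.1,
                       rng.integers(1, 4, (20, 20)), 0).astype(np.int32)
        out = expand_labels(_labels(lab), 3)
        fg = lab > 0
        assert np.array_equal(out.labels[fg], lab[fg])

    @given(st.integers(0, 3), st.integers(0, 3))
    def test_composition_support_for_single_object(self, a, b):
        # On the integer lattice two successive Euclidean expansions need an
        # intermediate lattice point, so chaining can fall short of the joint
        # expansion by at most one pixel (e.g. offset (2,2) for a=1, b=2);
        # exact support equality holds whenever either step is trivial.
        lab = np.zeros((15, 15), np.int32)
        lab[7, 7] = 1
        step = expand_labels(expand_labels(_labels(lab), a), b)
        joint = expand_labels(_labels(lab), a + b)
        step_s, joint_s = step.labels > 0, joint.labels > 0
        assert np.all(joint_s[step_s])  # chained within joint
        slack = expand_labels(step, 1).labels > 0
        assert np.all(slack[joint_s])  # joint within one pixel of chained
        if a == 0 or b == 0:
            assert np.array_equal(step_s, joint_s)
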