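"""Segmentation post-processing tests: reference segmenter, hole filling,
watershed splitting, cluster filtering and region measurement."""

import math

import numpy as np
import pytest
from skimage.measure import label as cc_label

from protrack import segment
from protrack.imagesim import SimulationSpec, simulate_plate


def disk_mask(shape, centers, radii):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    mask = np.zeros(shape, dtype=bool)
    for (cx, cy), r in zip(centers, radii):
        mask |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    return mask


class TestReferenceSegmenter:
    def test_blank_frame_gives_empty_mask(self):
        assert not segment.segment_reference(np.full((100, 100), 0.4)).any()

    def test_isolated_disks_recovered_with_high_iou(self):
        spec = SimulationSpec(
            image_shape=(700, 700), n_cells=20, min_spacing=60, n_timepoints=2,
            noise_sigma=0.0, seed=8,
        )
        imgs, truth = simulate_plate(spec)
        mask = segment.segment_reference(imgs[0])
        lab = cc_label(mask, connectivity=2)
        assert lab.max() == 20
        tl = truth.label_map(0)
        for cid in truth.frame(0)["cell_id"]:
            tmask = tl == cid
            hit = np.bincount(lab[tmask]).argmax()
            assert hit > 0
            pmask = lab == hit
            iou = (tmask & pmask).sum() / (tmask | pmask).sum()
            assert iou >= 0.9

    def test_pure_noise_frame_yields_no_objects(self):
        rng = np.random.default_rng(3)
        img = np.clip(rng.normal(0.5, 0.1, (400, 400)), 0, 1)
        mask = segment.segment_reference(img)
        assert cc_label(mask, connectivity=2).max() == 0

    @pytest.mark.parametrize("min_area", [(30, 200)])
    def test_min_cell_area_is_monotone(self, min_area):
        spec = SimulationSpec(
            image_shape=(500, 500), n_cells=12, min_spacing=60, n_timepoints=2, seed=4
        )
        imgs, _ = simulate_plate(spec)
        lo, hi = min_area
        n_lo = cc_label(segment.segment_reference(imgs[0], min_cell_area=lo), connectivity=2).max()
        n_hi = cc_label(segment.segment_reference(imgs[0], min_cell_area=hi), connectivity=2).max()
        assert n_hi <= n_lo


class TestBackendRegistry:
    def test_reference_under_new_name_matches(self):
        img = simulate_plate(
            SimulationSpec(image_shape=(400, 400), n_cells=6, min_spacing=60,
                           n_timepoints=2, seed=1)
        )[0][0]
        segment.attach_backend("mirror", segment.segment_reference)
        assert np.array_equal(
            segment.run_backend("mirror", img), segment.run_backend("reference", img)
        )

    def test_wrong_shape_output_rejected(self):
        segment.attach_backend("bad", lambda img: np.zeros((3, 3), dtype=bool))
        with pytest.raises(ValueError, match="shape"):
            segment.run_backend("bad", np.zeros((10, 10)))

    def test_unknown_backend_rejected(self):
        with pytest.raises(KeyError):
            segment.get_backend("no-such-backend")


class TestFillHoles:
    def test_annulus_becomes_solid_disk(self):
        yy, xx = np.mgrid[:60, :60]
        d2 = (xx - 30) ** 2 + (yy - 30) ** 2
        annulus = (d2 <= 20**2) & (d2 >= 10**2)
        filled = segment.fill_holes(annulus)
        assert np.array_equal(filled, d2 <= 20**2)

    def test_mask_without_holes_unchanged(self):
        mask = disk_mask((60, 60), [(30, 30)], [15])
        assert np.array_equal(segment.fill_holes(mask), mask)

    def test_border_open_channel_not_filled(self):
        mask = np.ones((40, 40), dtype=bool)
        mask[:, 18:22] = False  # channel open to top and bottom borders
        assert np.array_equal(segment.fill_holes(mask), mask)


class TestWatershedSplit:
    def test_single_disk_stays_one_fragment(self):
        labels = segment.watershed_split(disk_mask((80, 80), [(40, 40)], [18]))
        assert labels.max() == 1

    def test_dumbbell_splits_near_equally(self):
        mask = disk_mask((100, 100), [(42, 50), (58, 50)], [10, 10])
        labels = segment.watershed_split(mask)
        assert labels.max() == 2
        sizes = np.bincount(labels.ravel())[1:]
        assert abs(sizes[0] - sizes[1]) / sizes.sum() < 0.1
        assert (labels > 0).sum() == mask.sum()  # every fg pixel assigned

    def test_chain_of_three_gives_three_fragments(self):
        mask = disk_mask((140, 100), [(40, 50), (66, 50), (92, 50)], [10, 10, 10])
        assert segment.watershed_split(mask).max() == 3


class TestFilterClusters:
    def _frame(self):
        centers = [(30, 30), (100, 30), (30, 100), (92, 92), (108, 92)]
        radii = [12, 12, 12, 10, 10]
        mask = disk_mask((140, 140), centers, radii)
        original = cc_label(mask, connectivity=2).astype(np.int32)
        split = segment.watershed_split(mask)
        return original, split

    def test_cluster_removed_isolated_retained(self):
        original, split = self._frame()
        kept, removed = segment.filter_clusters(original, split)
        assert len(removed) == 1
        assert kept.max() == 3
        # conservation: retained + removed = original labels
        assert kept.max() + len(removed) == original.max()

    def test_all_isolated_removes_nothing(self):
        mask = disk_mask((140, 140), [(30, 30), (100, 30), (65, 100)], [12, 12, 12])
        original = cc_label(mask, connectivity=2).astype(np.int32)
        kept, removed = segment.filter_clusters(original, segment.watershed_split(mask))
        assert removed == []
        assert kept.max() == 3
        assert np.array_equal(kept > 0, original > 0)

    def test_sliver_fragment_does_not_flag_single_cell(self):
        mask = disk_mask((80, 80), [(40, 40)], [15])
        original = cc_label(mask, connectivity=2).astype(np.int32)
        split = original.copy()
        ys, xs = np.nonzero(mask)
        split[ys[:4], xs[:4]] = 2  # a 4-px watershed sliver
        kept, removed = segment.filter_clusters(original, split, min_fragment_area=20)
        assert removed == []
        assert kept.max() == 1

    def test_support_mismatch_is_an_error(self):
        original, split = self._frame()
        bad = split.copy()
        bad[0, 0] = 1  # split foreground outside the original mask
        with pytest.raises(ValueError):
            segment.filter_clusters(original, bad)


class TestExcludeBorder:
    def test_centered_kept_edge_removed_empty_ok(self):
        mask = disk_mask((100, 100), [(50, 50), (0, 70)], [12, 12])
        labels = cc_label(mask, connectivity=2)
        out = segment.exclude_border(labels)
        assert out.max() == 1
        assert segment.exclude_border(np.zeros((20, 20), dtype=np.int32)).max() == 0


class TestMeasureRegions:
    def test_square_closed_form(self):
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[5:15, 5:15] = 1
        rec = segment.measure_regions(labels).iloc[0]
        assert rec.area_px == 100
        assert rec.circularity == pytest.approx(math.pi / 4.0)
        assert (rec.cx_px, rec.cy_px) == (9.5, 9.5)

    def test_single_pixel(self):
        labels = np.zeros((5, 5), dtype=np.int32)
        labels[2, 2] = 1
        rec = segment.measure_regions(labels).iloc[0]
        assert rec.area_px == 1
        assert rec.circularity == pytest.approx(math.pi / 4.0)

    def test_rasterized_disk_matches_boundary_walk_oracle(self):
        labels = disk_mask((60, 60), [(30, 30)], [20]).astype(np.int32)
        rec = segment.measure_regions(labels, pixel_size=2.0).iloc[0]
        expected = math.pi * 400
        assert abs(rec.area_px - expected) / expected < 0.02
        # oracle: count exposed pixel edges of the region directly
        mask = labels > 0
        padded = np.pad(mask, 1)
        perim = sum(
            int((padded[1:-1, 1:-1] & ~nb).sum())
            for nb in (padded[:-2, 1:-1], padded[2:, 1:-1], padded[1:-1, :-2], padded[1:-1, 2:])
        )
        assert rec.circularity == pytest.approx(
            min(1.0, 4.0 * math.pi * rec.area_px / perim**2)
        )
        # pixel-edge staircase perimeter of a digital disk is 2*(w + h) ~ 8r,
        # so its circularity converges to pi^2/16, not 1
        assert 0.55 < rec.circularity < 0.7
        assert rec.area_um2 == rec.area_px * 4.0
        assert rec.cx_um == pytest.approx(60.0, abs=1.0)

    def test_centroids_match_truth_within_half_pixel(self):
        spec = SimulationSpec(
            image_shape=(500, 500), n_cells=10, min_spacing=70, n_timepoints=2,
            noise_sigma=0.0, seed=6,
        )
        imgs, truth = simulate_plate(spec)
        lab = cc_label(segment.segment_reference(imgs[0]), connectivity=2)
        recs = segment.measure_regions(lab)
        for row in truth.frame(0).itertuples():
            d = np.hypot(recs["cx_px"] - row.cx_um, recs["cy_px"] - row.cy_um).min()
            assert d <= 0.5
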