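"""Binarization, contour-tracing region labeling and region filtering.

The labeler is checked against an independent flood-fill oracle
(scipy.ndimage.label with 8-connectivity) on random masks, and its
contours against closure/orientation invariants.
"""

import numpy as np
import pytest
from scipy import ndimage

from seedsalt import (PlateImage, SegmentationConfig, binarize, count_objects,
                      filter_regions, label_regions, preset, segment)
from seedsalt.segmentation import otsu_threshold
from seedsalt.synthetic import default_spec, generate_plate


def grey_image(values, mode="FLUO"):
    arr = np.asarray(values, dtype=np.uint8)
    return PlateImage(id="t", pixels=np.repeat(arr[:, :, None], 3, axis=2), mode=mode)


def config(**kw):
    base = dict(name="t", channel="grey", threshold=100,
                polarity="bright_objects", min_area=0, max_area=10**9)
    return SegmentationConfig(**{**base, **kw})


def flood_fill_partition(mask):
    lab, n = ndimage.label(mask, structure=np.ones((3, 3)))
    return {frozenset(zip(*np.nonzero(lab == i))) for i in range(1, n + 1)}


def region_partition(regions):
    return {frozenset(map(tuple, r.pixels)) for r in regions}


class TestBinarize:
    def test_uniform_below_threshold_gives_empty_mask(self):
        mask = binarize(grey_image(np.full((4, 4), 50)), config(threshold=100))
        assert not mask.any()

    def test_direct_comparison_2x2(self):
        mask = binarize(grey_image([[10, 200], [30, 250]]), config(threshold=100))
        assert mask.sum() == 2
        assert mask[0, 1] and mask[1, 1]

    def test_dark_objects_polarity(self):
        mask = binarize(grey_image([[10, 200], [30, 250]]),
                        config(threshold=100, polarity="dark_objects"))
        assert mask.sum() == 2
        assert mask[0, 0] and mask[1, 0]

    def test_threshold_is_inclusive_both_polarities(self):
        img = grey_image([[100]])
        assert binarize(img, config(threshold=100)).all()
        assert binarize(img, config(threshold=100, polarity="dark_objects")).all()

    def test_roi_excludes_outside_pixels(self):
        img = grey_image(np.full((11, 11), 200))
        mask = binarize(img, config(roi=(5.0, 5.0, 3.0)))
        rows, cols = np.nonzero(mask)
        assert ((rows - 5) ** 2 + (cols - 5) ** 2 <= 9).all()
        assert mask.sum() < 11 * 11

    def test_otsu_separates_bimodal_exactly(self):
        rng = np.random.default_rng(5)
        values = rng.choice([50, 200], size=(20, 20))
        img = grey_image(values)
        for polarity, target in (("bright_objects", 200), ("dark_objects", 50)):
            mask = binarize(img, config(threshold="otsu", polarity=polarity))
            assert (values[mask] == target).all()
            assert mask.sum() == (values == target).sum()

    def test_otsu_matches_bruteforce_between_class_variance(self):
        rng = np.random.default_rng(6)
        values = np.clip(np.concatenate([rng.normal(70, 15, 300),
                                         rng.normal(180, 20, 500)]), 0, 255).astype(np.uint8)
        thr = otsu_threshold(values, "bright_objects")
        # exhaustive oracle over all 256 thresholds of the foreground rule
        def between_var(t):
            fg = values[values >= t].astype(float)
            bg = values[values < t].astype(float)
            if len(fg) == 0 or len(bg) == 0:
                return -1.0
            return len(fg) * len(bg) * (fg.mean() - bg.mean()) ** 2
        best = max(range(256), key=lambda t: (between_var(t), -t))
        assert thr == best


class TestLabelRegions:
    def test_single_pixel_region(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        regions = label_regions(mask)
        assert len(regions) == 1
        assert regions[0].area == 1
        assert regions[0].outer_contour.tolist() == [[1, 1]]

    def test_diagonal_pixels_are_one_region(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[0, 0] = mask[1, 1] = True
        assert len(label_regions(mask)) == 1

    def test_partition_matches_flood_fill_on_random_masks(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            shape = (int(rng.integers(1, 33)), int(rng.integers(1, 33)))
            mask = rng.random(shape) < rng.uniform(0.15, 0.7)
            regions = label_regions(mask)
            assert sum(r.area for r in regions) == mask.sum()
            assert region_partition(regions) == flood_fill_partition(mask)

    def test_hole_adjacent_to_external_contour_start(self):
        # regression: a pixel can open both the external contour and a hole
        mask = np.array([[0, 1, 1, 1],
                         [1, 0, 1, 1],
                         [1, 0, 1, 0],
                         [1, 1, 1, 1]], dtype=bool)
        regions = label_regions(mask)
        assert len(regions) == 1
        assert regions[0].area == mask.sum()

    def test_labels_are_consecutive_in_scan_order(self):
        mask = np.zeros((5, 9), dtype=bool)
        mask[0, 6] = mask[2, 3] = mask[4, 0] = True
        regions = label_regions(mask)
        assert [r.label for r in regions] == [1, 2, 3]
        assert [tuple(r.pixels[0]) for r in regions] == [(0, 6), (2, 3), (4, 0)]

    def test_contour_is_closed_clockwise_cycle_within_pixels(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            mask = rng.random((16, 16)) < 0.45
            for region in label_regions(mask):
                contour = region.outer_contour
                pixset = set(map(tuple, region.pixels))
                assert all(tuple(p) in pixset for p in contour)
                closed = np.vstack([contour, contour[:1]])
                steps = np.abs(np.diff(closed, axis=0)).max(axis=1)
                assert (steps[:-1] <= 1).all()  # 8-neighbor steps
                if len(contour) >= 3:
                    # clockwise in image coordinates: with x=col, y=row the
                    # frame is left-handed, so the shoelace sum of a
                    # clockwise cycle is non-negative (3x3 square: +8)
                    x, y = closed[:, 1], closed[:, 0]
                    signed = np.sum(x[:-1] * y[1:] - x[1:] * y[:-1])
                    assert signed >= 0

    def test_translation_shifts_pixel_sets(self):
        rng = np.random.default_rng(9)
        mask = rng.random((20, 20)) < 0.4
        big = np.zeros((30, 30), dtype=bool)
        big[5:25, 7:27] = mask
        base = label_regions(mask)
        shifted = label_regions(big)
        assert len(base) == len(shifted)
        shifted_parts = region_partition(shifted)
        for region in base:
            moved = frozenset((r + 5, c + 7) for r, c in map(tuple, region.pixels))
            assert moved in shifted_parts

    def test_contour_length_at_least_one_step_per_boundary_pixel(self):
        from seedsalt.features import _contour_length

        rng = np.random.default_rng(10)
        mask = rng.random((24, 24)) < 0.5
        for region in label_regions(mask):
            boundary_pixels = {tuple(p) for p in region.outer_contour}
            assert _contour_length(region.outer_contour) >= len(boundary_pixels)


class TestFilterRegions:
    def test_min_area_gate_removes_speck_and_relabels(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[0, 0] = True  # 1-px speck encountered first
        mask[5:15, 5:15] = True  # 100-px seed
        regions = label_regions(mask)
        kept = filter_regions(regions, config(min_area=5))
        assert len(kept) == 1
        assert kept[0].label == 1
        assert kept[0].area == 100

    def test_max_area_gate_removes_rim_blob(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[2:28, 2:28] = True  # huge rim-like blob
        mask[2:26, 4:26] = False
        mask[10:13, 10:13] = True  # 9-px seed
        regions = label_regions(mask)
        kept = filter_regions(regions, config(max_area=50))
        assert [r.area for r in kept] == [9]

    def test_matches_bruteforce_predicate_on_random_regions(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            mask = rng.random((32, 32)) < 0.5
            regions = label_regions(mask)
            cfg = config(min_area=int(rng.integers(0, 5)),
                         max_area=int(rng.integers(5, 40)),
                         roi=(16.0, 16.0, float(rng.uniform(5, 20))))
            kept = filter_regions(regions, cfg)
            cr, cc, rad = cfg.roi
            expected = [r for r in regions
                        if cfg.min_area <= r.area <= cfg.max_area
                        and (r.centroid[0] - cr) ** 2 + (r.centroid[1] - cc) ** 2 <= rad**2]
            assert [tuple(map(tuple, r.pixels)) for r in kept] == \
                   [tuple(map(tuple, r.pixels)) for r in expected]
            assert [r.label for r in kept] == list(range(1, len(kept) + 1))


class TestCountObjects:
    def test_blank_image_counts_zero(self):
        img = grey_image(np.zeros((32, 32)))
        assert count_objects(img, preset("FLUO")) == 0

    def test_synthetic_plate_count_matches_ground_truth(self, small_plate, fluo_config):
        assert count_objects(small_plate.image, fluo_config) == len(small_plate.truth)

    def test_podlike_sideview_count_matches_ground_truth(self):
        # elongated dark objects on a mid background, counted with a custom
        # detection setup (the generic object-counting use case)
        spec = default_spec("VISFRONT", "non-salt", seed=21, height=400, width=600,
                            dish_center=(200.0, 300.0), dish_radius=180.0,
                            n_seeds=12, semi_major_mean=25.0, semi_major_sd=3.0,
                            aspect_mean=5.0, aspect_sd=0.5)
        plate = generate_plate(spec)
        cfg = config(channel="grey", threshold=95, polarity="dark_objects",
                     min_area=30, max_area=5000)
        assert count_objects(plate.image, cfg) == 12
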