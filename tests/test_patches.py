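"""Patch extraction: bounding boxes, homogenization, IoU and blur QC."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.draw import ellipse

import mnquant as m
from mnquant.patches import bbox_iou

from conftest import brute_force_bboxes


class TestMaskToBboxes:
    def test_single_square(self):
        mask = np.zeros((40, 40), dtype=np.int32)
        mask[10:20, 10:20] = 3
        boxes = m.mask_to_bboxes(mask)
        assert len(boxes) == 1
        b = boxes[0]
        assert (b.label, b.y_min, b.y_max, b.x_min, b.x_max) == (3, 10, 20, 10, 20)

    def test_all_background_gives_empty_list(self):
        assert m.mask_to_bboxes(np.zeros((10, 10), dtype=np.int32)) == []

    def test_negative_labels_rejected(self):
        mask = np.zeros((5, 5), dtype=np.int32)
        mask[0, 0] = -1
        with pytest.raises(ValueError, match="negative"):
            m.mask_to_bboxes(mask)

    def test_non_consecutive_labels_and_sorting(self):
        mask = np.zeros((30, 30), dtype=np.int32)
        mask[1:4, 1:4] = 17
        mask[10:12, 10:15] = 5
        boxes = m.mask_to_bboxes(mask)
        assert [b.label for b in boxes] == [5, 17]

    def test_agrees_with_brute_force_scan(self, scene_grid):
        """Oracle equivalence on seeded synthetic scenes."""
        for scene in scene_grid:
            expected = brute_force_bboxes(scene.mask)
            got = {
                b.label: (b.y_min, b.y_max, b.x_min, b.x_max)
                for b in m.mask_to_bboxes(scene.mask)
            }
            assert got == expected


class TestExpandBbox:
    def test_expansion_with_lower_clipping(self):
        b = m.BoundingBox(1, 10, 20, 10, 20)
        e = m.expand_bbox(b, 20, (256, 256))
        assert (e.y_min, e.y_max, e.x_min, e.x_max) == (0, 40, 0, 40)

    def test_zero_expansion_is_identity(self):
        b = m.BoundingBox(1, 10, 20, 10, 20)
        assert m.expand_bbox(b, 0, (256, 256)) == b

    def test_upper_bound_clipping(self):
        b = m.BoundingBox(1, 250, 256, 250, 256)
        e = m.expand_bbox(b, 20, (256, 256))
        assert (e.y_min, e.y_max, e.x_min, e.x_max) == (230, 256, 230, 256)


class TestAreaPercentileFilter:
    def _boxes(self, areas):
        return [m.BoundingBox(i + 1, 0, 1, 0, a) for i, a in enumerate(areas)]

    def test_uniform_areas_1_to_100(self):
        # declared definition: linear-interpolation 5th percentile of 1..100
        # is 5.95; strict-below removes areas 1..5 (computed by the
        # independent sort-and-count oracle below)
        areas = list(range(1, 101))
        cutoff = np.percentile(np.sort(areas), 5.0)
        expected_removed = sorted(a for a in areas if a < cutoff)
        assert expected_removed == [1, 2, 3, 4, 5]
        kept, removed = m.filter_by_area_percentile(self._boxes(areas), 5.0)
        assert sorted(b.area for b in removed) == expected_removed
        assert len(kept) == 95

    def test_all_equal_areas_is_noop(self):
        kept, removed = m.filter_by_area_percentile(self._boxes([7] * 20), 5.0)
        assert removed == [] and len(kept) == 20

    def test_percentile_zero_removes_nothing(self):
        kept, removed = m.filter_by_area_percentile(self._boxes([1, 2, 3]), 0.0)
        assert removed == [] and len(kept) == 3

    def test_partition_property(self, default_scene):
        boxes = m.mask_to_bboxes(default_scene.mask)
        kept, removed = m.filter_by_area_percentile(boxes, 5.0)
        assert sorted(b.label for b in kept + removed) == sorted(b.label for b in boxes)
        # order within kept preserved
        kept_labels = [b.label for b in kept]
        original_order = [b.label for b in boxes if b in kept]
        assert kept_labels == original_order

    def test_invalid_percentile_rejected(self):
        with pytest.raises(ValueError):
            m.filter_by_area_percentile(self._boxes([1, 2]), 100.0)


class TestScalingFactor:
    def test_printed_default_ratio(self):
        b = m.BoundingBox(1, 0, 256, 0, 200)
        assert m.compute_scaling_factor(b, 0.65, 256) == pytest.approx(0.65)

    def test_double_size_nucleus(self):
        b = m.BoundingBox(1, 0, 512, 0, 300)
        assert m.compute_scaling_factor(b, 0.65, 256) == pytest.approx(1.30)

    def test_algebraic_identity(self):
        # max side = final_size / ratio  =>  factor 1
        b = m.BoundingBox(1, 0, 400, 0, 100)
        assert m.compute_scaling_factor(b, 0.5, 200) == pytest.approx(1.0)


class TestExtractPatch:
    def test_output_shape_is_final_size(self, default_scene):
        boxes = m.mask_to_bboxes(default_scene.mask)
        for b in boxes[:5]:
            patch = m.extract_patch(default_scene.image, b)  # defaults: 256
            assert patch.pixels.shape == (256, 256)

    def test_border_nucleus_still_full_size(self):
        img = np.zeros((64, 64), dtype=np.float32)
        mask = np.zeros((64, 64), dtype=np.int32)
        mask[0:10, 0:8] = 1
        img[0:10, 0:8] = 1.0
        b = m.mask_to_bboxes(mask)[0]
        patch = m.extract_patch(img, b, m.PatchExtractionConfig(final_size=64))
        assert patch.pixels.shape == (64, 64)

    def test_nucleus_footprint_occupies_ratio_of_patch(self):
        """A 100x80 tight box maps to a max footprint of 166 +/- 2 px."""
        img = np.zeros((300, 300), dtype=np.float32)
        mask = np.zeros((300, 300), dtype=np.int32)
        rr, cc = ellipse(150, 150, 50, 40)  # tight box 100 x 80 (spans 99x79)
        mask[rr, cc] = 1
        img[rr, cc] = 0.8
        b = m.mask_to_bboxes(mask)[0]
        cfg = m.PatchExtractionConfig()
        proj = m.project_mask_patch(mask, b, cfg)
        ys, xs = np.where(proj == 1)
        span = max(ys.max() - ys.min() + 1, xs.max() - xs.min() + 1)
        assert abs(span - round(0.65 * 256)) <= 2

    def test_footprint_ratio_invariant_across_scene(self, small_scene):
        cfg = m.PatchExtractionConfig(final_size=96)
        for b in m.mask_to_bboxes(small_scene.mask):
            proj = m.project_mask_patch(small_scene.mask, b, cfg)
            ys, xs = np.where(proj == b.label)
            span = max(ys.max() - ys.min() + 1, xs.max() - xs.min() + 1)
            assert abs(span / 96 - 0.65) <= 2 / 96

    def test_normalized_range_and_constant_patch(self):
        img = np.full((50, 50), 3.3, dtype=np.float32)
        mask = np.zeros((50, 50), dtype=np.int32)
        mask[20:30, 20:30] = 1
        b = m.mask_to_bboxes(mask)[0]
        patch = m.extract_patch(img, b, m.PatchExtractionConfig(final_size=64))
        assert np.all(patch.pixels == 0.0)  # degenerate normalization

    def test_bbox_outside_image_rejected(self):
        img = np.zeros((20, 20), dtype=np.float32)
        with pytest.raises(ValueError, match="outside"):
            m.extract_patch(img, m.BoundingBox(1, 10, 30, 0, 5))

    def test_non_finite_pixels_rejected(self):
        img = np.zeros((40, 40), dtype=np.float32)
        img[12, 12] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            m.extract_patch(img, m.BoundingBox(1, 10, 20, 10, 20))


class TestIouAudit:
    def test_identical_boxes(self):
        a = m.BoundingBox(1, 0, 10, 0, 10)
        b = m.BoundingBox(2, 0, 10, 0, 10)
        assert bbox_iou(a, b) == 1.0
        frac, flagged = m.iou_audit([a, b], 0.5)
        assert frac == 1.0 and len(flagged) == 1

    def test_disjoint_boxes(self):
        a = m.BoundingBox(1, 0, 10, 0, 10)
        b = m.BoundingBox(2, 20, 30, 20, 30)
        assert bbox_iou(a, b) == 0.0

    def test_hand_computed_overlap(self):
        # [0,10)x[0,10) vs [5,15)x[5,15): inter 25, union 175 -> 1/7
        a = m.BoundingBox(1, 0, 10, 0, 10)
        b = m.BoundingBox(2, 5, 15, 5, 15)
        assert bbox_iou(a, b) == pytest.approx(25 / 175)

    def test_symmetry_and_range(self, default_scene):
        boxes = m.mask_to_bboxes(default_scene.mask)[:12]
        for i in range(len(boxes)):
            for j in range(i + 1, len(boxes)):
                iou = bbox_iou(boxes[i], boxes[j])
                assert 0.0 <= iou <= 1.0
                assert iou == bbox_iou(boxes[j], boxes[i])

    def test_fewer_than_two_boxes(self):
        assert m.iou_audit([], 0.5) == (0.0, [])
        assert m.iou_audit([m.BoundingBox(1, 0, 5, 0, 5)], 0.5) == (0.0, [])


class TestBlurQC:
    def test_constant_patch_scores_zero(self):
        assert m.blur_score(np.full((32, 32), 0.5)) == 0.0

    def test_gaussian_blur_strictly_lowers_score(self, default_scene):
        cfg = m.PatchExtractionConfig(final_size=96)
        patches, _ = m.extract_patches(default_scene.image, default_scene.mask, cfg)
        for p in patches[:10]:
            blurred = ndi.gaussian_filter(p.pixels, 2.0)
            assert m.blur_score(blurred) < m.blur_score(p)

    def test_pct_out_of_focus_separates_clusters(self, default_scene):
        cfg = m.PatchExtractionConfig(final_size=96)
        patches, _ = m.extract_patches(default_scene.image, default_scene.mask, cfg)
        sharp = patches[:10]
        blurry = []
        for p in patches[10:20]:
            q = m.NucleusPatch(
                label=p.label, pixels=ndi.gaussian_filter(p.pixels, 4.0),
                scaling_factor=p.scaling_factor, source_bbox=p.source_bbox,
            )
            blurry.append(q)
        scores_sharp = [m.blur_score(p) for p in sharp]
        scores_blurry = [m.blur_score(p) for p in blurry]
        assert max(scores_blurry) < min(scores_sharp)  # clusters separate
        threshold = (max(scores_blurry) + min(scores_sharp)) / 2
        assert m.pct_out_of_focus(sharp + blurry, threshold) == 50.0


def test_extract_patches_shape_mismatch_rejected(default_scene):
    with pytest.raises(ValueError, match="shape"):
        m.extract_patches(default_scene.image[:-1], default_scene.mask)


def test_patch_manifest_columns(small_scene):
    patches, _ = m.extract_patches(
        small_scene.image, small_scene.mask,
        m.PatchExtractionConfig(final_size=64), source_image_id="img0",
    )
    manifest = m.patch_manifest(patches)
    assert list(manifest.columns) == [
        "image_id", "label", "y_min", "y_max", "x_min", "x_max",
        "scaling_factor", "blur_score",
    ]
    assert len(manifest) == len(patches)
    assert (manifest["image_id"] == "img0").all()
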