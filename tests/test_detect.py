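"""Box geometry, matching, detection metrics and the reference detector."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from woundkit.detect import (
    BoundingBox,
    Detection,
    average_precision,
    crop_wound,
    evaluate_detections,
    exclude_region,
    f1_score_detection,
    filter_detections_by_mask,
    iou,
    match_detections,
    mean_ap_50_95,
    reference_detector,
)
from woundkit.errors import InvalidInputError, UndefinedMetricError


def B(x0, y0, x1, y1):
    return BoundingBox(float(x0), float(y0), float(x1), float(y1))


boxes = st.builds(
    lambda x, y, w, h: B(x, y, x + w, y + h),
    st.floats(0, 50), st.floats(0, 50), st.floats(1, 50), st.floats(1, 50),
)


class TestIoU:
    def test_identical_boxes(self):
        assert iou(B(0, 0, 10, 10), B(0, 0, 10, 10)) == 1.0

    def test_disjoint_boxes(self):
        assert iou(B(0, 0, 10, 10), B(20, 20, 30, 30)) == 0.0

    def test_half_overlap_arithmetic(self):
        assert iou(B(0, 0, 10, 10), B(5, 0, 15, 10)) == pytest.approx(1 / 3)

    @settings(derandomize=True, max_examples=50)
    @given(boxes, boxes)
    def test_symmetric_and_bounded(self, a, b):
        v = iou(a, b)
        assert v == pytest.approx(iou(b, a))
        assert 0.0 <= v <= 1.0
        assert iou(a, a) == pytest.approx(1.0)

    def test_degenerate_box_rejected(self):
        with pytest.raises(InvalidInputError):
            B(5, 5, 5, 10)


class TestMaskFiltering:
    def make_mask(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[:, :20] = True  # left half is skin
        return mask

    def test_box_inside_skin_kept(self):
        dets = [Detection(B(2, 2, 12, 12), 0.9)]
        assert filter_detections_by_mask(dets, self.make_mask()) == dets

    def test_box_on_background_removed(self):
        dets = [Detection(B(25, 2, 35, 12), 0.9)]
        assert filter_detections_by_mask(dets, self.make_mask()) == []

    def test_threshold_boundary(self):
        # box straddling the edge: 40% of columns on skin
        dets = [Detection(B(16, 0, 26, 10), 0.5)]
        mask = self.make_mask()
        assert filter_detections_by_mask(dets, mask, 0.5) == []
        assert filter_detections_by_mask(dets, mask, 0.3) == dets

    def test_zero_threshold_is_identity(self, rng):
        dets = [Detection(B(30, 30, 39, 39), 0.2), Detection(B(1, 1, 5, 5), 0.8)]
        assert filter_detections_by_mask(dets, self.make_mask(), 0.0) == dets

    def test_exclude_region_blanks_rectangle(self):
        mask = np.ones((20, 20), dtype=bool)
        corners = np.array([[5.0, 5.0], [10.0, 5.0], [10.0, 10.0], [5.0, 10.0]])
        out = exclude_region(mask, corners, pad_px=1)
        assert not out[4:11, 4:11].any()
        assert out[0, 0] and out[-1, -1] and out[11, 11]


class TestMatching:
    def test_single_exact_match(self):
        m = match_detections([Detection(B(0, 0, 10, 10), 0.9)], [B(0, 0, 10, 10)], 0.5)
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)

    def test_duplicate_detection_is_fp(self):
        dets = [Detection(B(0, 0, 10, 10), 0.9), Detection(B(1, 0, 11, 10), 0.8)]
        m = match_detections(dets, [B(0, 0, 10, 10)], 0.5)
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)

    def test_matches_oracle_on_random_small_instances(self, rng):
        for _ in range(200):
            n_d, n_g = rng.integers(0, 4), rng.integers(1, 3)
            dets = [
                Detection(B(x, y, x + w, y + h), float(c))
                for x, y, w, h, c in zip(
                    rng.uniform(0, 30, n_d), rng.uniform(0, 30, n_d),
                    rng.uniform(2, 20, n_d), rng.uniform(2, 20, n_d),
                    rng.random(n_d),
                )
            ]
            gts = [
                B(x, y, x + w, y + h)
                for x, y, w, h in zip(
                    rng.uniform(0, 30, n_g), rng.uniform(0, 30, n_g),
                    rng.uniform(2, 20, n_g), rng.uniform(2, 20, n_g),
                )
            ]
            m = match_detections(dets, gts, 0.5)
            o_dets = [((d.box.x_min, d.box.y_min, d.box.x_max, d.box.y_max), d.confidence)
                      for d in dets]
            o_gts = [(g.x_min, g.y_min, g.x_max, g.y_max) for g in gts]
            flags, n_matched = oracles.greedy_match(o_dets, o_gts, 0.5)
            assert m.tp == sum(flags) == n_matched
            assert m.fp == len(flags) - sum(flags)


class TestAveragePrecision:
    def test_perfect_single_detection(self):
        assert average_precision([Detection(B(0, 0, 10, 10), 1.0)], [B(0, 0, 10, 10)]) == 1.0

    def test_all_false_detections(self):
        dets = [Detection(B(30, 30, 40, 40), 0.9)]
        assert average_precision(dets, [B(0, 0, 10, 10)]) == 0.0

    def test_tp_fp_tp_ranking_gives_five_sixths(self):
        # ranked TP, FP, TP over 2 ground truths
        gts = [B(0, 0, 10, 10), B(100, 0, 110, 10)]
        dets = [
            Detection(B(0, 0, 10, 10), 0.9),       # TP
            Detection(B(50, 50, 60, 60), 0.8),     # FP
            Detection(B(100, 0, 110, 10), 0.7),    # TP
        ]
        assert average_precision(dets, gts, 0.5) == pytest.approx(5 / 6)

    def test_no_ground_truth_rejected(self):
        with pytest.raises(UndefinedMetricError):
            average_precision([Detection(B(0, 0, 1, 1), 1.0)], [])


class TestMeanAp:
    def test_pixel_perfect_is_one(self):
        dets = [Detection(B(0, 0, 10, 10), 1.0)]
        assert mean_ap_50_95(dets, [B(0, 0, 10, 10)]) == 1.0

    def test_iou_06_passes_three_thresholds(self):
        # 10x10 gt, detection shifted so IoU = 0.6: passes 0.50/0.55/0.60
        gt = B(0, 0, 10, 10)
        det = Detection(B(2.5, 0, 12.5, 10), 1.0)
        assert iou(det.box, gt) == pytest.approx(0.6)
        assert mean_ap_50_95([det], [gt]) == pytest.approx(3 / 10)

    def test_empty_detections(self):
        assert mean_ap_50_95([], [B(0, 0, 10, 10)]) == 0.0


class TestF1:
    def test_perfect(self):
        assert f1_score_detection([Detection(B(0, 0, 9, 9), 1.0)], [B(0, 0, 9, 9)]) == 1.0

    def test_two_thirds_case(self):
        gts = [B(0, 0, 10, 10), B(50, 0, 60, 10), B(100, 0, 110, 10)]
        dets = [
            Detection(B(0, 0, 10, 10), 0.9),
            Detection(B(50, 0, 60, 10), 0.8),
            Detection(B(200, 0, 210, 10), 0.7),  # FP; third gt unmatched
        ]
        assert f1_score_detection(dets, gts, 0.5) == pytest.approx(2 / 3)

    def test_no_detections(self):
        assert f1_score_detection([], [B(0, 0, 10, 10)]) == 0.0


class TestCrop:
    def test_full_image_zero_pad_identity(self, rng):
        img = rng.integers(0, 255, (20, 30, 3))
        out = crop_wound(img, B(0, 0, 30, 20), 0.0)
        assert np.array_equal(out, img)

    def test_exact_crop_dims(self, rng):
        img = rng.integers(0, 255, (40, 40, 3))
        assert crop_wound(img, B(10, 10, 20, 20), 0.0).shape == (10, 10, 3)

    def test_corner_box_with_pad_clips_to_bounds(self, rng):
        img = rng.integers(0, 255, (40, 40, 3))
        out = crop_wound(img, B(0, 0, 10, 10), 0.1)
        assert out.shape == (11, 11, 3)  # 1 px pad only on the inner sides

    def test_disjoint_box_rejected(self, rng):
        img = rng.integers(0, 255, (40, 40, 3))
        with pytest.raises(InvalidInputError):
            crop_wound(img, B(100, 100, 120, 120), 0.0)


class TestReferenceDetector:
    def test_single_wound_found(self, default_scene, skin_scene_mask):
        img, gt = default_scene
        dets = reference_detector(img, skin_scene_mask)
        assert any(iou(d.box, gt.wound_box) >= 0.5 for d in dets)

    def test_wound_free_skin_yields_nothing(self):
        from woundkit.preprocess import skin_mask
        from woundkit.synthdata import SceneSpec, generate_scene

        img, gt = generate_scene(SceneSpec(seed=3, wound=False, marker=False))
        dets = reference_detector(img, skin_mask(img))
        assert dets == []

    def test_two_disjoint_wounds_give_two_boxes(self):
        # two wounds rendered by compositing a second scene's wound pixels
        from woundkit.preprocess import skin_mask
        from woundkit.synthdata import SceneSpec, generate_scene

        a, gta = generate_scene(SceneSpec(seed=5, marker=False,
                                          wound_center=(100.0, 100.0)))
        b, gtb = generate_scene(SceneSpec(seed=5, marker=False,
                                          wound_center=(190.0, 190.0)))
        img = a.copy()
        img[gtb.wound_mask] = b[gtb.wound_mask]
        dets = reference_detector(img, skin_mask(img))
        hits_a = any(iou(d.box, gta.wound_box) >= 0.5 for d in dets)
        hits_b = any(iou(d.box, gtb.wound_box) >= 0.5 for d in dets)
        assert hits_a and hits_b and len(dets) >= 2
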