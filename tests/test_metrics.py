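"""Evaluation suite: overlap metrics, PRF, Hausdorff, Hungarian matching,
average precision and dataset aggregation — each against an independent
brute-force oracle where one exists."""

import itertools
import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from conftest import inst, random_blob_mask, square_mask
from headseg.metrics import (
    ConfusionCounts,
    average_precision,
    boundary_points,
    evaluate_dataset,
    hausdorff,
    hungarian_match,
    mask_iou_matrix,
    overlap_metrics,
    pixel_accuracy,
    prf,
)


class TestOverlapMetrics:
    def test_identical_and_disjoint_masks(self):
        a = square_mask((8, 8), 1, 1, 4, 4)
        assert overlap_metrics(a, a)["iou"] == 1.0
        assert overlap_metrics(a, a)["dice"] == 1.0
        b = square_mask((8, 8), 5, 5, 8, 8)
        assert overlap_metrics(a, b)["iou"] == 0.0
        assert overlap_metrics(a, b)["dice"] == 0.0

    def test_two_squares_overlapping_two_pixels(self):
        a = square_mask((6, 6), 0, 0, 2, 2)
        b = square_mask((6, 6), 1, 0, 3, 2)  # overlap = 2 px
        m = overlap_metrics(a, b)
        assert m["iou"] == pytest.approx(2 / 6)
        assert m["dice"] == pytest.approx(4 / 8)

    def test_both_empty_is_flagged_undefined_not_zero(self):
        z = np.zeros((4, 4), dtype=bool)
        m = overlap_metrics(z, z)
        assert m["undefined"] and math.isnan(m["iou"])

    def test_matches_pixel_oracle_and_dice_dominates_iou(self, rng):
        for _ in range(30):
            a, b = random_blob_mask(rng), random_blob_mask(rng)
            m = overlap_metrics(a, b)
            tp = int((a & b).sum())
            fp = int((a & ~b).sum())
            fn = int((~a & b).sum())
            assert m["iou"] == tp / (tp + fp + fn)
            assert m["dice"] == 2 * tp / (2 * tp + fp + fn)
            assert m["dice"] >= m["iou"]


class TestPRF:
    def test_hand_arithmetic_example(self):
        out = prf(ConfusionCounts(tp=9, fp=1, fn=3))
        assert out["precision"] == pytest.approx(0.9)
        assert out["recall"] == pytest.approx(0.75)
        assert out["f1"] == pytest.approx(0.8182, abs=1e-4)

    def test_degenerate_counts_flagged(self):
        out = prf(ConfusionCounts(tp=0, fp=0, fn=5))
        assert out["recall"] == 0.0
        assert math.isnan(out["precision"])
        assert "precision" in out["undefined"]

    def test_f1_equals_precision_when_balanced(self):
        out = prf(ConfusionCounts(tp=8, fp=2, fn=2))
        assert out["f1"] == pytest.approx(out["precision"])

    def test_f1_equals_dice_on_induced_pixel_counts(self, rng):
        for _ in range(10):
            a, b = random_blob_mask(rng), random_blob_mask(rng)
            m = overlap_metrics(a, b)
            assert prf(m["pixel_counts"])["f1"] == pytest.approx(m["dice"])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1)


class TestPixelAccuracy:
    def test_identity_complement_and_partial(self):
        a = square_mask((10, 10), 0, 0, 5, 10)
        assert pixel_accuracy(a, a) == 1.0
        assert pixel_accuracy(a, ~a) == 0.0
        b = a.copy()
        b[:1, :] = ~b[:1, :]  # 10 of 100 pixels flipped
        assert pixel_accuracy(a, b) == pytest.approx(0.9)

    def test_empty_raster_rejected(self):
        with pytest.raises(ValueError):
            pixel_accuracy(np.zeros((0, 4), dtype=bool),
                           np.zeros((0, 4), dtype=bool))


def _hausdorff_oracle(a, b):
    pa, pb = boundary_points(a), boundary_points(b)
    d = cdist(pa, pb)
    return max(d.min(axis=1).max(), d.min(axis=0).max())


class TestHausdorff:
    def test_identical_masks_zero(self):
        a = square_mask((9, 9), 2, 2, 7, 7)
        assert hausdorff(a, a) == 0.0

    def test_three_four_five_single_pixels(self):
        a = np.zeros((6, 6), dtype=bool)
        b = np.zeros((6, 6), dtype=bool)
        a[0, 0] = True
        b[3, 4] = True
        assert hausdorff(a, b) == pytest.approx(5.0)

    def test_nested_squares_match_brute_force(self):
        outer = square_mask((24, 24), 2, 2, 22, 22)
        inner = square_mask((24, 24), 7, 7, 17, 17)
        assert hausdorff(outer, inner) == pytest.approx(
            _hausdorff_oracle(outer, inner))

    def test_metric_axioms_on_random_triples(self, rng):
        for _ in range(10):
            a, b, c = (random_blob_mask(rng) for _ in range(3))
            dab, dba = hausdorff(a, b), hausdorff(b, a)
            assert dab == pytest.approx(dba)  # symmetry
            assert hausdorff(a, a) == 0.0  # identity
            assert dab <= hausdorff(a, c) + hausdorff(c, b) + 1e-9  # triangle

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            hausdorff(np.zeros((4, 4), dtype=bool), square_mask((4, 4), 0, 0, 2, 2))


def _best_permutation_total(iou):
    """Exhaustive assignment oracle: max total IoU over all permutations."""
    n_p, n_g = iou.shape
    best = 0.0
    k = min(n_p, n_g)
    for rows in itertools.permutations(range(n_p), k):
        for cols in itertools.permutations(range(n_g), k):
            best = max(best, sum(iou[r, c] for r, c in zip(rows, cols)))
    return best


class TestHungarianMatch:
    def test_exact_single_pair(self):
        m = square_mask((8, 8), 1, 1, 5, 5)
        res = hungarian_match([inst(m, 0.9)], [inst(m)])
        assert res.pairs == [(0, 0, 1.0)]
        assert not res.unmatched_pred and not res.unmatched_gt

    def test_empty_prediction_list(self):
        gt = [inst(square_mask((6, 6), 0, 0, 3, 3))]
        res = hungarian_match([], gt)
        assert res.pairs == [] and res.unmatched_gt == [0]

    def test_matches_exhaustive_permutation_oracle(self, rng):
        for trial in range(12):
            n_p, n_g = rng.integers(1, 7), rng.integers(1, 7)
            preds = [inst(random_blob_mask(rng), 0.5) for _ in range(n_p)]
            gts = [inst(random_blob_mask(rng)) for _ in range(n_g)]
            iou = mask_iou_matrix(preds, gts)
            res = hungarian_match(preds, gts)
            total = sum(p[2] for p in res.pairs)
            assert total == pytest.approx(_best_permutation_total(iou), abs=1e-9)

    def test_min_iou_discards_weak_pairs(self, rng):
        a = square_mask((10, 10), 0, 0, 5, 5)
        b = square_mask((10, 10), 4, 4, 9, 9)  # IoU = 1/49
        res = hungarian_match([inst(a, 0.9)], [inst(b)], min_iou=0.5)
        assert res.pairs == []
        assert res.unmatched_pred == [0] and res.unmatched_gt == [0]

    def test_one_to_one_constraint(self, rng):
        preds = [inst(random_blob_mask(rng), 0.5) for _ in range(5)]
        gts = [inst(random_blob_mask(rng)) for _ in range(3)]
        res = hungarian_match(preds, gts)
        assert len({p for p, _, _ in res.pairs}) == len(res.pairs)
        assert len({g for _, g, _ in res.pairs}) == len(res.pairs)

    def test_invalid_min_iou_rejected(self):
        with pytest.raises(ValueError):
            hungarian_match([], [], min_iou=1.0)


class TestAveragePrecision:
    def test_single_matching_detection(self):
        assert average_precision([(0.3, True)], 1) == 1.0

    def test_spurious_lower_confidence_detection_keeps_ap_one(self):
        assert average_precision([(0.9, True), (0.8, False)], 1,
                                 interpolation_mode="all_point") == 1.0

    def test_confidence_order_irrelevant_when_all_tp(self):
        dets = [(0.1, True), (0.5, True), (0.9, True)]
        assert average_precision(dets, 3) == 1.0
        assert average_precision([(1 - c, t) for c, t in dets], 3) == 1.0

    def test_hand_built_pr_curve(self):
        # ranks: TP FP TP TP FP over 4 gt -> all-point area 0.625 (by hand)
        dets = [(0.9, True), (0.8, False), (0.7, True), (0.6, True), (0.5, False)]
        assert average_precision(dets, 4, interpolation_mode="all_point") == (
            pytest.approx(0.625))
        assert average_precision(dets, 4, interpolation_mode="101_point") == (
            pytest.approx(0.625))

    def test_zero_gt_with_detections_is_undefined(self):
        assert math.isnan(average_precision([(0.5, False)], 0))
        assert average_precision([], 0) == 0.0

    def test_101_point_never_exceeds_all_point(self, rng):
        for _ in range(50):
            n_gt = int(rng.integers(1, 40))
            n_det = int(rng.integers(1, 80))
            n_tp = int(rng.integers(0, min(n_gt, n_det) + 1))
            flags = np.zeros(n_det, dtype=bool)
            flags[rng.choice(n_det, n_tp, replace=False)] = True
            dets = [(float(c), bool(t))
                    for c, t in zip(rng.random(n_det), flags)]
            a101 = average_precision(dets, n_gt, interpolation_mode="101_point")
            aall = average_precision(dets, n_gt, interpolation_mode="all_point")
            assert a101 <= aall + 1e-12

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            average_precision([], 1, interpolation_mode="11_point")


def _perfect_fixture(rng, n_images=3):
    gts = []
    for _ in range(n_images):
        gts.append([inst(random_blob_mask(rng), class_id=0)
                    for _ in range(int(rng.integers(1, 4)))])
    preds = [[inst(g.mask.copy(), conf=0.9) for g in img] for img in gts]
    return preds, gts


class TestEvaluateDataset:
    def test_perfect_predictor_identity_all_protocols(self, rng):
        preds, gts = _perfect_fixture(rng)
        for protocol in ("coco", "yolo", "sam_universal"):
            r = evaluate_dataset(preds, gts, protocol)
            if protocol in ("coco", "yolo"):
                assert r.map50 == 1.0 and r.map50_95 == 1.0
            assert r.precision == 1.0 and r.recall == 1.0
            if protocol == "sam_universal":
                assert r.iou_mean == 1.0 and r.dice_mean == 1.0
                assert r.pa == 1.0 and r.hausdorff_mean == 0.0

    def test_empty_predictions_zero_recall_and_ap(self, rng):
        _, gts = _perfect_fixture(rng)
        r = evaluate_dataset([[] for _ in gts], gts, "yolo")
        assert r.recall == 0.0 and r.map50 == 0.0

    def test_three_image_fixture_matches_hand_computed_map(self):
        # disjoint unit squares so every IoU is exactly 0 or 1; detection
        # ranking TP FP TP TP FP over 4 gt reproduces the hand-built 0.625 AP
        shape = (16, 16)
        cells = [square_mask(shape, 2 * i, 2 * i, 2 * i + 2, 2 * i + 2)
                 for i in range(6)]
        gts = [[inst(cells[0]), inst(cells[1])], [inst(cells[2])],
               [inst(cells[3])]]
        preds = [
            [inst(cells[0], 0.9), inst(cells[4], 0.8)],
            [inst(cells[2], 0.7), inst(cells[5], 0.5)],
            [inst(cells[3], 0.6)],
        ]
        r = evaluate_dataset(preds, gts, "yolo")
        assert r.map50 == pytest.approx(0.625)

    def test_sam_universal_pooled_vs_per_instance_aggregation(self, rng):
        preds, gts = _perfect_fixture(rng)
        pooled = evaluate_dataset(preds, gts, "sam_universal",
                                  aggregation="dataset_pooled")
        assert pooled.iou_mean == 1.0 and pooled.dice_mean == 1.0
        assert pooled.aggregation == "dataset_pooled"

    def test_unknown_protocol_rejected(self, rng):
        preds, gts = _perfect_fixture(rng)
        with pytest.raises(ValueError):
            evaluate_dataset(preds, gts, "voc")

    def test_misaligned_lists_rejected(self):
        with pytest.raises(ValueError):
            evaluate_dataset([[]], [[], []], "yolo")
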