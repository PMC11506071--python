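"""Evaluation stack: confusion cells, metrics, polygons, dataset outputs."""

import numpy as np
import pandas as pd
import pytest

from laryngoseg.color_codec import COLOR_TABLE, HueBandRule, class_mask
from laryngoseg.evaluation import (
    ConfusionCells,
    MAUC_HALF_WIDTHS,
    accuracy,
    confusion_cells,
    evaluate_ground_truth,
    evaluate_pairs,
    extract_max_polygon,
    f1_per_image,
    gram_difference,
    iou_boxes,
    iou_pixels,
    mauc,
    precision_recall,
)
from laryngoseg.reference_tables import TEST_1035, TEST_300, WORKED_EXAMPLE_CELLS

from test_color_codec import brute_force_classify


def paint(shape, patches):
    """Black canvas with [(class_id, y0, y1, x0, x1), ...] painted solid."""
    img = np.zeros((*shape, 3), dtype=np.uint8)
    for class_id, y0, y1, x0, x1 in patches:
        img[y0:y1, x0:x1] = COLOR_TABLE[class_id].rgb
    return img


def oracle_cells(pred_img, gt_img, class_id):
    tp = tn = fp = fn = 0
    for y in range(pred_img.shape[0]):
        for x in range(pred_img.shape[1]):
            p = brute_force_classify(pred_img[y, x]) == class_id
            g = brute_force_classify(gt_img[y, x]) == class_id
            tp += p and g
            fp += p and not g
            fn += g and not p
            tn += not p and not g
    return ConfusionCells(tp, tn, fp, fn)


class TestConfusionCells:
    def test_perfect_prediction_counts(self):
        gt = paint((4, 4), [])
        for y, x in [(0, 0), (1, 1), (2, 3), (3, 0), (3, 3)]:
            gt[y, x] = COLOR_TABLE[6].rgb
        cells = confusion_cells(gt, gt, 6)
        assert (cells.tp, cells.tn, cells.fp, cells.fn) == (5, 11, 0, 0)

    def test_all_black_prediction_gives_only_misses(self):
        gt = paint((8, 8), [(6, 0, 3, 0, 3)])
        cells = confusion_cells(np.zeros_like(gt), gt, 6)
        assert cells.fn == 9 and cells.fp == 0 and cells.tp == 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_cells(np.zeros((4, 4, 3), np.uint8), np.zeros((5, 5, 3), np.uint8), 0)

    def test_matches_per_pixel_oracle_on_random_pairs(self, rng):
        for _ in range(3):
            pred = rng.integers(0, 256, size=(8, 8, 3), dtype=np.uint8)
            gt = rng.integers(0, 256, size=(8, 8, 3), dtype=np.uint8)
            for class_id in (0, 3, 6):
                got = confusion_cells(pred, gt, class_id)
                want = oracle_cells(pred, gt, class_id)
                assert (got.tp, got.tn, got.fp, got.fn) == (want.tp, want.tn, want.fp, want.fn)

    def test_conservation(self, rng):
        pred = rng.integers(0, 256, size=(8, 8, 3), dtype=np.uint8)
        gt = rng.integers(0, 256, size=(8, 8, 3), dtype=np.uint8)
        for class_id in range(7):
            assert confusion_cells(pred, gt, class_id).total == 64


class TestScalarMetrics:
    def test_worked_example_accuracy(self):
        assert accuracy(WORKED_EXAMPLE_CELLS) == pytest.approx(0.989, abs=5e-4)

    def test_perfect_negative_case(self):
        assert accuracy((0, 100, 0, 0)) == 1.0

    def test_second_campaign_class6_accuracy(self):
        cells = (2814.15, 93923.13, 697.20, 869.52)
        assert accuracy(cells) == pytest.approx(0.984, abs=5e-4)
        assert round(accuracy(cells), 2) == 0.98

    def test_all_zero_cells_rejected(self):
        with pytest.raises(ValueError):
            accuracy((0, 0, 0, 0))

    def test_printed_class6_precision_recall(self):
        row = TEST_300[0]
        p, r = precision_recall((row.tp, row.tn, row.fp, row.fn))
        assert round(p, 2) == 0.85 and round(r, 2) == 0.78

    def test_printed_class0_precision_recall(self):
        row = next(r for r in TEST_300 if r.class_id == 0)
        p, r = precision_recall((row.tp, row.tn, row.fp, row.fn))
        assert p == pytest.approx(0.647, abs=5e-3)
        assert r == pytest.approx(0.273, abs=5e-3)
        assert round(p, 2) == 0.65 and round(r, 2) == 0.27

    def test_balanced_cells_give_half(self):
        p, r = precision_recall((5, 0, 5, 5))
        assert p == 0.5 and r == 0.5

    def test_degenerate_cells_give_zero(self):
        assert precision_recall((0, 10, 0, 0)) == (0.0, 0.0)

    def test_f1_perfect_and_missed(self):
        assert f1_per_image((10, 54, 0, 0)) == 1.0
        assert f1_per_image((0, 54, 0, 10)) == 0.0

    def test_f1_equals_harmonic_mean_of_precision_recall(self, rng):
        for _ in range(20):
            tp, fp, fn = rng.integers(1, 50, size=3)
            p, r = precision_recall((tp, 0, fp, fn))
            harmonic = 2 * p * r / (p + r)
            assert f1_per_image((tp, 0, fp, fn)) == pytest.approx(harmonic)

    def test_iou_f1_algebraic_identity(self, rng):
        for _ in range(10):
            pred = rng.random((12, 12)) > 0.6
            gt = rng.random((12, 12)) > 0.6
            cells = _mask_cells(pred, gt)
            f1 = f1_per_image(cells)
            if f1 > 0:
                assert iou_pixels(pred, gt) == pytest.approx(f1 / (2 - f1))


def _mask_cells(pred, gt):
    tp = np.sum(pred & gt)
    fp = np.sum(pred & ~gt)
    fn = np.sum(~pred & gt)
    return ConfusionCells(tp, pred.size - tp - fp - fn, fp, fn)


class TestIoU:
    def test_identical_masks(self, rng):
        m = rng.random((16, 16)) > 0.7
        if not m.any():
            m[0, 0] = True
        assert iou_pixels(m, m.copy()) == 1.0
        assert iou_boxes(m, m.copy()) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((16, 16), bool)
        b = np.zeros((16, 16), bool)
        a[0:4, 0:4] = True
        b[10:14, 10:14] = True
        assert iou_pixels(a, b) == 0.0
        assert iou_boxes(a, b) == 0.0

    def test_offset_rectangles_give_one_third(self):
        a = np.zeros((32, 32), bool)
        b = np.zeros((32, 32), bool)
        a[5:15, 5:15] = True
        b[5:15, 10:20] = True  # overlap 10×5 = 50, union 150
        assert iou_pixels(a, b) == pytest.approx(1 / 3)
        assert iou_boxes(a, b) == pytest.approx(1 / 3)

    def test_both_empty_defined_as_zero(self):
        empty = np.zeros((8, 8), bool)
        assert iou_pixels(empty, empty) == 0.0
        assert iou_boxes(empty, empty) == 0.0


def mauc_oracle(pred_img, gt_img, class_id, rule=HueBandRule()):
    """Independent sweep: per-pixel oracle classification at each width."""
    gt = np.array(
        [[brute_force_classify(gt_img[y, x], rule) == class_id
          for x in range(gt_img.shape[1])] for y in range(gt_img.shape[0])]
    )
    n_pos, n_neg = gt.sum(), gt.size - gt.sum()
    pts = [(0.0, 0.0), (1.0, 1.0)]
    for width in MAUC_HALF_WIDTHS:
        wide = HueBandRule(width, rule.min_saturation, rule.min_value)
        pred = np.array(
            [[brute_force_classify(pred_img[y, x], wide) == class_id
              for x in range(pred_img.shape[1])] for y in range(pred_img.shape[0])]
        )
        pts.append((np.sum(pred & ~gt) / n_neg, np.sum(pred & gt) / n_pos))
    pts.sort()
    xs, ys = zip(*pts)
    return float(np.trapezoid(ys, xs))


class TestMauc:
    def test_perfect_prediction_near_ceiling(self):
        gt = paint((16, 16), [(6, 2, 10, 2, 10)])
        assert mauc(gt, gt, 6) > 0.9

    def test_all_black_prediction_at_most_half(self):
        gt = paint((16, 16), [(6, 2, 10, 2, 10)])
        assert mauc(np.zeros_like(gt), gt, 6) <= 0.5

    def test_empty_ground_truth_flagged_as_nan(self):
        img = paint((8, 8), [(6, 0, 2, 0, 2)])
        assert np.isnan(mauc(img, np.zeros_like(img), 6))

    def test_matches_independent_sweep_oracle(self, rng):
        pred = rng.integers(0, 256, size=(8, 8, 3), dtype=np.uint8)
        gt = paint((8, 8), [(6, 1, 5, 1, 5)])
        assert mauc(pred, gt, 6) == pytest.approx(mauc_oracle(pred, gt, 6), abs=1e-6)


class TestGramDifference:
    def test_identical_features_give_zero(self, rng):
        f = rng.normal(size=(4, 5, 5))
        assert gram_difference(f, f.copy()) == 0.0

    def test_scaling_bilinearity(self, rng):
        f = rng.normal(size=(3, 4, 4))
        zero = np.zeros_like(f)
        base = gram_difference(f, zero)
        assert gram_difference(2 * f, f) == pytest.approx(3 * base, rel=1e-6)

    def test_manual_two_channel_oracle(self):
        a = np.array([[[1.0, 2.0], [0.0, 1.0]], [[0.0, 1.0], [1.0, 0.0]]])
        b = np.zeros_like(a)
        # flattened channels a0=[1,2,0,1], a1=[0,1,1,0]:
        # G(a) = [[a0·a0, a0·a1], [a1·a0, a1·a1]] / 8 = [[6, 2], [2, 2]] / 8
        expected = np.linalg.norm(np.array([[6.0, 2.0], [2.0, 2.0]]) / 8.0)
        assert gram_difference(a, b) == pytest.approx(expected)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            gram_difference(np.zeros((2, 3, 3)), np.zeros((2, 4, 4)))


class TestExtractMaxPolygon:
    def test_single_square(self):
        img = paint((64, 64), [(6, 20, 30, 20, 30)])
        record = extract_max_polygon(img, 6)
        assert record.area == 100
        assert record.centroid == pytest.approx((24.5, 24.5))
        assert record.area_ratio == 1.0
        assert record.n_colors == 1
        assert len(record.vertices) > 0

    def test_two_class_area_ratio(self):
        img = paint((64, 64), [(6, 0, 10, 0, 10), (0, 40, 50, 40, 46)])
        rec6 = extract_max_polygon(img, 6)
        assert rec6.area_ratio == pytest.approx(100 / 160)
        assert rec6.n_colors == 2

    def test_all_black_gives_empty_record(self):
        record = extract_max_polygon(np.zeros((32, 32, 3), np.uint8), 6)
        assert record.area == 0.0 and record.n_colors == 0
        assert len(record.vertices) == 0


class TestDatasetEvaluation:
    def test_ground_truth_against_itself_is_perfect(self, tiny_manifest, tmp_path):
        table, preds, summary = evaluate_ground_truth(tiny_manifest, tmp_path / "selftest")
        present = table[table.TP > 0]
        assert len(present) > 0
        for col in ("F1", "IoU", "Precision", "Recall"):
            np.testing.assert_allclose(present[col], 1.0)

    def test_prediction_csv_schema(self, tiny_manifest, tmp_path):
        _, preds, _ = evaluate_ground_truth(tiny_manifest, tmp_path / "schema")
        assert list(preds.columns) == [f"C{i}" for i in range(1, 14)]
        assert len(preds) == len(tiny_manifest.rows("test"))
        assert ((preds["C10"] >= 0) & (preds["C10"] <= 1)).all()

    def test_mean_cells_equal_mean_of_per_image_cells(self, rng):
        preds = [rng.integers(0, 256, size=(8, 8, 3), dtype=np.uint8) for _ in range(10)]
        gts = [paint((8, 8), [(6, 0, rng.integers(1, 6), 0, rng.integers(1, 6))]) for _ in range(10)]
        table = evaluate_pairs(preds, gts)
        row = table[table.Cls == 6].iloc[0]
        manual = [confusion_cells(p, g, 6) for p, g in zip(preds, gts)]
        assert row.TP == pytest.approx(np.mean([c.tp for c in manual]))
        assert row.FN == pytest.approx(np.mean([c.fn for c in manual]))

    def test_permutation_invariance(self, rng):
        preds = [rng.integers(0, 256, size=(8, 8, 3), dtype=np.uint8) for _ in range(6)]
        gts = [paint((8, 8), [(5, 0, 4, 0, 4)]) for _ in range(6)]
        table_a = evaluate_pairs(preds, gts)
        order = rng.permutation(6)
        table_b = evaluate_pairs([preds[i] for i in order], [gts[i] for i in order])
        pd.testing.assert_frame_equal(table_a, table_b)

    def test_output_files_written(self, tiny_manifest, tmp_path):
        _, _, summary = evaluate_ground_truth(tiny_manifest, tmp_path / "files")
        out = summary["out_dir"]
        from pathlib import Path

        root = Path(out)
        assert (root / "metrics.csv").exists()
        assert (root / "predictions.csv").exists()
        n_test = len(tiny_manifest.rows("test"))
        assert len(list((root / "JPG").glob("*.jpg"))) == n_test
        assert len(list((root / "PNG").glob("*.png"))) == n_test


class TestPrintedTableIdentities:
    """The published per-class tables are reproduced from their own cells."""

    @pytest.mark.parametrize("row", TEST_300 + TEST_1035,
                             ids=lambda r: f"n{r.count}-cls{r.class_id}")
    def test_precision_recall_acc_match_printed_columns(self, row):
        cells = (row.tp, row.tn, row.fp, row.fn)
        p, r = precision_recall(cells)
        assert round(p, 2) == pytest.approx(row.precision, abs=1e-9)
        assert round(r, 2) == pytest.approx(row.recall, abs=1e-9)
        assert round(accuracy(cells), 2) == pytest.approx(row.acc, abs=1e-9)
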