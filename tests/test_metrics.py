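"""Metric suite: confusion counts, accuracies, IoU family, Dice, BF
score and the error overlay, each checked against independent
per-pixel brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from busseg.metrics import (
    ConfusionCounts,
    accuracy_metrics,
    bf_score,
    boundary_pixels,
    confusion_counts,
    default_bf_tolerance,
    dice,
    evaluate_pair,
    evaluate_set,
    iou_metrics,
    overlay_errors,
)

from conftest import bf_score_loop, boundary_loop, confusion_loop, random_mask_pair

EXAMPLE = ConfusionCounts(tp=6, fp=2, fn=2, tn=90)


class TestConfusion:
    def test_identical_masks(self, rng):
        gold = (rng.random((12, 12)) < 0.3).astype(np.uint8)
        c = confusion_counts(gold, gold)
        k = int(gold.sum())
        assert (c.tp, c.fp, c.fn, c.tn) == (k, 0, 0, 144 - k)

    def test_all_background_prediction(self, rng):
        gold = (rng.random((12, 12)) < 0.3).astype(np.uint8)
        c = confusion_counts(np.zeros_like(gold), gold)
        k = int(gold.sum())
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, k, 144 - k)

    def test_matches_per_pixel_loop(self, rng):
        pred, gold = random_mask_pair(rng, side=8)
        c = confusion_counts(pred, gold)
        assert (c.tp, c.fp, c.fn, c.tn) == confusion_loop(pred, gold)

    def test_shape_and_label_validation(self):
        with pytest.raises(ValueError):
            confusion_counts(np.zeros((3, 3)), np.zeros((4, 4)))
        with pytest.raises(ValueError):
            confusion_counts(np.full((3, 3), 2), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, fn=0, tn=0)


class TestScalarMetrics:
    def test_worked_example(self):
        """TP=6 FP=2 FN=2 TN=90: hand substitution into the formulas."""
        g, m = accuracy_metrics(EXAMPLE)
        assert g == pytest.approx(0.96)
        assert m == pytest.approx((0.75 + 90 / 92) / 2)
        iou_l, iou_b, mean_iou, weighted, w_l, w_b = iou_metrics(EXAMPLE)
        assert iou_l == pytest.approx(0.6)
        assert iou_b == pytest.approx(90 / 94)
        assert mean_iou == pytest.approx((0.6 + 90 / 94) / 2)
        assert (w_l, w_b) == (0.08, 0.92)
        assert weighted == pytest.approx(0.08 * 0.6 + 0.92 * 90 / 94)
        assert dice(EXAMPLE) == pytest.approx(0.75)

    def test_perfect_prediction(self):
        c = ConfusionCounts(tp=10, fp=0, fn=0, tn=90)
        assert accuracy_metrics(c) == (1.0, 1.0)
        assert iou_metrics(c)[:4] == (1.0, 1.0, 1.0, 1.0)
        assert dice(c) == 1.0

    def test_all_background_on_half_lesion_gold(self):
        c = ConfusionCounts(tp=0, fp=0, fn=50, tn=50)
        g, m = accuracy_metrics(c)
        assert g == 0.5 and m == 0.5

    def test_disjoint_masks_give_zero_dice(self):
        assert dice(ConfusionCounts(tp=0, fp=5, fn=5, tn=90)) == 0.0

    def test_empty_class_flags_nan_not_zero(self):
        no_lesion = ConfusionCounts(tp=0, fp=0, fn=0, tn=100)
        assert math.isnan(accuracy_metrics(no_lesion)[1])
        assert math.isnan(iou_metrics(no_lesion)[0])
        assert math.isnan(dice(no_lesion))

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    @settings(max_examples=60, derandomize=True)
    def test_bounds_and_dice_iou_identity(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        c = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)
        vals = [*accuracy_metrics(c), *iou_metrics(c), dice(c)]
        for v in vals:
            assert math.isnan(v) or 0.0 <= v <= 1.0
        iou_l = iou_metrics(c)[0]
        if not math.isnan(iou_l):
            assert dice(c) == pytest.approx(2 * iou_l / (1 + iou_l))

    def test_flipping_fp_to_tn_never_hurts(self):
        c0 = ConfusionCounts(tp=6, fp=3, fn=2, tn=89)
        c1 = ConfusionCounts(tp=6, fp=2, fn=2, tn=90)
        assert accuracy_metrics(c1)[0] >= accuracy_metrics(c0)[0]
        assert iou_metrics(c1)[0] >= iou_metrics(c0)[0]
        assert dice(c1) >= dice(c0)


class TestOracleEquivalence:
    def test_vectorized_matches_loop_on_random_pairs(self, rng):
        """All count-derived metrics equal an independent per-pixel loop
        implementation on 100 random 16x16 pairs."""
        for _ in range(100):
            pred, gold = random_mask_pair(rng)
            c = confusion_counts(pred, gold)
            tp, fp, fn, tn = confusion_loop(pred, gold)
            assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)
            total = 256
            g, m = accuracy_metrics(c)
            assert g == pytest.approx((tp + tn) / total, abs=1e-12)
            if tp + fn and tn + fp:
                assert m == pytest.approx(
                    (tp / (tp + fn) + tn / (tn + fp)) / 2, abs=1e-12
                )
            iou_l = iou_metrics(c)[0]
            if tp + fn + fp:
                assert iou_l == pytest.approx(tp / (tp + fn + fp), abs=1e-12)

    def test_label_swap_symmetry(self, rng):
        pred, gold = random_mask_pair(rng)
        a = iou_metrics(confusion_counts(pred, gold))
        b = iou_metrics(confusion_counts(1 - pred, 1 - gold))
        assert a[0] == pytest.approx(b[1])
        assert a[4] == pytest.approx(b[5])
        assert accuracy_metrics(confusion_counts(pred, gold))[0] == pytest.approx(
            accuracy_metrics(confusion_counts(1 - pred, 1 - gold))[0]
        )


class TestBFScore:
    def test_identity_scores_one(self, rng):
        gold = np.zeros((20, 20), dtype=np.uint8)
        gold[5:15, 6:14] = 1
        for tol in (0, 1, 3):
            assert bf_score(gold, gold, tol) == 1.0

    def test_boundary_matches_loop(self, rng):
        mask = (rng.random((16, 16)) < 0.4).astype(np.uint8)
        assert np.array_equal(boundary_pixels(mask), boundary_loop(mask))

    def test_shifted_square_matches_brute_force(self):
        """Square shifted beyond the tolerance: score computed by
        all-pairs distance matching on a 32x32 instance."""
        gold = np.zeros((32, 32), dtype=np.uint8)
        gold[10:20, 10:20] = 1
        tol = 2
        pred = np.roll(gold, tol + 2, axis=1)
        assert bf_score(pred, gold, tol) == pytest.approx(
            bf_score_loop(pred, gold, tol), abs=1e-12
        )

    def test_random_pairs_match_brute_force(self, rng):
        for _ in range(5):
            pred, gold = random_mask_pair(rng, side=12)
            for tol in (0, 1, 2):
                got = bf_score(pred, gold, tol)
                want = bf_score_loop(pred, gold, tol)
                assert (math.isnan(got) and math.isnan(want)) or got == pytest.approx(
                    want, abs=1e-12
                )

    def test_empty_pred_boundary_scores_zero(self):
        gold = np.zeros((10, 10), dtype=np.uint8)
        gold[3:7, 3:7] = 1
        assert bf_score(np.zeros_like(gold), gold, 2) == 0.0

    def test_both_empty_flagged_missing(self):
        z = np.zeros((10, 10), dtype=np.uint8)
        assert math.isnan(bf_score(z, z, 2))

    def test_default_tolerance_tracks_diagonal(self):
        assert default_bf_tolerance((160, 160)) == math.ceil(0.0075 * math.hypot(160, 160))
        assert default_bf_tolerance((320, 320)) == 4


class TestOverlay:
    def test_perfect_prediction_has_no_error_colors(self, rng):
        gold = (rng.random((16, 16)) < 0.3).astype(np.uint8)
        img = overlay_errors(gold, gold)
        assert not (img == (255, 105, 180)).all(axis=-1).any()
        assert not (img == (0, 200, 0)).all(axis=-1).any()

    def test_all_lesion_on_all_background_is_all_pink(self):
        pred = np.ones((8, 8), dtype=np.uint8)
        gold = np.zeros_like(pred)
        img = overlay_errors(pred, gold)
        assert (img == (255, 105, 180)).all(axis=-1).all()

    def test_error_pixel_counts_match_confusion(self, rng):
        pred, gold = random_mask_pair(rng)
        img = overlay_errors(pred, gold)
        c = confusion_counts(pred, gold)
        assert (img == (255, 105, 180)).all(axis=-1).sum() == c.fp
        assert (img == (0, 200, 0)).all(axis=-1).sum() == c.fn

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            overlay_errors(np.zeros((3, 3)), np.zeros((4, 4)))


class TestEvaluateSet:
    def _pair(self, rng):
        gold = np.zeros((20, 20), dtype=np.uint8)
        gold[4:16, 4:16] = 1
        pred = gold.copy()
        pred[rng.integers(4, 16), rng.integers(4, 16)] = 0
        return pred, gold

    def test_single_pair_mean_equals_report_std_missing(self, rng):
        pair = self._pair(rng)
        per_image, summary = evaluate_set([pair])
        report = evaluate_pair(*pair)
        assert per_image.loc[0, "dice"] == pytest.approx(report.dice)
        assert summary.loc["dice", "mean"] == pytest.approx(report.dice)
        assert math.isnan(summary.loc["dice", "std"])

    def test_two_identical_pairs_zero_std(self, rng):
        pair = self._pair(rng)
        _, summary = evaluate_set([pair, pair])
        assert summary.loc["global_accuracy", "std"] == 0.0

    def test_three_pairs_mean_is_hand_average(self, rng):
        pairs = [self._pair(rng) for _ in range(3)]
        per_image, summary = evaluate_set(pairs)
        by_hand = np.mean([evaluate_pair(*p).iou_lesion for p in pairs])
        assert summary.loc["iou_lesion", "mean"] == pytest.approx(by_hand)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            evaluate_set([])
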