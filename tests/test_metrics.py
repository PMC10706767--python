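"""Dice, top-margin error, pooled AUC, and the threshold sweep."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from marginseg.metrics import (
    dice_coefficient,
    roc_auc,
    threshold_sweep,
    tumor_margin_error,
)
from marginseg.phantom import tradeoff_probability_maps

from conftest import blob_mask, random_mask


class TestDice:
    def test_identity_and_disjoint(self):
        a = blob_mask((10, 10), 2, 5, 2, 5)
        b = blob_mask((10, 10), 6, 9, 6, 9)
        assert dice_coefficient(a, a) == 1.0
        assert dice_coefficient(a, b) == 0.0

    def test_partial_overlap_arithmetic(self):
        truth = blob_mask((20, 20), 0, 10, 0, 10)  # 100 px
        pred = blob_mask((20, 20), 0, 5, 0, 10)  # 50 px, all inside truth
        assert dice_coefficient(truth, pred) == pytest.approx(2 * 50 / 150)

    def test_empty_conventions(self):
        empty = np.zeros((5, 5))
        full = np.ones((5, 5))
        assert dice_coefficient(empty, empty) == 1.0
        assert dice_coefficient(full, empty) == 0.0

    def test_symmetric_and_flip_invariant(self, rng):
        a, b = random_mask(rng), random_mask(rng)
        assert dice_coefficient(a, b) == dice_coefficient(b, a)
        assert dice_coefficient(a, b) == dice_coefficient(a[::-1], b[::-1])

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice_coefficient(np.ones((4, 4)), np.ones((5, 4)))


class TestMarginError:
    def test_fig_style_example(self):
        truth = blob_mask((30, 30), 10, 20, 5, 25)
        pred = blob_mask((30, 30), 14, 20, 5, 25)
        m = tumor_margin_error(truth, pred, row_spacing_mm=0.1)
        assert (m.tm_gt, m.tm_pred) == (10, 14)
        assert m.error_mm == pytest.approx(0.4)

    def test_identical_masks_zero(self):
        truth = blob_mask((30, 30), 10, 20, 5, 25)
        assert tumor_margin_error(truth, truth, 0.1).error_mm == 0.0

    def test_up_down_shift_symmetry(self):
        truth = blob_mask((30, 30), 10, 20, 5, 25)
        up = blob_mask((30, 30), 7, 17, 5, 25)
        down = blob_mask((30, 30), 13, 23, 5, 25)
        assert tumor_margin_error(truth, up, 0.1).error_mm == pytest.approx(
            tumor_margin_error(truth, down, 0.1).error_mm
        )

    def test_horizontal_translation_invariant(self):
        truth = blob_mask((30, 30), 10, 20, 5, 15)
        pred = blob_mask((30, 30), 12, 22, 14, 24)
        shifted = np.roll(pred, 5, axis=1)
        assert tumor_margin_error(truth, pred, 0.1).error_mm == tumor_margin_error(
            truth, shifted, 0.1
        ).error_mm

    def test_down_shift_scales_with_spacing(self):
        truth = blob_mask((30, 30), 10, 20, 5, 25)
        for k in (1, 3, 7):
            pred = blob_mask((30, 30), 10 + k, 20, 5, 25)
            assert tumor_margin_error(truth, pred, 0.25).error_mm == pytest.approx(k * 0.25)

    def test_empty_prediction_sentinel(self):
        truth = blob_mask((30, 30), 10, 20, 5, 25)
        m = tumor_margin_error(truth, np.zeros((30, 30)), 0.1)
        assert m.no_tumor_predicted and m.tm_pred is None
        assert m.error_mm == pytest.approx((29 - 10) * 0.1)

    def test_empty_ground_truth_raises(self):
        with pytest.raises(ValueError, match="ground truth"):
            tumor_margin_error(np.zeros((5, 5)), np.ones((5, 5)), 0.1)


class TestPooledAUC:
    def test_perfect_and_inverted(self):
        truth = blob_mask((8, 8), 2, 5, 2, 5)
        assert roc_auc([truth], [truth.astype(float)])[0] == pytest.approx(1.0)
        assert roc_auc([truth], [1.0 - truth.astype(float)])[0] == pytest.approx(0.0)

    def test_matches_mann_whitney_rank_oracle(self, rng):
        # 20-pixel pool; AUC equals U / (n_pos * n_neg)
        truth = (rng.random((4, 5)) < 0.5).astype(int)
        truth[0, 0], truth[0, 1] = 0, 1
        scores = rng.random((4, 5))
        auc, _, _ = roc_auc([truth], [scores])
        pos, neg = scores[truth == 1], scores[truth == 0]
        u = mannwhitneyu(pos, neg).statistic
        assert auc == pytest.approx(u / (pos.size * neg.size))

    def test_invariant_under_monotone_transform(self, rng):
        truth = random_mask(rng)
        truth[0, 0] = 0
        scores = rng.random((8, 8))
        a1, _, _ = roc_auc([truth], [scores])
        a2, _, _ = roc_auc([truth], [scores**3])
        assert a1 == pytest.approx(a2)

    def test_single_class_pool_raises(self):
        with pytest.raises(ValueError, match="single class"):
            roc_auc([np.ones((4, 4))], [np.random.rand(4, 4)])


class TestThresholdSweep:
    def test_perfect_maps_constant_curves(self):
        truth = blob_mask((16, 16), 4, 10, 4, 10)
        sweep = threshold_sweep([truth], [truth.astype(float)], [0.25, 0.5, 0.75], 0.1)
        assert np.allclose(sweep.mean_dice, 1.0)
        assert np.allclose(sweep.mean_margin_error_mm, 0.0)

    def test_manual_per_threshold_evaluation(self):
        truth = blob_mask((8, 8), 2, 6, 2, 6)
        pmap = np.zeros((8, 8))
        pmap[2:6, 2:6] = 0.6
        pmap[3:6, 3:6] = 0.9
        pmap[0, 0] = 0.3
        sweep = threshold_sweep([truth], [pmap], [0.25, 0.5, 0.75], row_spacing_mm=1.0)
        # thr 0.25: tumor + (0,0) speck; thr 0.5: exact; thr 0.75: inner 3x3
        d1 = 2 * 16 / (16 + 17)
        assert sweep.per_image_dice[:, 0] == pytest.approx([d1, 1.0, 2 * 9 / 25])
        assert sweep.per_image_margin_mm[:, 0] == pytest.approx([2.0, 0.0, 1.0])

    def test_tradeoff_phantom_separates_optima(self):
        truths, maps = tradeoff_probability_maps(n_images=6, seed=3)
        sweep = threshold_sweep(truths, maps, np.arange(0.05, 1.0, 0.05), 0.1)
        assert sweep.best_dice_threshold != sweep.best_margin_threshold

    def test_bad_threshold_lists(self):
        truth = blob_mask((8, 8), 2, 6, 2, 6)
        with pytest.raises(ValueError):
            threshold_sweep([truth], [truth.astype(float)], [])
        with pytest.raises(ValueError):
            threshold_sweep([truth], [truth.astype(float)], [0.5, 0.5])
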