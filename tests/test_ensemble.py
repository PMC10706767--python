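"""Fusion strategies and their validation-split optimization."""

import numpy as np
import pytest

from marginseg.ensemble import (
    EnsembleConfig,
    apply_classifier,
    fit_fusion_classifier,
    fuse_average,
    fuse_vote,
    optimize_fusion,
)

from conftest import blob_mask


def const_maps(values, shape=(4, 4)):
    return [np.full(shape, v) for v in values]


class TestAveraging:
    def test_idempotent_on_identical_maps(self):
        maps = const_maps([0.7, 0.7, 0.7])
        np.testing.assert_allclose(fuse_average(maps), maps[0])

    def test_unweighted_mean(self):
        np.testing.assert_allclose(fuse_average(const_maps([0.2, 0.8])), 0.5)

    def test_degenerate_weights_select_one_model(self):
        rng = np.random.default_rng(0)
        maps = [rng.random((4, 4)) for _ in range(5)]
        np.testing.assert_allclose(fuse_average(maps, [1, 0, 0, 0, 0]), maps[0])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        maps = [rng.random((4, 4)) for _ in range(4)]
        np.testing.assert_allclose(fuse_average(maps), fuse_average(maps[::-1]))

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            fuse_average(const_maps([0.2, 0.8]), [-1, 2])

    def test_output_in_unit_interval(self):
        rng = np.random.default_rng(2)
        maps = [rng.random((6, 6)) for _ in range(3)]
        fused = fuse_average(maps, [0.2, 0.3, 0.5])
        assert fused.min() >= 0 and fused.max() <= 1


class TestVoting:
    def test_union_and_intersection_limits(self):
        rng = np.random.default_rng(3)
        maps = [rng.random((5, 5)) for _ in range(4)]
        binarized = np.stack([m >= 0.5 for m in maps])
        np.testing.assert_array_equal(fuse_vote(maps, 0.5, 1), binarized.any(axis=0))
        np.testing.assert_array_equal(fuse_vote(maps, 0.5, 4), binarized.all(axis=0))

    def test_matches_exhaustive_count(self):
        rng = np.random.default_rng(4)
        maps = [rng.random((3, 3)) for _ in range(5)]
        out = fuse_vote(maps, 0.5, 3)
        for i in range(3):
            for j in range(3):
                votes = sum(m[i, j] >= 0.5 for m in maps)
                assert out[i, j] == (votes >= 3)

    def test_monotone_in_vote_count(self):
        rng = np.random.default_rng(5)
        maps = [rng.random((6, 6)) for _ in range(5)]
        prev = fuse_vote(maps, 0.5, 1)
        for count in range(2, 6):
            cur = fuse_vote(maps, 0.5, count)
            assert np.all(prev[cur > 0])  # foreground shrinks
            prev = cur

    def test_vote_count_out_of_range(self):
        with pytest.raises(ValueError):
            fuse_vote(const_maps([0.5, 0.5]), 0.5, 3)


class TestClassifier:
    def _pool(self, informative_first=True, n=12, seed=0):
        rng = np.random.default_rng(seed)
        truths, maps = [], []
        for _ in range(n):
            truth = blob_mask((8, 8), 2, 6, 2, 6)
            good = np.clip(truth + rng.normal(0, 0.05, truth.shape), 0, 1)
            noise = [np.clip(rng.random((8, 8)), 0, 1) for _ in range(4)]
            per_model = [good] + noise if informative_first else noise + [good]
            truths.append(truth)
            maps.append(per_model)
        return maps, truths

    def test_weight_concentrates_on_informative_model(self):
        maps, truths = self._pool()
        cfg = fit_fusion_classifier(maps, truths)
        coefs = np.abs(cfg.classifier_coef)
        assert np.argmax(coefs) == 0

    def test_prediction_invariant_to_swapping_duplicate_features(self):
        rng = np.random.default_rng(1)
        truth = blob_mask((8, 8), 2, 6, 2, 6)
        base = np.clip(truth + rng.normal(0, 0.1, truth.shape), 0, 1)
        other = rng.random((8, 8))
        cfg = fit_fusion_classifier([[base, base, other]] * 6, [truth] * 6)
        p1 = apply_classifier(cfg, [base, base, other])
        cfg_sw = EnsembleConfig(
            "classifier",
            classifier_coef=[cfg.classifier_coef[1], cfg.classifier_coef[0], cfg.classifier_coef[2]],
            classifier_intercept=cfg.classifier_intercept,
        )
        p2 = apply_classifier(cfg_sw, [base, base, other])
        np.testing.assert_allclose(p1, p2, atol=1e-9)

    def test_perfect_maps_reach_full_training_accuracy(self):
        truth = blob_mask((8, 8), 2, 6, 2, 6)
        maps = [[truth.astype(float)] * 3] * 5
        cfg = fit_fusion_classifier(maps, [truth] * 5)
        pred = apply_classifier(cfg, [truth.astype(float)] * 3) >= 0.5
        np.testing.assert_array_equal(pred, truth.astype(bool))

    def test_single_class_pool_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            fit_fusion_classifier([[np.zeros((4, 4))]], [np.zeros((4, 4))])


class TestOptimization:
    def test_weighted_avg_prefers_the_perfect_model(self):
        rng = np.random.default_rng(6)
        truths = [blob_mask((16, 16), 4, 12, 4, 12) for _ in range(4)]
        maps = [
            [t.astype(float)] + [rng.random((16, 16)) for _ in range(2)] for t in truths
        ]
        cfg = optimize_fusion(maps, truths, "weighted_avg", criterion="dice",
                              weight_step=0.2, postprocess=False)
        assert np.argmax(cfg.model_weights) == 0
        assert cfg.model_weights[0] >= 0.6

    def test_identical_models_fall_back_to_uniform(self):
        truths = [blob_mask((8, 8), 2, 6, 2, 6) for _ in range(3)]
        maps = [[t.astype(float)] * 4 for t in truths]
        cfg = optimize_fusion(maps, truths, "weighted_avg", criterion="dice",
                              weight_step=0.5, postprocess=False)
        np.testing.assert_allclose(cfg.model_weights, 0.25)

    def test_dice_and_margin_criteria_pick_different_thresholds(self):
        from marginseg.phantom import tradeoff_probability_maps

        truths, maps = tradeoff_probability_maps(n_images=6, seed=0)
        per_model = [[m] * 2 for m in maps]
        dice_cfg = optimize_fusion(per_model, truths, "unweighted_avg", criterion="dice",
                                   postprocess=False)
        margin_cfg = optimize_fusion(per_model, truths, "unweighted_avg", criterion="margin",
                                     postprocess=False)
        assert dice_cfg.prob_threshold != margin_cfg.prob_threshold
        assert margin_cfg.prob_threshold <= 0.35 < dice_cfg.prob_threshold

    def test_empty_validation_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            optimize_fusion([], [], "vote")


def test_config_json_roundtrip(tmp_path):
    cfg = EnsembleConfig("weighted_avg", model_weights=[0.5, 0.25, 0.25], prob_threshold=0.4)
    path = tmp_path / "cfg.json"
    cfg.to_json(path)
    loaded = EnsembleConfig.from_json(path)
    assert loaded == cfg
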