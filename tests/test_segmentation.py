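import numpy as np
import pytest

from lynsu.roi import CUBE_SHAPE, Cube
from lynsu.segmentation import (
    ConfusionCounts,
    LossConfig,
    SegModelConfig,
    _loss_and_grad,
    build_segmenter,
    categorical_focal_loss,
    dice_loss,
    dice_loss_from_counts,
    load_segmenter,
    predict_roi,
    save_segmenter,
    total_loss,
    train_segmenter,
    weighted_dice_loss,
)


def _counts(tp1, fp1, fn1, tp2, fp2, fn2):
    total = tp1 + fp1 + fn1 + tp2 + fp2 + fn2  # fabricate consistent tn
    return ConfusionCounts(
        tp=[tp1, tp2],
        fp=[fp1, fp2],
        fn=[fn1, fn2],
        tn=[total - tp1 - fp1 - fn1, total - tp2 - fp2 - fn2],
    )


class TestDiceLoss:
    def test_identity_zero(self):
        m = np.zeros((4, 4, 4))
        m[1:3, 1:3, 1:3] = 1
        assert dice_loss(m, m) == 0.0

    def test_disjoint_one(self):
        a = np.zeros(10)
        b = np.zeros(10)
        a[:3] = 1
        b[5:] = 1
        assert dice_loss(a, b) == 1.0

    def test_count_form_third(self):
        # TP=2, FP=1, FN=1 -> 1 - 4/6 = 1/3
        assert dice_loss_from_counts(2, 1, 1) == pytest.approx(1 / 3)
        gt = np.array([1, 1, 1, 0])
        pred = np.array([1, 1, 0, 1])
        assert dice_loss(gt, pred) == pytest.approx(1 / 3)

    def test_both_empty_zero(self):
        assert dice_loss(np.zeros(5), np.zeros(5)) == 0.0
        assert dice_loss_from_counts(0, 0, 0) == 0.0

    def test_count_and_soft_form_agree_on_hard_predictions(self, rng):
        gt = rng.integers(0, 2, size=200)
        pred = rng.integers(0, 2, size=200)
        tp = int((gt & pred).sum())
        fp = int((~gt.astype(bool) & pred.astype(bool)).sum())
        fn = int((gt.astype(bool) & ~pred.astype(bool)).sum())
        assert dice_loss(gt, pred) == pytest.approx(dice_loss_from_counts(tp, fp, fn))


class TestWeightedDice:
    def test_perfect_prediction_zero(self):
        assert weighted_dice_loss(_counts(10, 0, 0, 5, 0, 0)) == 0.0

    def test_equal_weights_equal_pooled(self):
        c = _counts(2, 1, 1, 2, 1, 1)
        pooled = dice_loss_from_counts(tp=4, fp=2, fn=2)
        assert weighted_dice_loss(c, weights=(0.5, 0.5)) == pytest.approx(pooled)

    def test_hand_substitution(self):
        # w=(0.4,0.6), TP1=10, TP2=2, FN1=FP1=0, FN2=FP2=2:
        # M = 5.2, denom = 2*5.2 + 0.6*2 + 0.6*2 = 12.8 -> 1 - 10.4/12.8 = 0.1875
        c = _counts(10, 0, 0, 2, 2, 2)
        assert weighted_dice_loss(c, weights=(0.4, 0.6)) == pytest.approx(0.1875)

    def test_printed_grouping_variant(self):
        # matched term once in the denominator: perfect prediction -> -1
        c = _counts(10, 0, 0, 5, 0, 0)
        assert weighted_dice_loss(c, printed_grouping=True) == pytest.approx(-1.0)

    def test_all_zero_counts(self):
        assert weighted_dice_loss(_counts(0, 0, 0, 0, 0, 0)) == 0.0

    def test_equal_weights_equals_pooled_random(self, rng):
        for _ in range(10):
            v = rng.integers(0, 50, size=6)
            c = _counts(*v)
            pooled = dice_loss_from_counts(v[0] + v[3], v[1] + v[4], v[2] + v[5])
            assert weighted_dice_loss(c, weights=(0.5, 0.5)) == pytest.approx(pooled)


class TestFocalLoss:
    def test_gamma0_alpha1_is_cross_entropy(self, rng):
        # independent oracle: mean of -log p at the true class
        labels = rng.integers(0, 2, size=(50,))
        p_fg = rng.uniform(0.05, 0.95, size=50)
        probs = np.stack([1 - p_fg, p_fg], axis=-1)
        onehot = np.stack([labels == 0, labels == 1], axis=-1).astype(float)
        ce = -np.mean([np.log(probs[i, labels[i]]) for i in range(50)])
        fl = categorical_focal_loss(onehot, probs, alpha=(1.0, 1.0), gamma=0.0)
        assert fl == pytest.approx(ce, abs=1e-9)

    def test_half_probability_is_log2(self):
        onehot = np.array([[0.0, 1.0]])
        probs = np.array([[0.5, 0.5]])
        fl = categorical_focal_loss(onehot, probs, alpha=(1.0, 1.0), gamma=0.0)
        assert fl == pytest.approx(np.log(2), abs=1e-9)

    def test_perfect_probability_goes_to_zero(self):
        onehot = np.array([[0.0, 1.0]])
        probs = np.array([[0.0, 1.0]])
        assert categorical_focal_loss(onehot, probs, alpha=(1.0, 1.0), gamma=2.0) < 1e-5

    def test_gamma2_quarter_factor_at_half(self):
        onehot = np.array([[0.0, 1.0]])
        probs = np.array([[0.5, 0.5]])
        base = categorical_focal_loss(onehot, probs, alpha=(1.0, 1.0), gamma=0.0)
        fl = categorical_focal_loss(onehot, probs, alpha=(1.0, 1.0), gamma=2.0)
        assert fl == pytest.approx(0.25 * base, abs=1e-9)

    def test_alpha_scales_linearly(self):
        onehot = np.array([[0.0, 1.0]])
        probs = np.array([[0.5, 0.5]])
        a = categorical_focal_loss(onehot, probs, alpha=(1.0, 0.75), gamma=2.0)
        b = categorical_focal_loss(onehot, probs, alpha=(1.0, 0.25), gamma=2.0)
        assert a == pytest.approx(3 * b)

    def test_decreasing_in_true_class_probability(self):
        onehot = np.array([[0.0, 1.0]])
        vals = [
            categorical_focal_loss(onehot, np.array([[1 - p, p]]))
            for p in (0.2, 0.5, 0.8, 0.99)
        ]
        assert vals == sorted(vals, reverse=True)


class TestTotalLoss:
    def _setup(self, rng):
        gt = rng.integers(0, 2, size=(6, 6, 6))
        p_fg = rng.uniform(0.01, 0.99, size=(6, 6, 6))
        probs = np.stack([1 - p_fg, p_fg], axis=-1)
        return gt, probs

    def test_lambda_zero_is_weighted_dice(self, rng):
        gt, probs = self._setup(rng)
        cfg = LossConfig(lambda_mix=0.0)
        tl = total_loss(gt, probs, cfg)
        onehot = np.stack([gt == 0, gt == 1], axis=-1).astype(float)
        tp = (onehot * probs).sum(axis=(0, 1, 2))
        fn = (onehot * (1 - probs)).sum(axis=(0, 1, 2))
        fp = ((1 - onehot) * probs).sum(axis=(0, 1, 2))
        m = 0.4 * tp[0] + 0.6 * tp[1]
        denom = 2 * m + 0.4 * (fn[0] + fp[0]) + 0.6 * (fn[1] + fp[1])
        assert tl == pytest.approx(1 - 2 * m / denom)

    def test_perfect_hard_prediction_near_zero(self):
        gt = np.zeros((4, 4, 4), dtype=int)
        gt[1:3, 1:3, 1:3] = 1
        probs = np.stack([gt == 0, gt == 1], axis=-1).astype(float)
        assert total_loss(gt, probs, LossConfig(lambda_mix=1.0)) < 1e-4

    def test_linear_in_lambda(self, rng):
        gt, probs = self._setup(rng)
        l0 = total_loss(gt, probs, LossConfig(lambda_mix=0.0))
        l1 = total_loss(gt, probs, LossConfig(lambda_mix=1.0))
        l2 = total_loss(gt, probs, LossConfig(lambda_mix=2.0))
        assert l2 - l1 == pytest.approx(l1 - l0, rel=1e-9)


class TestLossGradient:
    def test_matches_finite_differences(self, rng):
        from lynsu.segmentation import _loss_and_grad

        logits = rng.normal(size=(2, 3, 4, 4)).astype(np.float32)
        labels = rng.integers(0, 2, size=(3, 4, 4))
        g = np.stack([labels == 0, labels == 1]).astype(np.float32)
        cfg = LossConfig()
        _, grad = _loss_and_grad(g, logits, cfg)
        eps = 1e-2
        num = np.zeros_like(grad, dtype=np.float64)
        it = np.nditer(logits, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = logits[idx]
            logits[idx] = orig + eps
            lp, _ = _loss_and_grad(g, logits, cfg)
            logits[idx] = orig - eps
            lm, _ = _loss_and_grad(g, logits, cfg)
            logits[idx] = orig
            num[idx] = (lp - lm) / (2 * eps)
        np.testing.assert_allclose(grad, num, atol=5e-4)


def _toy_cubes(rng, n=4, sources=("a", "b")):
    cubes = []
    for i in range(n):
        data = rng.integers(0, 80, size=CUBE_SHAPE).astype(np.uint8)
        mask = np.zeros(CUBE_SHAPE, dtype=np.int64)
        mask[20:40, 40:80, 40:80] = 1
        data[20:40, 40:80, 40:80] += 120
        cubes.append(Cube(data, (0, 0, 0), mask=mask, source_id=sources[i % len(sources)]))
    return cubes


TINY = SegModelConfig(base_channels=2, pooling_rounds=3, epochs=1, learning_rate=1e-3, seed=0)


class TestModelContract:
    def test_output_shape_and_normalization(self, rng):
        model = build_segmenter(TINY)
        probs = model.predict(rng.integers(0, 256, CUBE_SHAPE).astype(np.uint8))
        assert probs.shape == CUBE_SHAPE + (2,)
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-5)

    def test_pooling_rounds_5_valid(self):
        build_segmenter(SegModelConfig(pooling_rounds=5, base_channels=2))

    def test_pooling_rounds_7_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            SegModelConfig(pooling_rounds=7, encoder_blocks=(1,) * 7)

    def test_encoder_blocks_must_cover_rounds(self):
        with pytest.raises(ValueError, match="encoder_blocks"):
            SegModelConfig(pooling_rounds=6, encoder_blocks=(1, 1, 1))

    def test_untrained_predict_roi_rejected(self, rng):
        from lynsu.roi import ROIGeometry, STD_SHAPE, StandardizedROI

        roi = StandardizedROI(
            data=np.zeros(STD_SHAPE, dtype=np.uint8),
            geometry=ROIGeometry((0, 168, 0, 168), (124, 168, 168), (124, 168, 168), 0, 0),
        )
        with pytest.raises(ValueError, match="trained"):
            predict_roi(build_segmenter(TINY), roi)


class TestTraining:
    def test_too_few_cubes_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            train_segmenter(_toy_cubes(rng, n=1), TINY)

    def test_checkpoint_is_best_validation(self, rng):
        cfg = SegModelConfig(base_channels=2, pooling_rounds=3, epochs=2, learning_rate=3e-3, seed=1)
        model = train_segmenter(_toy_cubes(rng, n=4), cfg)
        assert model.trained
        assert model.best_epoch is not None
        assert model.history["val_loss"][model.best_epoch] == min(model.history["val_loss"])

    def test_deterministic_given_seed(self, rng):
        cubes = _toy_cubes(rng, n=3)
        m1 = train_segmenter(cubes, TINY)
        m2 = train_segmenter(cubes, TINY)
        x = cubes[0].data
        np.testing.assert_array_equal(m1.predict(x), m2.predict(x))

    def test_save_load_round_trip(self, tmp_path, rng):
        cubes = _toy_cubes(rng, n=2)
        model = train_segmenter(cubes, TINY)
        path = str(tmp_path / "seg.npz")
        save_segmenter(model, path)
        back = load_segmenter(path)
        assert back.trained
        np.testing.assert_array_equal(model.predict(cubes[0].data), back.predict(cubes[0].data))
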