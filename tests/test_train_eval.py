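"""Metrics against exhaustive counting, the class-balanced loss, the CLR
schedule, and training-loop contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eugnet import (
    ConfusionCounts,
    GridMaskPolicy,
    ModelConfig,
    TrainConfig,
    balanced_accuracy_fg,
    balanced_loss,
    build_model,
    class_weights,
    clr,
    confusion,
    evaluate,
    mean_dsc,
    mean_iou,
    train,
)
from eugnet.synthdata import SegDataset


def counting_oracle(pred, truth, k):
    """Exhaustive per-pixel loop: the independent reference for all counts."""
    tp = [0] * k
    fp = [0] * k
    fn = [0] * k
    tn = [0] * k
    for p, t in zip(np.ravel(pred).tolist(), np.ravel(truth).tolist()):
        for c in range(k):
            if t == c and p == c:
                tp[c] += 1
            elif t != c and p == c:
                fp[c] += 1
            elif t == c and p != c:
                fn[c] += 1
            else:
                tn[c] += 1
    return tp, fp, fn, tn


@pytest.fixture
def four_by_four():
    """Truth has 4 foreground pixels; prediction covers 2 of them plus 2
    background pixels."""
    truth = np.zeros((4, 4), np.uint8)
    truth[1, 1] = truth[1, 2] = truth[2, 1] = truth[2, 2] = 1
    pred = np.zeros((4, 4), np.uint8)
    pred[1, 1] = pred[1, 2] = 1   # 2 hits
    pred[0, 0] = pred[3, 3] = 1   # 2 false alarms
    return pred, truth


class TestConfusion:
    def test_perfect_prediction_has_no_errors(self, rng):
        truth = (rng.random((8, 8)) > 0.7).astype(np.uint8)
        c = confusion(truth, truth, 2)
        for k in range(2):
            assert c.fp(k) == 0 and c.fn(k) == 0

    def test_hand_counted_example(self, four_by_four):
        pred, truth = four_by_four
        c = confusion(pred, truth, 2)
        assert (c.tp(1), c.fp(1), c.fn(1), c.tn(1)) == (2, 2, 2, 10)

    def test_complement_prediction(self):
        truth = np.array([[0, 1], [1, 0]], np.uint8)
        c = confusion(1 - truth, truth, 2)
        assert c.tp(1) == 0 and c.tn(1) == 0

    def test_background_foreground_duality(self, rng):
        pred = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        truth = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        c = confusion(pred, truth, 2)
        assert c.tp(0) == c.tn(1) and c.fp(0) == c.fn(1)
        assert c.tp(0) + c.fp(0) + c.fn(0) + c.tn(0) == 64

    def test_validation(self):
        with pytest.raises(ValueError):
            confusion(np.zeros((2, 2)), np.zeros((3, 3)), 2)
        with pytest.raises(ValueError):
            confusion(np.full((2, 2), 2), np.zeros((2, 2)), 2)


class TestMetrics:
    def test_perfect_prediction_scores_one(self, rng):
        truth = (rng.random((8, 8)) > 0.7).astype(np.uint8)
        c = confusion(truth, truth, 2)
        assert mean_iou(c) == 1.0
        assert mean_dsc(c) == 1.0
        assert balanced_accuracy_fg(c) == 1.0

    def test_hand_computed_example(self, four_by_four):
        pred, truth = four_by_four
        c = confusion(pred, truth, 2)
        assert mean_iou(c) == pytest.approx((2 / 6 + 10 / 14) / 2, abs=1e-12)
        assert mean_dsc(c) == pytest.approx((4 / 8 + 20 / 24) / 2, abs=1e-12)
        assert balanced_accuracy_fg(c) == pytest.approx((2 / 4 + 10 / 12) / 2,
                                                        abs=1e-12)

    def test_empty_union_convention(self):
        c = confusion(np.zeros((4, 4), np.uint8), np.zeros((4, 4), np.uint8), 2)
        assert mean_iou(c) == 1.0 and mean_dsc(c) == 1.0
        assert balanced_accuracy_fg(c) == 1.0

    def test_all_foreground_prediction_on_half_foreground_truth(self):
        truth = np.zeros((4, 4), np.uint8)
        truth[:2] = 1
        c = confusion(np.ones((4, 4), np.uint8), truth, 2)
        assert balanced_accuracy_fg(c) == pytest.approx(0.5)

    def test_against_counting_oracle_random_masks(self, rng):
        for _ in range(200):
            pred = rng.integers(0, 2, (8, 8)).astype(np.uint8)
            truth = rng.integers(0, 2, (8, 8)).astype(np.uint8)
            c = confusion(pred, truth, 2)
            tp, fp, fn, tn = counting_oracle(pred, truth, 2)
            for k in range(2):
                assert (c.tp(k), c.fp(k), c.fn(k), c.tn(k)) == \
                    (tp[k], fp[k], fn[k], tn[k])
            ious = [1.0 if tp[k] + fp[k] + fn[k] == 0
                    else tp[k] / (tp[k] + fp[k] + fn[k]) for k in range(2)]
            assert mean_iou(c) == pytest.approx(np.mean(ious), abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_dsc_iou_identity_and_ordering(self, seed):
        """DSC_k = 2 IoU_k / (1 + IoU_k) per class, hence
        mean DSC >= mean IoU for every confusion matrix."""
        r = np.random.default_rng(seed)
        pred = r.integers(0, 2, (8, 8)).astype(np.uint8)
        truth = r.integers(0, 2, (8, 8)).astype(np.uint8)
        c = confusion(pred, truth, 2)
        for k in range(2):
            iou = c.tp(k) / u if (u := c.tp(k) + c.fp(k) + c.fn(k)) else 1.0
            dsc = 2 * c.tp(k) / du if (du := 2 * c.tp(k) + c.fp(k) + c.fn(k)) else 1.0
            assert dsc == pytest.approx(2 * iou / (1 + iou), abs=1e-12)
        assert mean_dsc(c) >= mean_iou(c) - 1e-12

    def test_balanced_accuracy_requires_two_classes(self):
        c = ConfusionCounts(np.eye(3, dtype=np.int64))
        with pytest.raises(ValueError):
            balanced_accuracy_fg(c)


class TestClassWeights:
    def test_equal_frequencies_give_unit_weights(self):
        np.testing.assert_allclose(class_weights([50, 50]), [1.0, 1.0])

    def test_inverse_frequency_normalization(self):
        # freq (0.9, 0.1) -> w proportional to (1/0.9, 1/0.1), sum = K = 2
        w = class_weights([90, 10])
        np.testing.assert_allclose(w, [0.2, 1.8], atol=1e-12)
        assert w.sum() == pytest.approx(2.0)

    def test_mode_none(self):
        np.testing.assert_array_equal(class_weights([90, 10], mode="none"),
                                      [1.0, 1.0])

    def test_absent_class_gets_capped_maximum(self):
        w = class_weights([100, 0])
        assert w[1] > w[0]
        assert np.isfinite(w).all()

    def test_all_zero_histogram_rejected(self):
        with pytest.raises(ValueError):
            class_weights([0, 0])


class TestBalancedLoss:
    def test_uniform_scores_equal_weights_is_ln2(self):
        scores = np.zeros((2, 4, 4), np.float32)
        truth = np.random.default_rng(0).integers(0, 2, (4, 4))
        loss = balanced_loss(scores, truth, np.ones(2))
        assert loss == pytest.approx(np.log(2), rel=1e-6)

    def test_saturated_scores_drive_loss_to_zero(self):
        truth = np.random.default_rng(1).integers(0, 2, (4, 4))
        scores = np.full((2, 4, 4), -50.0, np.float32)
        np.put_along_axis(scores, truth[None], 50.0, axis=0)
        assert balanced_loss(scores, truth, np.ones(2)) < 1e-6

    def test_doubling_foreground_weight_doubles_its_contribution(self, rng):
        scores = rng.standard_normal((2, 6, 6)).astype(np.float32)
        truth = np.ones((6, 6), np.int64)  # all foreground
        base = balanced_loss(scores, truth, np.array([1.0, 1.0]))
        doubled = balanced_loss(scores, truth, np.array([1.0, 2.0]))
        assert doubled == pytest.approx(2 * base, rel=1e-6)

    def test_equal_weights_match_unweighted_cross_entropy(self, rng):
        scores = rng.standard_normal((2, 5, 5)).astype(np.float32)
        truth = rng.integers(0, 2, (5, 5))
        loss = balanced_loss(scores, truth, np.ones(2))
        # independent cross-entropy: stable softmax in float64
        z = scores.astype(np.float64)
        z -= z.max(axis=0, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=0, keepdims=True))
        ref = -logp[truth, np.arange(5)[:, None], np.arange(5)[None, :]].mean()
        assert loss == pytest.approx(ref, rel=1e-5)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            balanced_loss(np.zeros((2, 4, 4)), np.zeros((3, 3)), np.ones(2))


class TestClr:
    CFG = TrainConfig(base_lr=1e-4, max_lr=1e-2, clr_cycle_steps=100)

    def test_cycle_start_is_base_lr(self):
        assert clr(0, self.CFG) == 1e-4

    def test_half_cycle_is_max_lr(self):
        assert clr(50, self.CFG) == 1e-2

    def test_quarter_cycle_is_midpoint(self):
        assert clr(25, self.CFG) == pytest.approx((1e-4 + 1e-2) / 2)

    def test_never_leaves_bounds(self):
        lrs = np.array([clr(s, self.CFG) for s in range(1000)])
        assert lrs.min() == 1e-4 and lrs.max() == 1e-2

    def test_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(base_lr=1e-2, max_lr=1e-4)
        with pytest.raises(ValueError):
            clr(-1, self.CFG)


class _OracleModel:
    """Duck-typed stand-in that predicts a fixed transform of the truth."""

    def __init__(self, masks, transform):
        self.config = ModelConfig(depth=2, base_channels=1)
        self._masks = masks
        self._transform = transform

    def predict(self, images, batch_size=8):
        return self._transform(self._masks)


class TestEvaluate:
    def test_ground_truth_model_scores_one(self, tiny_dataset):
        model = _OracleModel(tiny_dataset.masks, lambda m: m.copy())
        rep = evaluate(model, tiny_dataset)
        assert rep.mean_iou == 1.0 and rep.mean_dsc == 1.0
        assert rep.balanced_accuracy_fg == 1.0
        assert rep.macro_mean_dsc == 1.0

    def test_all_background_model(self, tiny_dataset):
        model = _OracleModel(tiny_dataset.masks, lambda m: np.zeros_like(m))
        rep = evaluate(model, tiny_dataset)
        c = rep.counts
        assert c.tp(1) == 0
        dsc0 = 2 * c.tp(0) / (2 * c.tp(0) + c.fp(0) + c.fn(0))
        assert rep.mean_dsc == pytest.approx(dsc0 / 2)
        assert rep.mean_dsc < 1.0

    def test_report_satisfies_dsc_iou_identity(self, tiny_dataset, rng):
        noisy = (tiny_dataset.masks ^ (rng.random(tiny_dataset.masks.shape) > 0.9))
        model = _OracleModel(noisy.astype(np.uint8), lambda m: m)
        rep = evaluate(model, tiny_dataset)
        for iou, dsc in zip(rep.iou_per_class, rep.dsc_per_class):
            assert dsc == pytest.approx(2 * iou / (1 + iou), abs=1e-12)

    def test_empty_dataset_rejected(self, tiny_dataset):
        model = _OracleModel(tiny_dataset.masks, lambda m: m)
        empty = SegDataset(tiny_dataset.images[:0], tiny_dataset.masks[:0])
        with pytest.raises(ValueError):
            evaluate(model, empty)


class TestTrain:
    def _config(self, **kw):
        defaults = dict(epochs=1, batch_size=2, seed=0, val_fraction=0.25,
                        gridmask=GridMaskPolicy(d_range=(4, 8), apply_prob=0.0,
                                                rotate=False))
        defaults.update(kw)
        return TrainConfig(**defaults)

    def test_smoke_one_epoch(self, tiny_dataset):
        model = build_model(ModelConfig(depth=2, base_channels=2), seed=0)
        ds = tiny_dataset.subset(np.arange(4))
        history = train(model, ds, self._config())
        assert len(history) == 1
        assert np.isfinite(history[0]["loss"])
        assert set(history[0]) == {"epoch", "loss", "accuracy", "mean_dsc"}

    def test_same_seed_identical_history(self, tiny_dataset):
        cfg = self._config(epochs=2,
                           gridmask=GridMaskPolicy(d_range=(4, 8), apply_prob=0.5))
        runs = []
        for _ in range(2):
            model = build_model(ModelConfig(depth=2, base_channels=2), seed=0)
            runs.append(train(model, tiny_dataset, cfg))
        assert runs[0] == runs[1]

    def test_empty_dataset_rejected(self, tiny_dataset):
        model = build_model(ModelConfig(depth=2, base_channels=2), seed=0)
        empty = SegDataset(tiny_dataset.images[:0], tiny_dataset.masks[:0])
        with pytest.raises(ValueError):
            train(model, empty, self._config())
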