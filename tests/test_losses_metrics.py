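"""Soft-Jaccard losses, cross-entropy, and the confusion-count metric suite."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from btformer.autodiff import Tensor
import btformer.autodiff as ad
from btformer.losses import (cross_entropy, one_hot, segmentation_loss, sja_loss,
                             soft_jaccard, wsja_loss, WSJA_OPTIMUM)
from btformer.metrics import (confusion_counts, evaluate_masks, format_metrics_table,
                              metrics_from_counts)

EPS = 1e-3


class TestSoftJaccard:
    def test_perfect_prediction_scores_one(self, rng):
        mask = rng.integers(0, 5, (6, 6))
        mask[:5, 0] = np.arange(5)  # ensure all classes present
        y = one_hot(mask)
        np.testing.assert_allclose(soft_jaccard(y, Tensor(y.copy())).data, 1.0, atol=1e-12)

    def test_empty_class_scores_one(self):
        mask = np.zeros((4, 4), dtype=int)  # classes 1..4 absent
        y = one_hot(mask)
        sja = soft_jaccard(y, Tensor(y.copy())).data
        np.testing.assert_allclose(sja, 1.0)  # absent classes give eps/eps

    def test_half_overlap_matches_hand_evaluation(self):
        # 4x4 toy: true class-1 region is the left half (8 px); prediction
        # puts probability 1 on class 1 over the top half (8 px, 4 px overlap)
        true = np.zeros((4, 4), dtype=int)
        true[:, :2] = 1
        pred = np.zeros((5, 4, 4))
        pred[1, :2, :] = 1.0
        pred[0, 2:, :] = 1.0
        sja = soft_jaccard(one_hot(true), Tensor(pred), eps=EPS).data
        # class 1: inter=4, union=8+8-4=12 -> (4+eps)/(12+eps)
        assert sja[1] == pytest.approx((4 + EPS) / (12 + EPS), rel=1e-12)
        # class 0: inter=4 (bottom-right quadrant), union=8+8-4=12
        assert sja[0] == pytest.approx((4 + EPS) / (12 + EPS), rel=1e-12)

    def test_invalid_eps_raises(self):
        y = one_hot(np.zeros((2, 2), dtype=int))
        with pytest.raises(ValueError):
            soft_jaccard(y, Tensor(y.copy()), eps=0.0)

    def test_monotone_in_true_class_mass(self, rng):
        true = np.zeros((4, 4), dtype=int)
        true[1:3, 1:3] = 1
        y = one_hot(true)
        pred = np.full((5, 4, 4), 0.2)
        base = soft_jaccard(y, Tensor(pred.copy())).data[1]
        pred2 = pred.copy()
        pred2[1, 1, 1] += 0.5  # more mass inside the true region
        pred2[0, 1, 1] -= 0.5
        higher = soft_jaccard(y, Tensor(pred2)).data[1]
        assert higher > base


class TestWSJALoss:
    def test_perfect_point_value(self):
        loss = wsja_loss(Tensor(np.ones(5)))
        assert float(loss.data) == pytest.approx(-6.8, abs=1e-12)
        assert float(loss.data) == pytest.approx(WSJA_OPTIMUM)

    def test_uniform_half_value(self):
        loss = wsja_loss(Tensor(np.full(5, 0.5)))
        assert float(loss.data) == pytest.approx(-3.4, abs=1e-12)

    def test_single_weight_variant_value(self):
        loss = sja_loss(Tensor(np.ones(5)))
        assert float(loss.data) == pytest.approx(-6.0, abs=1e-12)

    def test_perfect_point_is_infimum(self, rng):
        for _ in range(200):
            v = rng.uniform(0, 1, 5)
            assert float(wsja_loss(Tensor(v)).data) >= -6.8 - 1e-12
        # boundary vectors
        for v in (np.zeros(5), np.ones(5), np.array([1, 1, 1, 1, 0.999])):
            assert float(wsja_loss(Tensor(v)).data) >= -6.8 - 1e-12

    def test_gradient_weights_the_worst_classes_most(self):
        sja = Tensor(np.array([0.9, 0.3, 0.7, 0.5, 0.8]), requires_grad=True)
        wsja_loss(sja).backward()
        g = -sja.grad  # d(-loss)/dSJA
        np.testing.assert_allclose(g[1], 1.0 + 1.0)   # smallest: 1 + w1
        np.testing.assert_allclose(g[3], 1.0 + 0.8)   # second:   1 + w2
        np.testing.assert_allclose(g[[0, 2, 4]], 1.0)

    def test_continuity_at_ties(self):
        base = np.array([0.4, 0.4, 0.7, 0.8, 0.9])
        l0 = float(wsja_loss(Tensor(base)).data)
        for delta in (1e-9, -1e-9):
            v = base.copy()
            v[0] += delta
            assert abs(float(wsja_loss(Tensor(v)).data) - l0) < 1e-6

    def test_too_few_classes_raises(self):
        with pytest.raises(ValueError):
            wsja_loss(Tensor(np.array([0.5])))

    def test_training_loss_bounded_below_by_optimum(self, rng):
        logits = Tensor(rng.standard_normal((2, 5, 8, 8)))
        mask = rng.integers(0, 5, (2, 8, 8))
        loss = segmentation_loss(logits, mask, kind="wsja")
        assert float(loss.data) >= -6.8


class TestCrossEntropy:
    def test_matches_direct_evaluation(self, rng):
        logits = rng.standard_normal((1, 5, 3, 3))
        mask = rng.integers(0, 5, (1, 3, 3))
        got = float(cross_entropy(Tensor(logits.copy()), mask).data)
        p = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        expect = -np.mean([np.log(p[0, mask[0, i, j], i, j])
                           for i in range(3) for j in range(3)])
        assert got == pytest.approx(expect, rel=1e-10)


class TestMetrics:
    def test_hand_computed_counts(self):
        counts = {"TP": [8], "FP": [2], "TN": [88], "FN": [2]}
        m = metrics_from_counts(counts, reduction="macro", percent=False)
        assert m["precision"] == pytest.approx(0.8)
        assert m["recall"] == pytest.approx(0.8)
        assert m["dice"] == pytest.approx(0.8)
        assert m["jaccard"] == pytest.approx(2 / 3)
        assert m["accuracy"] == pytest.approx(0.96)

    def test_perfect_prediction_scores_100(self, rng):
        mask = rng.integers(0, 5, (10, 10))
        m = evaluate_masks([mask], [mask])
        for name, v in m.items():
            assert v == pytest.approx(100.0), name

    def test_dice_jaccard_identity(self, rng):
        for _ in range(50):
            tp, fp, fn = rng.integers(1, 50, 3)
            counts = {"TP": [tp], "FP": [fp], "TN": [100], "FN": [fn]}
            m = metrics_from_counts(counts, percent=False)
            assert m["dice"] == pytest.approx(2 * m["jaccard"] / (1 + m["jaccard"]))

    def test_precision_equals_recall_when_fp_equals_fn(self, rng):
        counts = {"TP": [17], "FP": [5], "TN": [60], "FN": [5]}
        m = metrics_from_counts(counts, percent=False)
        assert m["precision"] == pytest.approx(m["recall"])

    def test_confusion_counts_sum_to_pixel_count(self, rng):
        pred = rng.integers(0, 5, (12, 12))
        true = rng.integers(0, 5, (12, 12))
        c = confusion_counts(pred, true)
        total = c["TP"] + c["FP"] + c["TN"] + c["FN"]
        np.testing.assert_array_equal(total, 144)

    def test_undefined_class_excluded_and_logged(self, caplog):
        # class 1 absent from both prediction and truth -> precision undefined
        pred = np.zeros((4, 4), dtype=int)
        true = np.zeros((4, 4), dtype=int)
        import logging
        with caplog.at_level(logging.INFO, logger="btformer.metrics"):
            m = evaluate_masks([pred], [true], num_classes=2)
        assert np.isfinite(m["precision"])
        assert any("undefined" in r.message for r in caplog.records)

    def test_constant_background_predictor_matches_counting_oracle(self, rng):
        true = rng.integers(0, 5, (8, 8))
        pred = np.zeros((8, 8), dtype=int)
        m = evaluate_masks([pred], [true], percent=False)
        # independent oracle: accuracy per class counted directly
        accs = []
        for k in range(5):
            agree = ((pred == k) == (true == k)).mean()
            accs.append(agree)
        assert m["accuracy"] == pytest.approx(np.mean(accs))

    def test_table_formatting(self):
        rows = [{"method": "D=4", "dice": 91.234, "jaccard": 85.0,
                 "dice_sd": 0.05, "jaccard_sd": 0.1}]
        table = format_metrics_table(rows)
        assert "91.23±0.05" in table and "85.00±0.10" in table

    @settings(derandomize=True, max_examples=50)
    @given(tp=st.integers(0, 1000), fp=st.integers(0, 1000), fn=st.integers(0, 1000))
    def test_dice_jaccard_identity_holds_for_any_counts(self, tp, fp, fn):
        if tp + fp + fn == 0:
            return
        m = metrics_from_counts({"TP": [tp], "FP": [fp], "TN": [9], "FN": [fn]},
                                percent=False)
        assert m["dice"] == pytest.approx(2 * m["jaccard"] / (1 + m["jaccard"]))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.0, 1.0), min_size=5, max_size=5))
    def test_wsja_never_beats_perfect_prediction(self, sja):
        assert float(wsja_loss(Tensor(np.array(sja))).data) >= -6.8 - 1e-9

    def test_foreground_reduction_ignores_background(self):
        counts = {"TP": [0, 10], "FP": [50, 0], "TN": [50, 90], "FN": [0, 0]}
        fg = metrics_from_counts(counts, reduction="foreground", percent=False)
        assert fg["dice"] == pytest.approx(1.0)
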