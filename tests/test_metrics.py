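"""Metric suite against brute-force oracles and algebraic identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ultraseg as us


def _bce_oracle(y, p, eps=1e-7):
    total = 0.0
    for yi, pi in zip(y.ravel(), p.ravel()):
        pi = min(max(pi, eps), 1 - eps)
        total += yi * math.log(pi) + (1 - yi) * math.log(1 - pi)
    return -total / y.size


def _auc_oracle(probs, truth):
    pos = probs[truth == 1]
    neg = probs[truth == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


class TestBceLoss:
    def test_matching_hard_predictions_are_near_zero(self):
        y = np.array([[1, 0], [0, 1]])
        assert us.bce_loss(y, y.astype(float)) < 1e-5

    def test_uniform_half_prediction_is_ln2(self, rng):
        y = (rng.random((10, 10)) > 0.5).astype(int)
        assert us.bce_loss(y, np.full((10, 10), 0.5)) == pytest.approx(
            math.log(2), abs=1e-12)

    def test_three_pixel_oracle_value(self):
        got = us.bce_loss(np.array([1, 0, 1]), np.array([0.9, 0.2, 0.8]))
        assert got == pytest.approx(0.18388, abs=5e-6)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            us.bce_loss(np.empty((0,)), np.empty((0,)))

    @settings(deadline=None, max_examples=200)
    @given(seed=st.integers(0, 10 ** 6))
    def test_matches_scalar_summation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 30))
        y = (rng.random(n) > 0.5).astype(int)
        p = rng.random(n)
        assert us.bce_loss(y, p) == pytest.approx(_bce_oracle(y, p),
                                                  rel=1e-10)

    def test_constant_predictor_minimised_at_foreground_fraction(self):
        y = np.array([1] * 3 + [0] * 7)
        losses = {c: us.bce_loss(y, np.full(10, c))
                  for c in np.linspace(0.05, 0.95, 19)}
        best = min(losses, key=losses.get)
        assert best == pytest.approx(0.3, abs=0.05)


class TestConfusion:
    def test_perfect_prediction(self):
        t = np.zeros((10, 10), int)
        t[:2, :5] = 1
        c = us.confusion(t, t)
        assert (c.tp, c.tn, c.fp, c.fn) == (10, 90, 0, 0)

    def test_all_negative_prediction(self):
        t = np.array([1, 1, 1, 0, 0, 0, 0, 0])
        c = us.confusion(np.zeros(8, int), t)
        assert (c.tp, c.fn, c.tn, c.fp) == (0, 3, 5, 0)

    @settings(deadline=None, max_examples=200)
    @given(seed=st.integers(0, 10 ** 6))
    def test_matches_per_pixel_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        pred = (rng.random(16) > 0.5).astype(int)
        truth = (rng.random(16) > 0.5).astype(int)
        c = us.confusion(pred, truth)
        tally = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
        for p, t in zip(pred, truth):
            tally[{(1, 1): "tp", (0, 0): "tn",
                   (1, 0): "fp", (0, 1): "fn"}[(p, t)]] += 1
        assert (c.tp, c.tn, c.fp, c.fn) == (tally["tp"], tally["tn"],
                                            tally["fp"], tally["fn"])
        assert c.total == 16

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            us.confusion(np.zeros(4, int), np.zeros(5, int))

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="0/1"):
            us.confusion(np.array([0, 2]), np.array([0, 1]))


class TestBasicMetrics:
    def test_hand_arithmetic_oracle(self):
        r = us.basic_metrics(us.ConfusionCounts(tp=8, tn=85, fp=2, fn=5))
        assert r.pre == pytest.approx(0.8)
        assert r.sen == pytest.approx(8 / 13)
        assert r.f1 == pytest.approx(16 / 23)
        assert r.acc == pytest.approx(0.93)
        assert r.spe == pytest.approx(85 / 87)

    def test_perfect_prediction_scores_one_everywhere(self):
        r = us.basic_metrics(us.ConfusionCounts(10, 90, 0, 0))
        assert all(v == 1.0 for v in (r.acc, r.sen, r.spe, r.pre, r.f1))

    def test_all_negative_with_positives_present(self):
        r = us.basic_metrics(us.ConfusionCounts(0, 5, 0, 3))
        assert r.sen == 0.0 and r.pre == 0.0

    def test_degenerate_no_positives_anywhere(self):
        r = us.basic_metrics(us.ConfusionCounts(0, 8, 0, 0))
        assert r.sen == 1.0 and r.pre == 1.0 and r.f1 == 1.0

    def test_sen_spe_exchange_under_label_complement(self, rng):
        pred = (rng.random(50) > 0.6).astype(int)
        truth = (rng.random(50) > 0.4).astype(int)
        r = us.basic_metrics(us.confusion(pred, truth))
        rc = us.basic_metrics(us.confusion(1 - pred, 1 - truth))
        assert r.sen == pytest.approx(rc.spe)
        assert r.spe == pytest.approx(rc.sen)


class TestDice:
    def test_identical_nonempty_masks(self, rng):
        m = (rng.random((8, 8)) > 0.5).astype(int)
        assert us.dice(m, m) == 1.0

    def test_disjoint_nonempty_masks(self):
        a = np.array([1, 1, 0, 0])
        b = np.array([0, 0, 1, 1])
        assert us.dice(a, b) == 0.0

    def test_both_empty_masks(self):
        z = np.zeros(9, int)
        assert us.dice(z, z) == 1.0

    @settings(deadline=None, max_examples=200)
    @given(seed=st.integers(0, 10 ** 6))
    def test_equals_f1_from_confusion(self, seed):
        rng = np.random.default_rng(seed)
        pred = (rng.random(25) > rng.random()).astype(int)
        truth = (rng.random(25) > rng.random()).astype(int)
        f1 = us.basic_metrics(us.confusion(pred, truth)).f1
        assert abs(us.dice(pred, truth) - f1) < 1e-12


class TestRocAuc:
    def test_perfect_separation(self):
        truth = np.array([0, 0, 0, 1, 1])
        probs = np.array([0.1, 0.2, 0.3, 0.8, 0.9])
        assert us.roc_auc(probs, truth) == 1.0

    def test_constant_scores_give_half(self):
        truth = np.array([0, 1, 0, 1])
        assert us.roc_auc(np.full(4, 0.7), truth) == 0.5

    def test_six_pixel_pairwise_oracle(self):
        rng = np.random.default_rng(2)
        probs = rng.random(6)
        truth = np.array([1, 0, 0, 1, 0, 1])
        assert us.roc_auc(probs, truth) == pytest.approx(
            _auc_oracle(probs, truth), abs=1e-12)

    @settings(deadline=None, max_examples=200)
    @given(seed=st.integers(0, 10 ** 6))
    def test_matches_pairwise_enumeration_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 20))
        probs = np.round(rng.random(n), 1)  # coarse grid forces ties
        truth = np.zeros(n, int)
        truth[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
        if truth.all():
            truth[0] = 0
        assert us.roc_auc(probs, truth) == pytest.approx(
            _auc_oracle(probs, truth), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        probs = rng.random(40)
        truth = (rng.random(40) > 0.5).astype(int)
        truth[0], truth[1] = 0, 1
        a1 = us.roc_auc(probs, truth)
        a2 = us.roc_auc(1 / (1 + np.exp(-7 * probs)), truth)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_truth_rejected(self, rng):
        with pytest.raises(ValueError, match="both classes"):
            us.roc_auc(rng.random(5), np.ones(5, int))


class TestAggregateFolds:
    def test_identical_reports_have_zero_std(self):
        r = us.basic_metrics(us.ConfusionCounts(5, 90, 3, 2))
        agg = us.aggregate_folds([r, r, r])
        assert agg.n_folds == 3
        assert agg.dice == pytest.approx(r.dice)
        assert agg.std["dice"] == 0.0

    def test_two_fold_mean(self):
        r1 = us.MetricReport(dice=0.90)
        r2 = us.MetricReport(dice=0.94)
        agg = us.aggregate_folds([r1, r2])
        assert agg.dice == pytest.approx(0.92)

    def test_matches_numpy_mean_std_recomputation(self, rng):
        reports = [us.basic_metrics(us.confusion(
            (rng.random(40) > 0.5).astype(int),
            (rng.random(40) > 0.5).astype(int))) for _ in range(5)]
        agg = us.aggregate_folds(reports)
        for name in ("acc", "sen", "spe", "pre", "f1", "dice"):
            vals = [getattr(r, name) for r in reports]
            assert getattr(agg, name) == pytest.approx(np.mean(vals))
            assert agg.std[name] == pytest.approx(np.std(vals, ddof=1))

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            us.aggregate_folds([])


class TestReportIO:
    def test_json_and_csv_outputs(self, tmp_path):
        r1 = us.basic_metrics(us.ConfusionCounts(5, 90, 3, 2))
        r2 = us.basic_metrics(us.ConfusionCounts(7, 88, 2, 3))
        agg = us.aggregate_folds([r1, r2])
        us.write_report(agg, tmp_path / "r.json")
        us.write_report(agg, tmp_path / "r.csv")
        import json
        payload = json.loads((tmp_path / "r.json").read_text())
        assert payload["n_folds"] == 2
        lines = (tmp_path / "r.csv").read_text().strip().splitlines()
        assert lines[0].startswith("fold,")
        assert lines[-2].startswith("mean,") and lines[-1].startswith("std,")
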