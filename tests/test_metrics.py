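"""Metric formulas on hand-counted tables, identities, and loss properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ducknet import metrics as M

counts_strategy = st.builds(
    M.ConfusionCounts,
    tp=st.integers(0, 10_000), fp=st.integers(0, 10_000),
    fn=st.integers(0, 10_000), tn=st.integers(0, 10_000),
)


class TestConfusion:
    def test_hand_counted_2x2(self):
        pred = np.array([[1, 0], [1, 1]])
        truth = np.array([[1, 1], [0, 1]])
        c = M.confusion(pred, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 1, 1, 0)

    def test_equal_masks_no_errors(self, checker_mask):
        c = M.confusion(checker_mask, checker_mask)
        assert c.fp == 0 and c.fn == 0

    def test_all_background(self):
        z = np.zeros((5, 4), np.uint8)
        c = M.confusion(z, z)
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 0, 20)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            M.confusion(np.zeros((2, 2)), np.zeros((3, 2)))

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            M.confusion(np.array([[0.5, 1]]), np.array([[1, 1]]))


class TestFormulas:
    def test_hand_substitution(self):
        # substitute TP=2, FP=1, FN=1, TN=0 into each formula by hand
        c = M.ConfusionCounts(tp=2, fp=1, fn=1, tn=0)
        assert M.dice(c) == pytest.approx(4 / 6)
        assert M.jaccard(c) == pytest.approx(0.5)
        assert M.precision(c) == pytest.approx(2 / 3)
        assert M.recall(c) == pytest.approx(2 / 3)
        assert M.accuracy(c) == pytest.approx(0.5)

    def test_perfect_prediction(self):
        c = M.ConfusionCounts(tp=10, fp=0, fn=0, tn=5)
        for f in (M.dice, M.jaccard, M.precision, M.recall, M.accuracy):
            assert f(c) == 1.0

    def test_total_miss(self):
        c = M.ConfusionCounts(tp=0, fp=0, fn=7, tn=3)
        assert M.dice(c) == 0.0
        assert M.recall(c) == 0.0

    def test_both_empty_convention(self):
        c = M.ConfusionCounts(tp=0, fp=0, fn=0, tn=9)
        assert M.dice(c) == M.jaccard(c) == M.precision(c) == M.recall(c) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            M.ConfusionCounts(tp=-1, fp=0, fn=0, tn=0)

    @settings(max_examples=500)
    @given(counts_strategy)
    def test_dice_jaccard_identity(self, c):
        j = M.jaccard(c)
        assert M.dice(c) == pytest.approx(2 * j / (1 + j), abs=1e-12)

    @settings(max_examples=200)
    @given(counts_strategy)
    def test_metrics_in_unit_interval(self, c):
        if c.total == 0:
            return
        for f in (M.dice, M.jaccard, M.precision, M.recall, M.accuracy):
            assert 0.0 <= f(c) <= 1.0

    def test_permutation_invariance(self, rng):
        pred = (rng.random((12, 12)) > 0.6).astype(np.uint8)
        truth = (rng.random((12, 12)) > 0.5).astype(np.uint8)
        perm = rng.permutation(144)
        pred_p = pred.ravel()[perm].reshape(12, 12)
        truth_p = truth.ravel()[perm].reshape(12, 12)
        assert M.all_metrics(M.confusion(pred, truth)) == \
            M.all_metrics(M.confusion(pred_p, truth_p))


class TestDiceLoss:
    def test_perfect_crisp_prediction(self, checker_mask):
        assert M.dice_loss(checker_mask.astype(float), checker_mask) == pytest.approx(0.0, abs=1e-6)

    def test_inverted_prediction(self, checker_mask):
        inv = 1.0 - checker_mask
        assert M.dice_loss(inv, checker_mask) == pytest.approx(1.0, abs=1e-6)

    def test_hand_computed_2x2_soft_case(self):
        # prob all 0.5, truth = [[1,1],[0,0]]:
        # soft dice = 2*(0.5*2) / (0.5*4 + 2) = 2/4 = 0.5 -> loss 0.5
        prob = np.full((2, 2), 0.5)
        truth = np.array([[1, 1], [0, 0]])
        assert M.dice_loss(prob, truth) == pytest.approx(0.5, abs=1e-6)

    def test_complements_hard_dice_for_crisp_predictions(self, rng):
        truth = (rng.random((9, 9)) > 0.5).astype(np.uint8)
        pred = (rng.random((9, 9)) > 0.5).astype(np.uint8)
        loss = M.dice_loss(pred.astype(float), truth)
        hard = M.dice(M.confusion(pred, truth))
        assert loss + hard == pytest.approx(1.0, abs=1e-4)

    def test_monotone_toward_truth(self, rng):
        truth = (rng.random((8, 8)) > 0.5).astype(float)
        start = rng.random((8, 8))
        losses = []
        for alpha in np.linspace(0, 1, 11):
            prob = (1 - alpha) * start + alpha * truth
            losses.append(M.dice_loss(prob, truth))
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            M.dice_loss(np.zeros((2, 2)), np.zeros((2, 3)))


class TestEvaluateSet:
    def test_perfect_single(self, checker_mask):
        rep = M.evaluate_set([checker_mask.astype(float)], [checker_mask], 0.5)
        assert all(v == 1.0 for v in rep.means.values())

    def test_mean_of_two(self):
        truth = np.array([[1, 1], [1, 1]], np.uint8)
        perfect = truth.astype(float)
        half = np.array([[1.0, 1.0], [0.0, 0.0]])
        # dice of half vs truth = 2*2/(2+4) = 2/3; mean = (1 + 2/3)/2
        rep = M.evaluate_set([perfect, half], [truth, truth], 0.5)
        assert rep.means["dice"] == pytest.approx((1 + 2 / 3) / 2)

    def test_means_match_naive_reimplementation(self, rng):
        preds = [rng.random((6, 6)) for _ in range(5)]
        truths = [(rng.random((6, 6)) > 0.5).astype(np.uint8) for _ in range(5)]
        rep = M.evaluate_set(preds, truths, 0.4)
        # naive second path: recompute every metric from raw definitions
        naive = {m: [] for m in M.METRIC_NAMES}
        for p, t in zip(preds, truths):
            hard = (p > 0.4).astype(int)
            tp = int(((hard == 1) & (t == 1)).sum())
            fp = int(((hard == 1) & (t == 0)).sum())
            fn = int(((hard == 0) & (t == 1)).sum())
            tn = int(((hard == 0) & (t == 0)).sum())
            naive["dice"].append(2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 1.0)
            naive["jaccard"].append(tp / (tp + fp + fn) if tp + fp + fn else 1.0)
            naive["precision"].append(tp / (tp + fp) if tp + fp else (1.0 if fn == 0 else 0.0))
            naive["recall"].append(tp / (tp + fn) if tp + fn else (1.0 if fp == 0 else 0.0))
            naive["accuracy"].append((tp + tn) / 36)
        for m in M.METRIC_NAMES:
            assert rep.means[m] == pytest.approx(float(np.mean(naive[m])))

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            M.evaluate_set([], [], 0.5)

    def test_csv_roundtrip(self, tmp_path, checker_mask):
        rep = M.evaluate_set([checker_mask.astype(float)], [checker_mask], 0.5,
                             image_ids=["img0"])
        out = tmp_path / "report.csv"
        rep.to_csv(out)
        lines = out.read_text().strip().splitlines()
        assert lines[0].startswith("image_id,dice,jaccard")
        assert lines[1].startswith("img0,1.000000")
        assert lines[-1].startswith("mean,")

    def test_pooled_mode(self, rng):
        preds = [(rng.random((5, 5)) > 0.5).astype(np.uint8) for _ in range(3)]
        truths = [(rng.random((5, 5)) > 0.5).astype(np.uint8) for _ in range(3)]
        rep = M.evaluate_set(preds, truths, 0.5, pooled=True)
        tp = sum(((p == 1) & (t == 1)).sum() for p, t in zip(preds, truths))
        fp = sum(((p == 1) & (t == 0)).sum() for p, t in zip(preds, truths))
        fn = sum(((p == 0) & (t == 1)).sum() for p, t in zip(preds, truths))
        assert rep.means["dice"] == pytest.approx(2 * tp / (2 * tp + fp + fn))
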