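"""Tests for the training recipe, metrics and model-comparison statistics."""

import numpy as np
import pytest
from scipy import stats

from nactformer.model import DualInputTransformer
from nactformer.train import (
    TrainConfig,
    auc_score,
    compute_metrics,
    confidence_interval,
    delong_test,
    make_folds,
    mcnemar_test,
    paired_t_test,
    predict_scores,
    run_ablation,
    select_checkpoint,
    train_model,
)

from conftest import make_micro_pairs


def brute_force_auc(scores, labels):
    """O(n^2) pair counting with ties counted one half."""
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for x in pos:
        for y in neg:
            if x > y:
                wins += 1.0
            elif x == y:
                wins += 0.5
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_equals_brute_force_pair_counting(self):
        rng = np.random.default_rng(42)
        for n in (4, 10, 30):
            for _ in range(5):
                labels = rng.integers(0, 2, size=n)
                if len(np.unique(labels)) < 2:
                    continue
                # quantized scores force ties
                scores = np.round(rng.random(n), 1)
                assert auc_score(scores, labels) == pytest.approx(
                    brute_force_auc(scores, labels), abs=1e-12
                )

    def test_perfect_separation(self):
        scores = [0.1, 0.2, 0.8, 0.9]
        labels = [0, 0, 1, 1]
        m = compute_metrics(scores, labels)
        assert m.auc == 1.0 and m.accuracy == 1.0

    def test_single_class_rejected_but_counts_work(self):
        with pytest.raises(ValueError, match="single class"):
            auc_score([0.2, 0.8], [1, 1])
        from nactformer.train import confusion_counts

        c = confusion_counts([0.2, 0.8], [1, 1])
        assert (c.tp, c.fn) == (1, 1)


class TestMetrics:
    def test_hand_computed_confusion_metrics(self):
        # TP=5, TN=3, FP=1, FN=1
        scores = [0.9] * 5 + [0.1] + [0.2] * 3 + [0.7]
        labels = [1] * 5 + [1] + [0] * 3 + [0]
        m = compute_metrics(scores, labels)
        assert (m.counts.tp, m.counts.tn, m.counts.fp, m.counts.fn) == (5, 3, 1, 1)
        assert m.accuracy == pytest.approx(0.8)
        assert m.sensitivity == pytest.approx(5 / 6)
        assert m.specificity == pytest.approx(0.75)


class TestConfidenceInterval:
    def test_hand_computed_interval(self):
        mean, lo, hi = confidence_interval([0.90, 0.92, 0.94, 0.96, 0.98])
        assert mean == pytest.approx(0.94)
        se = np.std([0.90, 0.92, 0.94, 0.96, 0.98], ddof=1) / np.sqrt(5)
        assert se == pytest.approx(0.014142, abs=1e-6)
        assert lo == pytest.approx(0.94 - 1.96 * se, abs=1e-12)
        assert hi == pytest.approx(0.94 + 1.96 * se, abs=1e-12)
        assert (lo, hi) == (pytest.approx(0.91228, abs=1e-4), pytest.approx(0.96772, abs=1e-4))

    def test_equal_folds_give_zero_width(self):
        mean, lo, hi = confidence_interval([0.8, 0.8, 0.8])
        assert hi - lo == pytest.approx(0.0, abs=1e-15)
        assert mean == pytest.approx(0.8)

    def test_order_invariance_and_clipping(self):
        a = confidence_interval([0.1, 0.9, 0.5])
        b = confidence_interval([0.9, 0.5, 0.1])
        assert a == b
        _, lo, hi = confidence_interval([0.99, 1.0, 0.98])
        assert hi <= 1.0

    def test_single_value_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            confidence_interval([0.9])


def naive_delong(scores_a, scores_b, labels):
    """Independent placement-value DeLong computation with explicit loops."""
    scores_a, scores_b = np.asarray(scores_a), np.asarray(scores_b)
    labels = np.asarray(labels)
    pos = np.where(labels == 1)[0]
    neg = np.where(labels == 0)[0]
    m, n = len(pos), len(neg)

    def placements(s):
        v10 = np.zeros(m)
        v01 = np.zeros(n)
        for i, ip in enumerate(pos):
            for j, jn in enumerate(neg):
                psi = 1.0 if s[ip] > s[jn] else (0.5 if s[ip] == s[jn] else 0.0)
                v10[i] += psi / n
                v01[j] += psi / m
        return v10, v01

    va10, va01 = placements(scores_a)
    vb10, vb01 = placements(scores_b)
    auc_a, auc_b = va10.mean(), vb10.mean()

    def cov(x, y):
        return ((x - x.mean()) * (y - y.mean())).sum() / (len(x) - 1)

    var = (cov(va10, va10) + cov(vb10, vb10) - 2 * cov(va10, vb10)) / m + (
        cov(va01, va01) + cov(vb01, vb01) - 2 * cov(va01, vb01)
    ) / n
    z = (auc_a - auc_b) / np.sqrt(var)
    return auc_a, auc_b, 2 * stats.norm.sf(abs(z))


class TestDeLong:
    def test_identical_scores_give_p_one(self):
        s = [0.1, 0.4, 0.35, 0.8, 0.7, 0.2]
        labels = [0, 0, 1, 1, 1, 0]
        auc_a, auc_b, p = delong_test(s, s, labels)
        assert auc_a == auc_b
        assert p == 1.0

    def test_matches_naive_placement_value_oracle(self):
        rng = np.random.default_rng(3)
        for n in (6, 8, 12):
            labels = np.array([1] * (n // 2) + [0] * (n - n // 2))
            a = rng.random(n)
            b = np.clip(a + rng.normal(0, 0.3, n), 0, 1)
            got = delong_test(a, b, labels)
            want = naive_delong(a, b, labels)
            assert got[0] == pytest.approx(want[0], abs=1e-12)
            assert got[1] == pytest.approx(want[1], abs=1e-12)
            assert got[2] == pytest.approx(want[2], abs=1e-10)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(9)
        labels = np.array([1, 1, 1, 0, 0, 0, 1, 0])
        a, b = rng.random(8), rng.random(8)
        auc_a, auc_b, p_ab = delong_test(a, b, labels)
        auc_b2, auc_a2, p_ba = delong_test(b, a, labels)
        assert (auc_a, auc_b) == (auc_a2, auc_b2)
        assert p_ab == pytest.approx(p_ba, abs=1e-15)

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            delong_test([0.1, 0.2], [0.3], [1, 0])


class TestMcNemar:
    def test_b10_c2_hand_arithmetic(self):
        # construct paired predictions with b=10, c=2 discordant cases
        labels = np.ones(20, dtype=int)
        preds_a = np.ones(20, dtype=int)
        preds_b = np.ones(20, dtype=int)
        preds_b[:10] = 0          # a correct, b wrong -> b = 10
        preds_a[10:12] = 0        # b correct, a wrong -> c = 2
        b, c, p = mcnemar_test(preds_a, preds_b, labels)
        assert (b, c) == (10, 2)
        assert p == pytest.approx(stats.chi2.sf(49 / 12, 1), abs=1e-12)
        assert p == pytest.approx(0.0433, abs=2e-4)

    def test_balanced_discordance(self):
        labels = np.ones(8, dtype=int)
        preds_a = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        preds_b = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        b, c, p = mcnemar_test(preds_a, preds_b, labels)
        assert (b, c) == (4, 4)
        assert p == pytest.approx(stats.chi2.sf(1 / 8, 1), abs=1e-12)
        assert p == pytest.approx(0.7237, abs=2e-4)

    def test_no_discordance_gives_p_one(self):
        labels = np.array([1, 0, 1, 0])
        preds = np.array([1, 0, 0, 1])
        assert mcnemar_test(preds, preds, labels)[2] == 1.0

    def test_exact_variant_matches_binomial(self):
        labels = np.ones(12, dtype=int)
        preds_a = np.ones(12, dtype=int)
        preds_b = np.ones(12, dtype=int)
        preds_b[:9] = 0
        preds_a[9:12] = 0
        _, _, p = mcnemar_test(preds_a, preds_b, labels, exact=True)
        assert p == pytest.approx(stats.binomtest(3, 12, 0.5).pvalue, abs=1e-12)


class TestPairedT:
    def test_identical_vectors(self):
        t, p = paired_t_test([0.8, 0.9, 0.7], [0.8, 0.9, 0.7])
        assert (t, p) == (0.0, 1.0)

    def test_constant_shift_is_degenerate(self):
        a = np.array([0.8, 0.82, 0.84, 0.86, 0.88])
        with pytest.warns(UserWarning, match="degenerate"):
            t, p = paired_t_test(a, a - 0.02)
        assert p == 0.0 and t == np.inf

    def test_hand_computed_t_statistic(self):
        a = [0.80, 0.85, 0.90]
        b = [0.78, 0.80, 0.88]
        t, p = paired_t_test(a, b)
        assert t == pytest.approx(3.0, abs=1e-10)
        assert p == pytest.approx(2 * stats.t.sf(3.0, df=2), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal-length"):
            paired_t_test([0.1, 0.2], [0.3])


class TestFoldsAndCheckpoints:
    def test_checkpoint_min_selection_contract(self):
        assert select_checkpoint([0.9, 0.5, 0.7, 0.6]) == 1

    def test_172_patients_give_35_35_34_34_34(self):
        folds = make_folds([f"P{i}" for i in range(172)], k=5, seed=0)
        assert sorted(len(f) for f in folds) == [34, 34, 34, 35, 35]

    def test_folds_partition_exactly_once(self):
        ids = [f"P{i}" for i in range(23)]
        folds = make_folds(ids, k=5, seed=3)
        flat = [pid for f in folds for pid in f]
        assert sorted(flat) == sorted(ids)

    def test_aggregate_mean_equals_hand_mean(self):
        from nactformer.train import FoldMetrics, Metrics, ConfusionCounts

        ms = [
            Metrics(auc=a, accuracy=a, sensitivity=a, specificity=a,
                    counts=ConfusionCounts(1, 1, 0, 0))
            for a in (0.8, 0.9, 1.0)
        ]
        fm = FoldMetrics.from_folds(ms)
        assert fm.aggregate["auc"][0] == pytest.approx(0.9)


class TestTraining:
    def test_loss_decreases_on_separable_micro_cohort(
        self, micro_model_config, micro_train_config
    ):
        pairs = make_micro_pairs(n=16, seed=0)
        train, val = pairs[:12], pairs[12:]
        model = DualInputTransformer(micro_model_config, seed=0)
        result = train_model(model, micro_train_config, train, val)
        assert result.train_losses[-1] < result.train_losses[0]

    def test_same_seed_reproduces_identical_metrics(
        self, micro_model_config, micro_train_config
    ):
        pairs = make_micro_pairs(n=16, seed=1)
        train, val = pairs[:12], pairs[12:]
        outs = []
        for _ in range(2):
            model = DualInputTransformer(micro_model_config, seed=5)
            train_model(model, micro_train_config, train, val)
            outs.append(predict_scores(model, val))
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_empty_dataset_rejected(self, micro_model_config, micro_train_config):
        model = DualInputTransformer(micro_model_config, seed=0)
        with pytest.raises(ValueError, match="non-empty"):
            train_model(model, micro_train_config, [], [])

    def test_invalid_train_config_rejected(self):
        with pytest.raises(ValueError, match="lr"):
            TrainConfig(lr=0.0)
        with pytest.raises(ValueError, match="betas"):
            TrainConfig(betas=(1.5, 0.9))


class TestCrossValidate:
    def test_micro_cross_validation_aggregates_fold_metrics(
        self, micro_model_config, micro_train_config
    ):
        from nactformer.train import cross_validate

        pairs = make_micro_pairs(n=15, seed=4)
        fm = cross_validate(pairs, micro_model_config, micro_train_config, k=3)
        evaluated = len(fm.per_fold) + len(fm.skipped_folds)
        assert evaluated == 3
        assert fm.per_fold, "at least one fold must evaluate both classes"
        for m in fm.per_fold:
            assert 0.0 <= m.auc <= 1.0
        if len(fm.per_fold) >= 2:
            aucs = [m.auc for m in fm.per_fold]
            assert fm.aggregate["auc"][0] == pytest.approx(np.mean(aucs))


class TestAblationHarness:
    def test_two_variant_grid_shape_and_determinism(
        self, micro_model_config, micro_train_config
    ):
        pairs = make_micro_pairs(n=15, seed=2)
        train, val, test = pairs[:9], pairs[9:12], pairs[12:]
        rows = run_ablation(
            ["pre_only", "pre_only"], train, val, test,
            micro_model_config, micro_train_config,
        )
        assert len(rows) == 2
        for key in ("auc", "accuracy", "sensitivity", "specificity",
                    "delong_p_vs_ref", "mcnemar_p_vs_ref"):
            assert key in rows[0]
        # identical variant listed twice with the same seed -> identical rows
        assert rows[0] == rows[1]

    def test_unknown_variant_rejected(self, micro_model_config, micro_train_config):
        with pytest.raises(ValueError, match="unknown ablation"):
            run_ablation(["bogus"], [], [], [], micro_model_config, micro_train_config)
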