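"""Metrics, CV plans, reference baselines and significance testing."""

import itertools

import numpy as np
import pytest

from burnrank.config import EncoderConfig, TrainConfig
from burnrank.evaluation import (
    baseline_brg,
    baseline_naive_mean,
    baseline_random_ranker,
    build_cv_plan,
    classification_metrics,
    compare_wilcoxon,
    ndcg,
    spearman_rho,
    train_invariant_ranker,
)


def dcg_reference(relevance_in_order):
    return sum(
        (2**r - 1) / np.log2(i + 2) for i, r in enumerate(relevance_in_order)
    )


class TestNDCG:
    def test_ideal_ordering_is_one(self):
        assert ndcg([5.0, 4.0, 3.0], [3.0, 2.0, 1.0]) == 1.0

    def test_printed_formula_on_small_example(self):
        rel = [3.0, 2.0, 1.0]
        dcg = 7 / 1 + 3 / np.log2(3) + 1 / 2
        assert dcg_reference(rel) == pytest.approx(dcg)
        assert ndcg([3.0, 2.0, 1.0], rel) == pytest.approx(1.0)
        # worst ordering of the same list
        worst = dcg_reference([1.0, 2.0, 3.0]) / dcg
        assert ndcg([1.0, 2.0, 3.0], rel) == pytest.approx(worst)

    def test_exhaustive_permutation_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(2, 7))
            rel = rng.integers(0, 4, size=n).astype(float)
            scores = rng.normal(size=n)
            order = np.argsort(-scores, kind="stable")
            got = ndcg(scores, rel)
            best = max(
                dcg_reference(rel[list(p)]) for p in itertools.permutations(range(n))
            )
            if best == 0:
                assert got == 1.0
            else:
                assert got == pytest.approx(dcg_reference(rel[order]) / best, abs=1e-8)

    def test_all_zero_relevance_defined_as_one(self):
        assert ndcg([1.0, 2.0], [0.0, 0.0]) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ndcg([], [])

    def test_swap_of_correctly_ordered_items_never_increases(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = 6
            rel = rng.uniform(0, 3, n)
            scores = np.argsort(np.argsort(rel)).astype(float)  # ideal scores
            i, j = sorted(rng.choice(n, 2, replace=False))
            swapped = scores.copy()
            swapped[[i, j]] = swapped[[j, i]]
            assert ndcg(swapped, rel) <= ndcg(scores, rel) + 1e-12

    def test_stable_tie_break_by_id(self):
        # equal scores: item order follows ids, deterministically
        a = ndcg([1.0, 1.0], [3.0, 0.0], ids=[0, 1])
        b = ndcg([1.0, 1.0], [3.0, 0.0], ids=[1, 0])
        assert a == 1.0 and b < 1.0


class TestSpearman:
    def test_identical_and_reversed(self):
        assert spearman_rho([1, 2, 3], [10, 20, 30]) == 1.0
        assert spearman_rho([3, 2, 1], [10, 20, 30]) == -1.0

    def test_hand_computed_example(self):
        assert spearman_rho([1, 2, 3, 5, 4], [1, 2, 3, 4, 5]) == pytest.approx(0.9)

    def test_zero_variance_missing(self):
        assert np.isnan(spearman_rho([1.0, 1.0, 1.0], [1, 2, 3]))

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(2)
        pred = rng.normal(size=20)
        target = rng.normal(size=20)
        assert spearman_rho(np.exp(pred), target) == pytest.approx(
            spearman_rho(pred, target)
        )


class TestClassificationMetrics:
    def test_perfect_separation(self):
        auc, f1 = classification_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert auc == 1.0 and f1 == 1.0

    def test_constant_probabilities_chance_auc(self):
        auc, _ = classification_metrics([0.5] * 6, [0, 1, 0, 1, 0, 1])
        assert auc == 0.5

    def test_f1_confusion_arithmetic(self):
        # 2 TP, 1 FP, 1 FN
        probs = [0.9, 0.9, 0.9, 0.1]
        labels = [1, 1, 0, 1]
        _, f1 = classification_metrics(probs, labels)
        assert f1 == pytest.approx(2 * 2 / (2 * 2 + 1 + 1))

    def test_auc_matches_rank_statistic(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(6, 20))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            p = rng.random(n)
            auc, _ = classification_metrics(p, y)
            pos, neg = p[y == 1], p[y == 0]
            ref = np.mean(
                [(a > b) + 0.5 * (a == b) for a in pos for b in neg]
            )
            assert auc == pytest.approx(ref, abs=1e-8)

    def test_single_class_auc_missing(self):
        auc, _ = classification_metrics([0.2, 0.8], [1, 1])
        assert np.isnan(auc)


class TestCVPlan:
    def test_balanced_deal(self):
        plan = build_cv_plan([f"p{i}" for i in range(20)], np.arange(20.0), 10, seed=0)
        counts = np.bincount(list(plan.fold_of.values()), minlength=10)
        assert (counts == 2).all()

    def test_subject_wise(self):
        pids = ["a", "a", "b", "b", "c", "c", "d", "e", "f", "g", "h", "i", "j", "k"]
        targets = np.arange(len(pids), dtype=float)
        plan = build_cv_plan(pids, targets, n_folds=3, seed=1)
        folds = [plan.fold_of[p] for p in pids]
        assert folds[0] == folds[1] and folds[2] == folds[3]

    def test_quartile_spread_in_folds(self):
        rng = np.random.default_rng(4)
        pids = [f"p{i}" for i in range(60)]
        targets = rng.normal(size=60)
        plan = build_cv_plan(pids, targets, n_folds=10, seed=0)
        for f in range(10):
            bins = {plan.strat_bin[p] for p in plan.test_participants(f)}
            assert len(bins) >= 3

    def test_too_few_participants(self):
        with pytest.raises(ValueError):
            build_cv_plan(["a", "b"], [1.0, 2.0], n_folds=10)

    def test_determinism(self):
        pids = [f"p{i}" for i in range(30)]
        t = np.arange(30.0)
        a = build_cv_plan(pids, t, 10, seed=5).fold_of
        b = build_cv_plan(pids, t, 10, seed=5).fold_of
        assert a == b


class TestBaselines:
    def test_brg_degenerate_training_labels(self):
        preds = baseline_brg([1, 1, 1], size=50, seed=0)
        assert (preds == 1.0).all()

    def test_brg_matches_empirical_rate(self):
        preds = baseline_brg([1] * 30 + [0] * 70, size=10000, seed=1)
        assert 0.28 <= preds.mean() <= 0.32

    def test_brg_chance_level_auc(self):
        rng = np.random.default_rng(2)
        aucs = []
        for rep in range(200):
            y = rng.integers(0, 2, 60)
            if len(np.unique(y)) < 2:
                continue
            p = baseline_brg(y, size=60, seed=rep)
            auc, _ = classification_metrics(p + 1e-9 * rng.random(60), y)
            aucs.append(auc)
        assert abs(np.mean(aucs) - 0.5) < 0.03

    def test_naive_mean(self):
        predict = baseline_naive_mean([2.0, 4.0])
        preds = predict(3)
        assert (preds == 3.0).all()
        assert np.isnan(spearman_rho(preds, [1.0, 2.0, 3.0]))

    def test_random_ranker_degenerate_cases(self):
        assert baseline_random_ranker([5.0], n_draws=10, seed=0) == 1.0
        assert baseline_random_ranker([2.0, 2.0, 2.0], n_draws=10, seed=0) == 1.0

    def test_random_ranker_matches_exhaustive_mean(self):
        rng = np.random.default_rng(5)
        rel = rng.uniform(0, 3, 5)
        exact = np.mean(
            [ndcg(np.array(p, dtype=float), rel) for p in itertools.permutations(range(5))]
        )
        est = np.mean(
            [baseline_random_ranker(rel, n_draws=1000, seed=s) for s in range(5)]
        )
        sd_single = np.std(
            [ndcg(np.array(p, dtype=float), rel) for p in itertools.permutations(range(5))]
        )
        # 1000 draws x 5 seeds: the estimate must sit within 3 SE of exact
        assert abs(est - exact) <= 3 * sd_single / np.sqrt(5000)

    def test_invariant_ranker_finds_planted_covariate_effect(self):
        rng = np.random.default_rng(6)
        n = 80
        Z = np.column_stack([rng.integers(0, 2, n), rng.normal(size=n)])
        targets = 2.0 * Z[:, 0] + 3.0 + 0.3 * rng.normal(size=n)
        pids = np.array([f"s{i}" for i in range(n)])
        enc = EncoderConfig(hidden_size=4, head_hidden_size=8, dropout=0.0, seed=0)
        tc = TrainConfig(learning_rate=1e-2, max_epochs=60, patience=60, seed=0)
        scorer = train_invariant_ranker(Z, targets, pids, enc, tc)
        rho = spearman_rho(scorer.score(None, None, Z), targets)
        assert rho > 0.5

    def test_invariant_ranker_constant_covariates(self):
        enc = EncoderConfig(hidden_size=4, head_hidden_size=4, dropout=0.0, seed=0)
        from burnrank.nn.gru import InvariantScorer

        m = InvariantScorer(2, enc)
        Z = np.ones((5, 2))
        scores = m.score(None, None, Z)
        assert np.ptp(scores) == 0.0
        assert np.isnan(spearman_rho(scores, [1, 2, 3, 4, 5]))


class TestWilcoxon:
    def test_identical_vectors_not_significant(self):
        res = compare_wilcoxon([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert not res.significant and res.p_value == 1.0

    def test_uniform_dominance_significant(self):
        b = np.arange(10.0)
        res = compare_wilcoxon(b + 1.0, b, alternative="greater")
        assert res.significant and res.p_value < 0.05

    def test_type_one_error_calibration(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = rng.normal(size=12)
            b = rng.normal(size=12)
            if compare_wilcoxon(a, b, "greater").significant:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compare_wilcoxon([1.0], [1.0, 2.0])
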