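"""Autodiff, recurrent scorer, pairwise losses and training loops."""

import numpy as np
import pytest

from burnrank.config import EncoderConfig, TrainConfig
from burnrank.nn.autodiff import Tensor
from burnrank.nn.gru import GRUScorer, InvariantScorer
from burnrank.nn.losses import (
    bce_loss_graph,
    margin_loss_graph,
    margin_ranking_loss,
    rank_prob_bce,
)
from burnrank.nn.training import make_pairs, train_pointwise, train_siamese


def finite_diff_check(loss_fn, params, h=1e-6, tol=1e-6):
    loss = loss_fn()
    loss.backward()
    grads = {k: (p.grad.copy() if p.grad is not None else np.zeros_like(p.data)) for k, p in params.items()}
    rng = np.random.default_rng(0)
    for name, p in params.items():
        flat = p.data.ravel()
        for idx in rng.choice(flat.size, size=min(4, flat.size), replace=False):
            old = flat[idx]
            flat[idx] = old + h
            lp = loss_fn().data
            flat[idx] = old - h
            lm = loss_fn().data
            flat[idx] = old
            fd = (lp - lm) / (2 * h)
            assert abs(fd - grads[name].ravel()[idx]) < tol, name


class TestAutodiff:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(3)
        enc = EncoderConfig(hidden_size=4, head_hidden_size=3, dropout=0.0, n_layers=2, seed=1)
        model = GRUScorer(3, 2, enc)
        X = rng.normal(size=(4, 5, 3))
        L = np.array([5, 2, 4, 1])
        Z = rng.normal(size=(4, 2))
        y = np.array([1.0, -1.0])

        def margin_loss():
            si = model.forward(X[:2], L[:2], Z[:2])
            sj = model.forward(X[2:], L[2:], Z[2:])
            return margin_loss_graph(si, sj, y, 0.5)

        def bce_loss():
            si = model.forward(X[:2], L[:2], Z[:2])
            sj = model.forward(X[2:], L[2:], Z[2:])
            return bce_loss_graph(si, sj, y)

        finite_diff_check(margin_loss, model.params)
        for p in model.params.values():
            p.grad = None
        finite_diff_check(bce_loss, model.params)

    def test_broadcast_gradient_shapes(self):
        a = Tensor(np.ones((3, 2)), requires_grad=True)
        b = Tensor(np.ones((1, 2)), requires_grad=True)
        (a * b + b).sum().backward()
        assert a.grad.shape == (3, 2)
        assert b.grad.shape == (1, 2)
        assert np.allclose(b.grad, 6.0)  # 3 from product + 3 from sum


class TestLosses:
    @pytest.mark.parametrize(
        "yi,yj,y,eps,expected",
        [
            (0.6, 0.0, 1, 0.5, 0.0),     # margin satisfied
            (1.0, 1.0, 1, 0.5, 0.5),     # tie penalized by exactly eps
            (0.3, 0.0, -1, 0.5, 0.8),    # wrong direction
        ],
    )
    def test_margin_examples(self, yi, yj, y, eps, expected):
        assert margin_ranking_loss(yi, yj, y, eps) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "yi,yj,y,expected",
        [
            (0.0, 0.0, 1, np.log(2.0)),
            (1.0, 0.0, 1, np.log1p(np.exp(-1.0))),
            (60.0, 0.0, 1, 0.0),  # saturated correct ordering
        ],
    )
    def test_bce_examples(self, yi, yj, y, expected):
        assert rank_prob_bce(yi, yj, y) == pytest.approx(expected, abs=1e-8)

    def test_losses_match_reference_on_random_triples(self):
        rng = np.random.default_rng(8)
        for _ in range(1000):
            yi, yj = rng.normal(scale=5, size=2)
            y = rng.choice([-1, 1])
            eps = rng.uniform(0.1, 2.0)
            ref_m = max(0.0, -y * (yi - yj) + eps)
            # independent stable route: -log sigmoid(y*d) = logaddexp(0, -y*d)
            ref_b = np.logaddexp(0.0, -y * (yi - yj))
            assert margin_ranking_loss(yi, yj, y, eps) == pytest.approx(ref_m, abs=1e-8)
            assert rank_prob_bce(yi, yj, y) == pytest.approx(ref_b, abs=1e-8)

    def test_margin_zero_iff_condition(self):
        rng = np.random.default_rng(9)
        for _ in range(500):
            yi, yj = rng.normal(size=2)
            y = rng.choice([-1, 1])
            eps = rng.uniform(0.1, 1.0)
            loss = float(margin_ranking_loss(yi, yj, y, eps))
            assert (loss == 0.0) == (y * (yi - yj) >= eps)

    def test_bce_stable_at_large_differences(self):
        assert np.isfinite(rank_prob_bce(50.0, -50.0, -1))

    def test_invalid_labels_rejected(self):
        with pytest.raises(ValueError):
            margin_ranking_loss(1.0, 0.0, 0, 0.5)
        with pytest.raises(ValueError):
            rank_prob_bce(1.0, 0.0, 2)
        with pytest.raises(ValueError):
            margin_ranking_loss(1.0, 0.0, 1, -0.1)

    def test_shift_invariance(self):
        """Adding a constant to both scores leaves pairwise losses unchanged."""
        rng = np.random.default_rng(10)
        yi, yj, c = rng.normal(size=3)
        for y in (-1, 1):
            assert margin_ranking_loss(yi + c, yj + c, y) == pytest.approx(
                margin_ranking_loss(yi, yj, y)
            )
            assert rank_prob_bce(yi + c, yj + c, y) == pytest.approx(
                rank_prob_bce(yi, yj, y)
            )


class TestMakePairs:
    def test_gap_filter(self):
        pairs = make_pairs([3.0, 3.4, 4.0], 0.5)
        got = {(p.i, p.j): p.label for p in pairs}
        assert got == {(0, 2): -1, (1, 2): -1}

    def test_all_equal_targets(self):
        assert make_pairs([2.0, 2.0, 2.0], 0.5) == []

    def test_combinatorial_count(self):
        targets = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert len(make_pairs(targets, 0.5)) == 5 * 4 // 2

    def test_within_subject_toggle(self):
        pairs = make_pairs([1.0, 5.0], 0.5, participants=["a", "a"], allow_within_subject=False)
        assert pairs == []


class TestScorer:
    def setup_method(self):
        self.enc = EncoderConfig(hidden_size=6, head_hidden_size=4, dropout=0.3, seed=2)
        self.model = GRUScorer(3, 2, self.enc)
        rng = np.random.default_rng(0)
        self.X = rng.normal(size=(2, 8, 3))
        self.L = np.array([5, 5])
        self.Z = rng.normal(size=(2, 2))

    def test_padding_content_is_ignored(self):
        X2 = self.X.copy()
        X2[:, 5:, :] = 999.0  # perturb padded tail only
        a = self.model.score(self.X, self.L, self.Z)
        b = self.model.score(X2, self.L, self.Z)
        assert np.array_equal(a, b)

    def test_eval_mode_deterministic(self):
        a = self.model.score(self.X, self.L, self.Z)
        b = self.model.score(self.X, self.L, self.Z)
        assert np.array_equal(a, b)

    def test_zero_network_scores_zero(self):
        self.model.zero_weights()
        assert np.array_equal(self.model.score(self.X, self.L, self.Z), [0.0, 0.0])

    def test_score_antisymmetry_of_shared_branches(self):
        si = self.model.score(self.X[[0]], self.L[[0]], self.Z[[0]])
        sj = self.model.score(self.X[[1]], self.L[[1]], self.Z[[1]])
        assert (si - sj) == pytest.approx(-(sj - si))
        # identical inputs through both branches give identical scores
        assert self.model.score(self.X[[0]], self.L[[0]], self.Z[[0]]) == pytest.approx(si)

    def test_feature_dim_mismatch(self):
        with pytest.raises(ValueError):
            self.model.score(self.X[:, :, :2], self.L, self.Z)


def _toy_rank_problem(n=50, T=5, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, T, 2))
    targets = X[:, :, 0].mean(axis=1) * 3.0
    Z = np.zeros((n, 1))
    L = np.full(n, T)
    pids = np.array([f"s{i}" for i in range(n)])
    return X, L, Z, targets, pids


class TestTraining:
    def test_patience_stops_after_ten_stale_epochs(self):
        X, L, Z, y, pids = _toy_rank_problem()
        tc = TrainConfig(learning_rate=1e-3, max_epochs=100, patience=10, seed=0,
                         pair_gap=0.5)
        enc = EncoderConfig(hidden_size=4, head_hidden_size=4, dropout=0.0, seed=0)
        # validation loss improves until epoch 3, never afterwards
        fake = lambda epoch: 1.0 if epoch >= 3 else 10.0 - epoch
        scorer = train_siamese(X, L, Z, y, pids, enc, tc, val_loss_override=fake)
        assert scorer.epochs_run == 13
        assert scorer.best_epoch == 3

    def test_separable_toy_problem_learned(self):
        X, L, Z, y, pids = _toy_rank_problem(n=50, T=5, seed=1)
        tc = TrainConfig(learning_rate=1e-2, max_epochs=100, patience=100,
                         batch_size=64, seed=1)
        enc = EncoderConfig(hidden_size=8, head_hidden_size=8, dropout=0.0, seed=1)
        scorer = train_siamese(X, L, Z, y, pids, enc, tc)
        scores = scorer.score(X, L, Z)
        pairs = make_pairs(y, 0.5)
        correct = sum(
            1 for p in pairs if np.sign(scores[p.i] - scores[p.j]) == p.label
        )
        assert correct / len(pairs) >= 0.95

    def test_seed_determinism_of_training(self):
        X, L, Z, y, pids = _toy_rank_problem(n=20, T=4, seed=2)
        tc = TrainConfig(learning_rate=1e-3, max_epochs=5, patience=5, seed=7)
        enc = EncoderConfig(hidden_size=4, head_hidden_size=4, dropout=0.2, seed=7)
        w1 = train_siamese(X, L, Z, y, pids, enc, tc).model.get_weights()
        w2 = train_siamese(X, L, Z, y, pids, enc, tc).model.get_weights()
        for k in w1:
            assert np.array_equal(w1[k], w2[k])

    def test_empty_pair_set_rejected(self):
        X, L, Z, y, pids = _toy_rank_problem(n=10, T=3, seed=3)
        tc = TrainConfig(seed=0)
        enc = EncoderConfig(seed=0)
        with pytest.raises(ValueError, match="pair"):
            train_siamese(X, L, Z, np.full(10, 3.0), pids, enc, tc)

    def test_pointwise_regression_fits_constant(self):
        rng = np.random.default_rng(4)
        n = 16
        X = rng.normal(size=(n, 4, 2))
        L = np.full(n, 4)
        Z = np.zeros((n, 1))
        y = np.full(n, 2.0)
        pids = np.array([f"s{i}" for i in range(n)])
        tc = TrainConfig(learning_rate=1e-2, max_epochs=200, patience=200,
                         loss="mse_reg", seed=0)
        enc = EncoderConfig(hidden_size=4, head_hidden_size=4, dropout=0.0, seed=0)
        scorer = train_pointwise(X, L, Z, y, pids, enc, tc)
        assert np.mean((scorer.score(X, L, Z) - 2.0) ** 2) < 0.01

    def test_pointwise_classification_degenerate_labels(self):
        rng = np.random.default_rng(5)
        n = 16
        X = rng.normal(size=(n, 4, 2))
        L = np.full(n, 4)
        Z = np.zeros((n, 1))
        y = np.ones(n)
        pids = np.array([f"s{i}" for i in range(n)])
        tc = TrainConfig(learning_rate=1e-2, max_epochs=200, patience=200,
                         loss="bce_class", seed=0)
        enc = EncoderConfig(hidden_size=4, head_hidden_size=4, dropout=0.0, seed=0)
        scorer = train_pointwise(X, L, Z, y, pids, enc, tc)
        assert scorer.predict_proba(X, L, Z).min() > 0.9

    def test_invariant_scorer_ignores_sequences(self):
        enc = EncoderConfig(hidden_size=4, head_hidden_size=4, dropout=0.0, seed=3)
        m = InvariantScorer(2, enc)
        rng = np.random.default_rng(0)
        Z = rng.normal(size=(3, 2))
        a = m.score(rng.normal(size=(3, 5, 7)), np.full(3, 5), Z)
        b = m.score(rng.normal(size=(3, 9, 1)), np.full(3, 9), Z)
        assert np.array_equal(a, b)
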