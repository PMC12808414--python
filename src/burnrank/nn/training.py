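"""Training loops for the pointwise and siamese (pairwise) recurrent models.

Both loops share one scaffold: Adam optimization, an internal subject-wise
validation split for early stopping with a fixed patience, and full seed
determinism (batch order, weight init, dropout masks).  The siamese loop
feeds each pair through the *same* scorer — one parameter set serves both
branches, so a single gradient step moves both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from ..config import EncoderConfig, TrainConfig
from .autodiff import Adam, Tensor
from .gru import GRUScorer, InvariantScorer, _ScorerBase
from .losses import bce_loss_graph, margin_loss_graph


@dataclass
class Pair:
    i: int
    j: int
    label: int  # +1 iff target_i > target_j


def make_pairs(
    targets: Sequence[float],
    pair_gap: float,
    participants: Optional[Sequence] = None,
    allow_within_subject: bool = True,
) -> List[Pair]:
    """Enumerate trainable ordered pairs.

    Every unordered pair of instances whose targets differ by at least
    ``pair_gap`` is emitted once, oriented by index order (i < j) with
    label +1 iff ``targets[i] > targets[j]``.  Pairs must be built strictly
    within one data split; cross-split pairing is a leakage bug.
    """
    t = np.asarray(targets, dtype=float)
    n = len(t)
    pairs: List[Pair] = []
    for i in range(n):
        for j in range(i + 1, n):
            gap = abs(t[i] - t[j])
            if gap < pair_gap or gap == 0.0:
                continue
            if (
                not allow_within_subject
                and participants is not None
                and participants[i] == participants[j]
            ):
                continue
            pairs.append(Pair(i, j, 1 if t[i] > t[j] else -1))
    return pairs


@dataclass
class TrainedScorer:
    model: _ScorerBase
    best_epoch: int
    epochs_run: int
    history: List[Tuple[float, float]] = field(default_factory=list)

    def score(self, X, lengths, Z) -> np.ndarray:
        return self.model.score(X, lengths, Z)

    def predict_proba(self, X, lengths, Z) -> np.ndarray:
        s = self.score(X, lengths, Z)
        return 1.0 / (1.0 + np.exp(-s))


def _subject_split(
    participants: np.ndarray, val_fraction: float, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    subjects = np.array(sorted(set(participants)))
    rng.shuffle(subjects)
    n_val = max(1, int(round(val_fraction * len(subjects))))
    if n_val >= len(subjects):
        n_val = len(subjects) - 1
    val_subjects = set(subjects[:n_val])
    val_mask = np.array([p in val_subjects for p in participants])
    return np.flatnonzero(~val_mask), np.flatnonzero(val_mask)


def _pair_loss_graph(model, X, lengths, Z, batch, loss_name, eps, training, rng):
    idx_i = np.array([p.i for p in batch])
    idx_j = np.array([p.j for p in batch])
    labels = np.array([p.label for p in batch], dtype=float)
    si = model.forward(X[idx_i], lengths[idx_i], Z[idx_i], training=training, rng=rng)
    sj = model.forward(X[idx_j], lengths[idx_j], Z[idx_j], training=training, rng=rng)
    if loss_name == "rank_margin":
        return margin_loss_graph(si, sj, labels, eps)
    return bce_loss_graph(si, sj, labels)


def _run_training(
    model: _ScorerBase,
    train_cfg: TrainConfig,
    epoch_fn: Callable[[np.random.Generator, Adam], None],
    val_fn: Callable[[], float],
    val_loss_override: Optional[Callable[[int], float]] = None,
) -> TrainedScorer:
    rng = np.random.default_rng(train_cfg.seed)
    opt = Adam(model.parameters(), lr=train_cfg.learning_rate)
    best_val = np.inf
    best_weights = model.get_weights()
    best_epoch = 0
    stale = 0
    history: List[Tuple[float, float]] = []
    epoch = 0
    for epoch in range(1, train_cfg.max_epochs + 1):
        epoch_fn(rng, opt)
        val_loss = (
            val_loss_override(epoch) if val_loss_override is not None else val_fn()
        )
        history.append((epoch, float(val_loss)))
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_weights = model.get_weights()
            best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= train_cfg.patience:
                break
    model.set_weights(best_weights)
    return TrainedScorer(model, best_epoch, epoch, history)


def train_siamese(
    X: np.ndarray,
    lengths: np.ndarray,
    Z: np.ndarray,
    targets: np.ndarray,
    participants: np.ndarray,
    encoder_cfg: EncoderConfig,
    train_cfg: TrainConfig,
    model: Optional[_ScorerBase] = None,
    val_loss_override: Optional[Callable[[int], float]] = None,
) -> TrainedScorer:
    """Fit the shared-weight pairwise ranker.

    A subject-wise ``val_fraction`` slice of the training windows is held
    out for early stopping; ranking pairs are built independently inside
    each side so no pair straddles the split.
    """
    X = np.asarray(X, dtype=float)
    lengths = np.asarray(lengths, dtype=int)
    Z = np.asarray(Z, dtype=float)
    targets = np.asarray(targets, dtype=float)
    participants = np.asarray(participants)
    split_rng = np.random.default_rng(train_cfg.seed + 1)
    tr_idx, va_idx = _subject_split(participants, train_cfg.val_fraction, split_rng)

    def side_pairs(idx: np.ndarray) -> List[Pair]:
        local = make_pairs(
            targets[idx],
            train_cfg.pair_gap,
            participants=participants[idx],
            allow_within_subject=train_cfg.allow_within_subject_pairs,
        )
        return [Pair(idx[p.i], idx[p.j], p.label) for p in local]

    train_pairs = side_pairs(tr_idx)
    val_pairs = side_pairs(va_idx)
    if not train_pairs:
        raise ValueError("no trainable pairs: all target gaps below pair_gap")
    if not val_pairs:
        # Degenerate validation side (tiny cohorts); fall back to train pairs.
        val_pairs = train_pairs

    if model is None:
        model = GRUScorer(X.shape[2], Z.shape[1], encoder_cfg)

    def epoch_fn(rng: np.random.Generator, opt: Adam) -> None:
        order = rng.permutation(len(train_pairs))
        if train_cfg.max_pairs_per_epoch > 0:
            order = order[: train_cfg.max_pairs_per_epoch]
        for lo in range(0, len(order), train_cfg.batch_size):
            batch = [train_pairs[k] for k in order[lo : lo + train_cfg.batch_size]]
            loss = _pair_loss_graph(
                model, X, lengths, Z, batch,
                train_cfg.loss, train_cfg.margin_eps, True, rng,
            )
            opt.zero_grad()
            loss.backward()
            opt.step()

    def val_fn() -> float:
        loss = _pair_loss_graph(
            model, X, lengths, Z, val_pairs,
            train_cfg.loss, train_cfg.margin_eps, False, None,
        )
        return float(loss.data)

    return _run_training(model, train_cfg, epoch_fn, val_fn, val_loss_override)


def train_pointwise(
    X: np.ndarray,
    lengths: np.ndarray,
    Z: np.ndarray,
    y: np.ndarray,
    participants: np.ndarray,
    encoder_cfg: EncoderConfig,
    train_cfg: TrainConfig,
    model: Optional[_ScorerBase] = None,
    val_loss_override: Optional[Callable[[int], float]] = None,
) -> TrainedScorer:
    """Fit the pointwise recurrent model.

    ``train_cfg.loss`` selects per-sample mean-squared error (regression on
    the continuous subscale score) or binary cross-entropy on a sigmoid
    output (classification against the dichotomized label).
    """
    X = np.asarray(X, dtype=float)
    lengths = np.asarray(lengths, dtype=int)
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    participants = np.asarray(participants)
    if len(y) == 0:
        raise ValueError("empty training set")
    if train_cfg.loss not in ("mse_reg", "bce_class"):
        raise ValueError("pointwise training requires loss mse_reg or bce_class")
    split_rng = np.random.default_rng(train_cfg.seed + 1)
    tr_idx, va_idx = _subject_split(participants, train_cfg.val_fraction, split_rng)
    if len(va_idx) == 0:
        va_idx = tr_idx

    if model is None:
        model = GRUScorer(X.shape[2], Z.shape[1], encoder_cfg)

    def sample_loss(idx: np.ndarray, training: bool, rng) -> Tensor:
        s = model.forward(X[idx], lengths[idx], Z[idx], training=training, rng=rng)
        t = y[idx].reshape(-1, 1)
        if train_cfg.loss == "mse_reg":
            d = s - Tensor(t)
            return (d * d).mean()
        # BCE with logits: t*softplus(-s) + (1-t)*softplus(s)
        return (Tensor(t) * (-s).softplus() + Tensor(1.0 - t) * s.softplus()).mean()

    def epoch_fn(rng: np.random.Generator, opt: Adam) -> None:
        order = rng.permutation(len(tr_idx))
        for lo in range(0, len(order), train_cfg.batch_size):
            idx = tr_idx[order[lo : lo + train_cfg.batch_size]]
            loss = sample_loss(idx, True, rng)
            opt.zero_grad()
            loss.backward()
            opt.step()

    def val_fn() -> float:
        return float(sample_loss(va_idx, False, None).data)

    return _run_training(model, train_cfg, epoch_fn, val_fn, val_loss_override)
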