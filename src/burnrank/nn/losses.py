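"""Pairwise ranking losses.

Two comparison functions over a pair of scalar scores (yhat_i, yhat_j) with
ground-truth ordering label y in {-1, +1} (y = +1 iff instance i should
rank above j):

* margin ranking loss:  max(0, -y * (yhat_i - yhat_j) + eps)
* RankNet-style BCE:    the score difference is squashed through a sigmoid
  to give P(i above j), scored with binary cross-entropy, computed in the
  numerically stable softplus form  log(1 + exp(-y * (yhat_i - yhat_j))).

Numpy versions here are the reference used for evaluation and testing; the
autodiff graph builds the same expressions during training.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


def _check_labels(y) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise ValueError("ordering labels must be -1 or +1")
    return y


def margin_ranking_loss(yhat_i, yhat_j, y, eps: float = 0.5):
    """Hinge loss on the signed score difference; zero iff y*(Δ) >= eps."""
    if eps <= 0:
        raise ValueError("margin eps must be > 0")
    y = _check_labels(y)
    d = np.asarray(yhat_i, dtype=float) - np.asarray(yhat_j, dtype=float)
    return np.maximum(0.0, -y * d + eps)


def rank_prob_bce(yhat_i, yhat_j, y):
    """Binary cross-entropy of sigmoid(yhat_i - yhat_j) against the label."""
    y = _check_labels(y)
    d = np.asarray(yhat_i, dtype=float) - np.asarray(yhat_j, dtype=float)
    x = -y * d
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


def margin_loss_graph(scores_i: Tensor, scores_j: Tensor, y: np.ndarray, eps: float) -> Tensor:
    y = _check_labels(y).reshape(-1, 1)
    diff = scores_i - scores_j
    return (Tensor(-y) * diff + eps).relu().mean()


def bce_loss_graph(scores_i: Tensor, scores_j: Tensor, y: np.ndarray) -> Tensor:
    y = _check_labels(y).reshape(-1, 1)
    diff = scores_i - scores_j
    return (Tensor(-y) * diff).softplus().mean()
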