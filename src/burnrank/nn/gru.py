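"""Recurrent sequence scorer and the time-invariant feed-forward baseline.

The scorer mirrors the sequential branch of the pairwise ranking
architecture: a (possibly stacked) GRU consumes the first ``valid_length``
daily observations of each window, its final hidden state is concatenated
with the time-invariant covariate vector, and a single-hidden-layer
feed-forward head with dropout maps the joint representation to one scalar
risk score.  Padded time steps are masked out of the recurrence, so padding
content can never influence the output.
"""

from __future__ import annotations

from typing import Dict, List, Optional

import numpy as np

from ..config import EncoderConfig
from .autodiff import Tensor


def _uniform_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class _ScorerBase:
    """Shared parameter bookkeeping for scorers."""

    params: Dict[str, Tensor]

    def parameters(self) -> List[Tensor]:
        return list(self.params.values())

    def get_weights(self) -> Dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def set_weights(self, weights: Dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            v.data = weights[k].copy()

    def zero_weights(self) -> None:
        for v in self.params.values():
            v.data = np.zeros_like(v.data)

    def _head(
        self,
        joint: Tensor,
        training: bool,
        rng: Optional[np.random.Generator],
    ) -> Tensor:
        hidden = (joint @ self.params["head_W1"] + self.params["head_b1"]).relu()
        if training and self.dropout > 0.0:
            if rng is None:
                raise ValueError("training-mode forward requires an rng for dropout")
            keep = 1.0 - self.dropout
            mask = (rng.random(hidden.shape) < keep).astype(float) / keep
            hidden = hidden * Tensor(mask)
        return hidden @ self.params["head_W2"] + self.params["head_b2"]


class GRUScorer(_ScorerBase):
    def __init__(self, n_features: int, n_invariant: int, config: EncoderConfig):
        self.n_features = n_features
        self.n_invariant = n_invariant
        self.config = config
        self.dropout = config.dropout
        h = config.hidden_size
        rng = np.random.default_rng(config.seed)
        params: Dict[str, np.ndarray] = {}
        in_dim = n_features
        for layer in range(config.n_layers):
            for gate in ("z", "r", "n"):
                params[f"gru{layer}_W{gate}"] = _uniform_init(rng, (in_dim, h), h)
                params[f"gru{layer}_U{gate}"] = _uniform_init(rng, (h, h), h)
                params[f"gru{layer}_bx{gate}"] = _uniform_init(rng, (1, h), h)
                params[f"gru{layer}_bh{gate}"] = _uniform_init(rng, (1, h), h)
            in_dim = h
        joint = h + n_invariant
        hh = config.head_hidden_size
        params["head_W1"] = _uniform_init(rng, (joint, hh), joint)
        params["head_b1"] = _uniform_init(rng, (1, hh), joint)
        params["head_W2"] = _uniform_init(rng, (hh, 1), hh)
        params["head_b2"] = _uniform_init(rng, (1, 1), hh)
        self.params = {k: Tensor(v, requires_grad=True) for k, v in params.items()}

    def forward(
        self,
        X: np.ndarray,
        lengths: np.ndarray,
        Z: np.ndarray,
        training: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> Tensor:
        """Score a batch.

        Parameters
        ----------
        X : (batch, time, n_features) array with padded tails.
        lengths : (batch,) valid lengths; steps at or beyond a sample's
            length are masked out of the recurrence.
        Z : (batch, n_invariant) time-invariant covariates.
        """
        X = np.asarray(X, dtype=float)
        Z = np.asarray(Z, dtype=float)
        lengths = np.asarray(lengths, dtype=int)
        if X.ndim != 3 or X.shape[2] != self.n_features:
            raise ValueError(
                f"expected (batch, time, {self.n_features}) sequences, got {X.shape}"
            )
        if Z.shape[1] != self.n_invariant:
            raise ValueError(
                f"expected {self.n_invariant} time-invariant covariates, got {Z.shape[1]}"
            )
        if np.any(lengths < 1):
            raise ValueError("every sample must have valid_length >= 1")
        B, T, _ = X.shape
        p = self.params
        layer_inputs: List[Tensor] = [Tensor(X[:, t, :]) for t in range(T)]
        h_final = None
        for layer in range(self.config.n_layers):
            h = Tensor(np.zeros((B, self.config.hidden_size)))
            outputs: List[Tensor] = []
            for t in range(T):
                x_t = layer_inputs[t]
                zg = (
                    x_t @ p[f"gru{layer}_Wz"] + p[f"gru{layer}_bxz"]
                    + h @ p[f"gru{layer}_Uz"] + p[f"gru{layer}_bhz"]
                ).sigmoid()
                rg = (
                    x_t @ p[f"gru{layer}_Wr"] + p[f"gru{layer}_bxr"]
                    + h @ p[f"gru{layer}_Ur"] + p[f"gru{layer}_bhr"]
                ).sigmoid()
                ng = (
                    x_t @ p[f"gru{layer}_Wn"] + p[f"gru{layer}_bxn"]
                    + rg * (h @ p[f"gru{layer}_Un"] + p[f"gru{layer}_bhn"])
                ).tanh()
                h_new = (1.0 - zg) * ng + zg * h
                mask = Tensor((t < lengths).astype(float)[:, None])
                h = mask * h_new + (1.0 - mask) * h
                outputs.append(h)
            layer_inputs = outputs
            h_final = h
        joint = Tensor.concat([h_final, Tensor(Z)], axis=1)
        return self._head(joint, training, rng)

    def score(self, X: np.ndarray, lengths: np.ndarray, Z: np.ndarray) -> np.ndarray:
        """Deterministic evaluation-mode scores as a flat numpy array."""
        return self.forward(X, lengths, Z, training=False).data.ravel()


class InvariantScorer(_ScorerBase):
    """Feed-forward scorer over time-invariant covariates only.

    Serves as the reference ranker quantifying how far demographic and
    occupational information alone goes, isolating the added value of the
    wearable-derived trajectories.
    """

    def __init__(self, n_invariant: int, config: EncoderConfig):
        self.n_invariant = n_invariant
        self.config = config
        self.dropout = config.dropout
        rng = np.random.default_rng(config.seed)
        hh = config.head_hidden_size
        params = {
            "head_W1": _uniform_init(rng, (n_invariant, hh), n_invariant),
            "head_b1": _uniform_init(rng, (1, hh), n_invariant),
            "head_W2": _uniform_init(rng, (hh, 1), hh),
            "head_b2": _uniform_init(rng, (1, 1), hh),
        }
        self.params = {k: Tensor(v, requires_grad=True) for k, v in params.items()}

    def forward(
        self,
        X: np.ndarray,
        lengths: np.ndarray,
        Z: np.ndarray,
        training: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> Tensor:
        Z = np.asarray(Z, dtype=float)
        if Z.shape[1] != self.n_invariant:
            raise ValueError(
                f"expected {self.n_invariant} time-invariant covariates, got {Z.shape[1]}"
            )
        return self._head(Tensor(Z), training, rng)

    def score(self, X: np.ndarray, lengths: np.ndarray, Z: np.ndarray) -> np.ndarray:
        return self.forward(X, lengths, Z, training=False).data.ravel()
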