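"""Federated averaging (FedAvg) for a small multilayer perceptron.

Each communication round the coordinator broadcasts the current parameters;
every party runs a few epochs of mini-batch gradient descent on its local
data and returns its updated parameters; the coordinator replaces the model
with the sample-count-weighted mean.  With one full-batch local step the
weighted mean of locally updated parameters equals one gradient step on the
pooled data exactly, which anchors the scheme's correctness; with more
local work the methods diverge gently and FedAvg trades communication for
fidelity.

The network is a plain-numpy MLP (default: one tanh hidden layer) so that
the federation logic carries no deep-learning-framework dependency.  Losses
are mean-per-sample (MSE or binary cross-entropy), making gradients
averages over rows — the property the count-weighted FedAvg identity needs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Architecture",
    "ModelParams",
    "TrainConfig",
    "init_params",
    "local_update",
    "fedavg",
    "train_federated",
]

DIVERGENCE_LOSS = 1e6


@dataclass(frozen=True)
class Architecture:
    """Layer sizes, e.g. (12, 32, 1): input, hidden..., output."""

    layer_sizes: tuple[int, ...] = (12, 32, 1)
    activation: str = "tanh"

    def __post_init__(self) -> None:
        if len(self.layer_sizes) < 2:
            raise ValueError("need at least input and output layers")
        if self.activation not in ("tanh", "relu", "identity"):
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass
class ModelParams:
    """Weights and biases per layer; the unit FedAvg averages."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def copy(self) -> "ModelParams":
        return ModelParams(
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
        )

    def as_vector(self) -> np.ndarray:
        parts = [w.ravel() for w in self.weights] + [
            b.ravel() for b in self.biases
        ]
        return np.concatenate(parts)

    @classmethod
    def from_vector(
        cls, v: np.ndarray, arch: Architecture
    ) -> "ModelParams":
        sizes = arch.layer_sizes
        weights, biases = [], []
        k = 0
        for i in range(len(sizes) - 1):
            n = sizes[i] * sizes[i + 1]
            weights.append(v[k : k + n].reshape(sizes[i], sizes[i + 1]))
            k += n
        for i in range(len(sizes) - 1):
            n = sizes[i + 1]
            biases.append(v[k : k + n].copy())
            k += n
        return cls(weights=weights, biases=biases)

    def to_dict(self) -> dict:
        return {
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }


@dataclass(frozen=True)
class TrainConfig:
    rounds: int = 50
    local_epochs: int = 1
    batch_size: int = 32
    learning_rate: float = 0.05
    loss: str = "mse"  # or "cross_entropy"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.rounds, self.local_epochs, self.batch_size) < 1:
            raise ValueError("rounds, epochs and batch size must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning rate must be >= 0")
        if self.loss not in ("mse", "cross_entropy"):
            raise ValueError(f"unknown loss {self.loss!r}")


def init_params(arch: Architecture, seed: int) -> ModelParams:
    """Glorot-uniform weights, zero biases, deterministic under the seed."""
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    sizes = arch.layer_sizes
    for i in range(len(sizes) - 1):
        limit = np.sqrt(6.0 / (sizes[i] + sizes[i + 1]))
        weights.append(
            rng.uniform(-limit, limit, size=(sizes[i], sizes[i + 1]))
        )
        biases.append(np.zeros(sizes[i + 1]))
    return ModelParams(weights=weights, biases=biases)


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "tanh":
        return np.tanh(z)
    if kind == "relu":
        return np.maximum(z, 0.0)
    return z


def _act_grad(a: np.ndarray, z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "tanh":
        return 1.0 - a**2
    if kind == "relu":
        return (z > 0).astype(float)
    return np.ones_like(z)


def forward(
    params: ModelParams, X: np.ndarray, arch: Architecture
) -> np.ndarray:
    """Network output; linear final layer (sigmoid applied inside the
    cross-entropy loss, not here)."""
    a = np.asarray(X, dtype=float)
    last = len(params.weights) - 1
    for i, (w, b) in enumerate(zip(params.weights, params.biases)):
        z = a @ w + b
        a = z if i == last else _act(z, arch.activation)
    return a


def loss_value(
    params: ModelParams,
    X: np.ndarray,
    y: np.ndarray,
    arch: Architecture,
    loss: str,
) -> float:
    """Mean-per-sample loss on a dataset."""
    out = forward(params, X, arch)
    y = np.asarray(y, dtype=float).reshape(out.shape)
    if loss == "mse":
        return float(np.mean((out - y) ** 2))
    # binary cross-entropy on logits, numerically stable
    z = out
    return float(np.mean(np.logaddexp(0.0, z) - y * z))


def _backprop(
    params: ModelParams,
    X: np.ndarray,
    y: np.ndarray,
    arch: Architecture,
    loss: str,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Gradients of the mean-per-sample loss w.r.t. all tensors."""
    n = X.shape[0]
    activations = [np.asarray(X, dtype=float)]
    zs = []
    a = activations[0]
    last = len(params.weights) - 1
    for i, (w, b) in enumerate(zip(params.weights, params.biases)):
        z = a @ w + b
        zs.append(z)
        a = z if i == last else _act(z, arch.activation)
        activations.append(a)
    y = np.asarray(y, dtype=float).reshape(activations[-1].shape)
    if loss == "mse":
        delta = 2.0 * (activations[-1] - y) / n
    else:  # d/dz of mean BCE-with-logits
        p = 1.0 / (1.0 + np.exp(-activations[-1]))
        delta = (p - y) / n
    grads_w: list[np.ndarray] = [None] * len(params.weights)
    grads_b: list[np.ndarray] = [None] * len(params.weights)
    for i in range(last, -1, -1):
        grads_w[i] = activations[i].T @ delta
        grads_b[i] = delta.sum(axis=0)
        if i > 0:
            delta = (delta @ params.weights[i].T) * _act_grad(
                activations[i], zs[i - 1], arch.activation
            )
    return grads_w, grads_b


def local_update(
    params: ModelParams,
    X: np.ndarray,
    y: np.ndarray,
    arch: Architecture,
    cfg: TrainConfig,
    rng: np.random.Generator,
) -> ModelParams:
    """``local_epochs`` of mini-batch SGD starting from the broadcast
    parameters; batches are reshuffled per epoch, deterministically under
    the party's RNG stream."""
    params = params.copy()
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    for _ in range(cfg.local_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            gw, gb = _backprop(params, X[idx], y[idx], arch, cfg.loss)
            for i in range(len(params.weights)):
                params.weights[i] -= cfg.learning_rate * gw[i]
                params.biases[i] -= cfg.learning_rate * gb[i]
            if not np.all(np.isfinite(params.weights[0])):
                raise FloatingPointError(
                    "NaN/inf parameters during local update"
                )
    return params


def fedavg(
    param_list: list[ModelParams], sample_counts: list[int]
) -> ModelParams:
    """Per-tensor weighted mean with weights n_i / Σn_i."""
    if len(param_list) != len(sample_counts):
        raise ValueError("one sample count per parameter set required")
    shapes = [[w.shape for w in p.weights] for p in param_list]
    if any(s != shapes[0] for s in shapes):
        raise ValueError("architecture mismatch across parties")
    total = float(sum(sample_counts))
    out = param_list[0].copy()
    for i in range(len(out.weights)):
        out.weights[i] = sum(
            (c / total) * p.weights[i]
            for c, p in zip(sample_counts, param_list)
        )
        out.biases[i] = sum(
            (c / total) * p.biases[i]
            for c, p in zip(sample_counts, param_list)
        )
    return out


def train_federated(
    parties: list[tuple[np.ndarray, np.ndarray]],
    arch: Architecture,
    cfg: TrainConfig,
) -> tuple[ModelParams, list[float]]:
    """Full FedAvg loop: broadcast → local update at each party → weighted
    average, for ``cfg.rounds`` rounds.

    Returns the final parameters and the per-round pooled training loss.
    Aborts (returning the last finite round) if the loss diverges.
    """
    if not parties:
        raise ValueError("need at least one party")
    counts = [X.shape[0] for X, _ in parties]
    params = init_params(arch, cfg.seed)
    party_rngs = [
        np.random.default_rng(s)
        for s in np.random.SeedSequence(cfg.seed).spawn(len(parties))
    ]
    history: list[float] = []
    for rnd in range(cfg.rounds):
        locals_ = [
            local_update(params, X, y, arch, cfg, party_rngs[i])
            for i, (X, y) in enumerate(parties)
        ]
        new_params = fedavg(locals_, counts)
        pooled_loss = sum(
            c * loss_value(new_params, X, y, arch, cfg.loss)
            for c, (X, y) in zip(counts, parties)
        ) / sum(counts)
        if not np.isfinite(pooled_loss) or pooled_loss > DIVERGENCE_LOSS:
            logger.error(
                "training diverged at round %d (loss=%g); "
                "returning last good parameters", rnd, pooled_loss
            )
            break
        params = new_params
        history.append(pooled_loss)
    return params, history
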