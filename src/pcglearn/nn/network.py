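"""Sequential network container, Adam optimizer and training loop."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import Layer, Softmax

__all__ = ["Network", "Adam", "TrainingHistory", "train_network"]


@dataclass
class TrainingHistory:
    """Per-epoch loss/accuracy curves plus wall time."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    wall_time_s: float = 0.0

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)

    def to_rows(self) -> list[dict]:
        return [
            {
                "epoch": e + 1,
                "train_loss": self.train_loss[e],
                "val_loss": self.val_loss[e] if self.val_loss else float("nan"),
                "train_acc": self.train_acc[e],
                "val_acc": self.val_acc[e] if self.val_acc else float("nan"),
            }
            for e in range(self.n_epochs)
        ]


class Network:
    """Ordered stack of layers ending in a softmax."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Forward pass stopping before the final softmax."""
        body = self.layers[:-1] if isinstance(self.layers[-1], Softmax) else self.layers
        for layer in body:
            x = layer.forward(x, train=train)
        return x

    def backward_from_logits(self, grad: np.ndarray) -> None:
        body = self.layers[:-1] if isinstance(self.layers[-1], Softmax) else self.layers
        for layer in reversed(body):
            grad = layer.backward(grad)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        outs = [
            self.forward(x[i : i + batch_size], train=False)
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(outs) if outs else np.empty((0, 2))

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(layer, name) for layer in self.layers for name in layer.params]

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)


class Adam:
    """Adam optimizer over a network's parameter arrays."""

    def __init__(self, network: Network, learning_rate: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.network = network
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {id(l): {k: np.zeros_like(v) for k, v in l.params.items()} for l in network.layers}
        self.v = {id(l): {k: np.zeros_like(v) for k, v in l.params.items()} for l in network.layers}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for layer in self.network.layers:
            for name, p in layer.params.items():
                g = layer.grads[name]
                m = self.m[id(layer)][name]
                v = self.v[id(layer)][name]
                m *= self.beta1
                m += (1 - self.beta1) * g
                v *= self.beta2
                v += (1 - self.beta2) * g * g
                p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _cross_entropy(probs: np.ndarray, y_onehot: np.ndarray, eps: float = 1e-12) -> float:
    return float(-np.mean(np.sum(y_onehot * np.log(np.maximum(probs, eps)), axis=1)))


def _softmax(z: np.ndarray) -> np.ndarray:
    shifted = z - z.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def train_network(
    network: Network,
    x: np.ndarray,
    y_onehot: np.ndarray,
    epochs: int,
    batch_size: int = 32,
    learning_rate: float = 1e-3,
    seed: int = 0,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> TrainingHistory:
    """Minibatch Adam training with categorical cross-entropy.

    Deterministic under (seed, data, architecture): shuffling uses its
    own generator, and all layer randomness (dropout, init) is seeded by
    the caller.
    """
    import time

    t0 = time.perf_counter()
    rng = np.random.default_rng(seed)
    opt = Adam(network, learning_rate=learning_rate)
    history = TrainingHistory()
    n = len(x)
    for _ in range(epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, yb = x[idx], y_onehot[idx]
            logits = network.forward_logits(xb, train=True)
            probs = _softmax(logits)
            losses.append(_cross_entropy(probs, yb) * len(idx))
            correct += int((probs.argmax(axis=1) == yb.argmax(axis=1)).sum())
            if learning_rate > 0:
                network.backward_from_logits((probs - yb) / len(idx))
                opt.step()
        history.train_loss.append(float(np.sum(losses) / n))
        history.train_acc.append(correct / n)
        if x_val is not None and len(x_val):
            probs = network.predict_proba(x_val)
            history.val_loss.append(_cross_entropy(probs, y_val))
            history.val_acc.append(
                float((probs.argmax(axis=1) == y_val.argmax(axis=1)).mean())
            )
    history.wall_time_s = time.perf_counter() - t0
    return history
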