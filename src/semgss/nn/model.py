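"""A sequential network container tying layers, loss and optimizer together."""

from __future__ import annotations

import numpy as np

from .layers import BatchNorm, Layer, softmax, softmax_cross_entropy
from .optim import Optimizer

__all__ = ["Network"]


class Network:
    """Plain sequential stack producing class logits.

    ``predict_proba`` applies softmax at inference (dropout off, batch-norm
    running statistics); ``train_step`` runs one forward/backward pass and an
    optimizer update and returns the batch loss.
    """

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, training=False))

    def param_pairs(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(parameter, gradient) pairs in a stable layer/key order."""
        pairs = []
        for layer in self.layers:
            params = layer.params
            grads = layer.grads
            for key in sorted(params):
                pairs.append((params[key], grads[key]))
        return pairs

    def train_step(self, x: np.ndarray, y: np.ndarray, optimizer: Optimizer) -> tuple[float, int]:
        """One forward/backward/update pass; returns (batch loss, batch hits)."""
        logits = self.forward(x, training=True)
        loss, dlogits = softmax_cross_entropy(logits, y)
        hits = int((logits.argmax(axis=1) == y).sum())
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        optimizer.step(self.param_pairs())
        return loss, hits

    def evaluate(self, x: np.ndarray, y: np.ndarray, batch_size: int = 64) -> tuple[float, float]:
        """(mean cross-entropy, accuracy) at inference settings."""
        losses, hits, n = 0.0, 0, len(y)
        for start in range(0, n, batch_size):
            xb, yb = x[start:start + batch_size], y[start:start + batch_size]
            logits = self.forward(xb, training=False)
            loss, _ = softmax_cross_entropy(logits, yb)
            losses += loss * len(yb)
            hits += int((logits.argmax(axis=1) == yb).sum())
        return losses / n, hits / n

    def get_weights(self) -> list:
        """Deep copy of all parameters and batch-norm running statistics."""
        snap = []
        for layer in self.layers:
            entry = {k: v.copy() for k, v in layer.params.items()}
            if isinstance(layer, BatchNorm):
                entry["__running_mean"] = layer.running_mean.copy()
                entry["__running_var"] = layer.running_var.copy()
            snap.append(entry)
        return snap

    def set_weights(self, snapshot: list) -> None:
        for layer, entry in zip(self.layers, snapshot):
            for k, v in entry.items():
                if k == "__running_mean":
                    layer.running_mean = v.copy()
                elif k == "__running_var":
                    layer.running_var = v.copy()
                else:
                    layer.params[k][...] = v

    def summary(self) -> list[str]:
        lines = []
        for layer in self.layers:
            n_par = sum(int(np.prod(p.shape)) for p in layer.params.values())
            lines.append(f"{type(layer).__name__:<12} params={n_par}")
        return lines
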