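"""First-order optimizers: adam, rmsprop, adadelta.

All mutate parameter arrays in place and keep per-parameter state keyed by
position, so the parameter list must be presented in a stable order.  ``lr``
is a plain attribute so a plateau schedule can lower it between epochs.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Optimizer", "Adam", "RMSprop", "Adadelta", "make_optimizer"]


class Optimizer:
    def __init__(self, lr: float) -> None:
        self.lr = lr
        self._state: dict[int, dict[str, np.ndarray]] = {}

    def _slot(self, idx: int, param: np.ndarray, names: tuple[str, ...]) -> dict[str, np.ndarray]:
        if idx not in self._state:
            self._state[idx] = {nm: np.zeros_like(param, dtype=np.float64) for nm in names}
        return self._state[idx]

    def step(self, pairs: list[tuple[np.ndarray, np.ndarray]]) -> None:
        raise NotImplementedError


class Adam(Optimizer):
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7) -> None:
        super().__init__(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, pairs):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for idx, (p, g) in enumerate(pairs):
            s = self._slot(idx, p, ("m", "v"))
            s["m"] = b1 * s["m"] + (1 - b1) * g
            s["v"] = b2 * s["v"] + (1 - b2) * g * g
            p -= (self.lr * (s["m"] / corr1) / (np.sqrt(s["v"] / corr2) + self.eps)).astype(p.dtype)


class RMSprop(Optimizer):
    def __init__(self, lr: float = 1e-3, rho: float = 0.9, eps: float = 1e-7) -> None:
        super().__init__(lr)
        self.rho, self.eps = rho, eps

    def step(self, pairs):
        for idx, (p, g) in enumerate(pairs):
            s = self._slot(idx, p, ("v",))
            s["v"] = self.rho * s["v"] + (1 - self.rho) * g * g
            p -= (self.lr * g / (np.sqrt(s["v"]) + self.eps)).astype(p.dtype)


class Adadelta(Optimizer):
    """Adadelta with an explicit learning-rate multiplier on the adapted step."""

    def __init__(self, lr: float = 1e-3, rho: float = 0.95, eps: float = 1e-7) -> None:
        super().__init__(lr)
        self.rho, self.eps = rho, eps

    def step(self, pairs):
        rho, eps = self.rho, self.eps
        for idx, (p, g) in enumerate(pairs):
            s = self._slot(idx, p, ("ag", "ad"))
            s["ag"] = rho * s["ag"] + (1 - rho) * g * g
            update = np.sqrt(s["ad"] + eps) / np.sqrt(s["ag"] + eps) * g
            s["ad"] = rho * s["ad"] + (1 - rho) * update * update
            p -= (self.lr * update).astype(p.dtype)


def make_optimizer(name: str, lr: float) -> Optimizer:
    table = {"adam": Adam, "rmsprop": RMSprop, "adadelta": Adadelta}
    if name not in table:
        raise ValueError(f"unknown optimizer {name!r}; choose from {sorted(table)}")
    return table[name](lr=lr)
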