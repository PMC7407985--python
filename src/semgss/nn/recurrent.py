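"""LSTM and bidirectional LSTM layers with backpropagation through time.

Sequences are ``(N, T, D)``.  Gate order inside the packed weight matrices is
(input, forget, cell, output); the forget-gate bias starts at 1, the usual
remedy for early forgetting.  A reversed cell consumes the sequence back to
front; the bidirectional wrapper concatenates a forward and a reversed cell
along the feature axis, time-aligned when returning full sequences, or the
two final states (each having consumed the whole sequence) otherwise.
"""

from __future__ import annotations

import numpy as np

from .layers import Layer

__all__ = ["LSTM", "BiLSTM"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class LSTM(Layer):
    """Unidirectional LSTM returning the full hidden sequence in time order."""

    def __init__(
        self,
        d_in: int,
        d_hidden: int,
        rng: np.random.Generator,
        reverse: bool = False,
        dtype=np.float32,
    ) -> None:
        super().__init__()
        self.d_in, self.d_hidden, self.reverse = d_in, d_hidden, reverse
        h = d_hidden
        b = np.zeros(4 * h, dtype=dtype)
        b[h:2 * h] = 1.0  # forget gate
        self.params = {
            "w": (rng.standard_normal((d_in, 4 * h)) / np.sqrt(d_in)).astype(dtype),
            "u": (rng.standard_normal((h, 4 * h)) / np.sqrt(h)).astype(dtype),
            "b": b,
        }

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, t_len, _ = x.shape
        h_dim = self.d_hidden
        xs = x[:, ::-1] if self.reverse else x
        w, u, b = self.params["w"], self.params["u"], self.params["b"]
        h = np.zeros((n, h_dim), dtype=x.dtype)
        c = np.zeros((n, h_dim), dtype=x.dtype)
        self._cache = []
        outs = np.empty((n, t_len, h_dim), dtype=x.dtype)
        for t in range(t_len):
            a = xs[:, t] @ w + h @ u + b
            i = _sigmoid(a[:, :h_dim])
            f = _sigmoid(a[:, h_dim:2 * h_dim])
            g = np.tanh(a[:, 2 * h_dim:3 * h_dim])
            o = _sigmoid(a[:, 3 * h_dim:])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            tanh_c = np.tanh(c)
            h = o * tanh_c
            outs[:, t] = h
            self._cache.append((xs[:, t], h_prev, c_prev, i, f, g, o, tanh_c))
        self._xs_dtype = x.dtype
        return outs[:, ::-1] if self.reverse else outs

    def backward(self, dy: np.ndarray) -> np.ndarray:
        # dy in time order; flip to processing order when reversed
        d_seq = dy[:, ::-1] if self.reverse else dy
        n, t_len, h_dim = d_seq.shape
        w, u = self.params["w"], self.params["u"]
        dw = np.zeros_like(w)
        du = np.zeros_like(u)
        db = np.zeros_like(self.params["b"])
        dxs = np.empty((n, t_len, self.d_in), dtype=dy.dtype)
        dh_next = np.zeros((n, h_dim), dtype=dy.dtype)
        dc_next = np.zeros((n, h_dim), dtype=dy.dtype)
        for t in range(t_len - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tanh_c = self._cache[t]
            dh = d_seq[:, t] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1.0 - tanh_c**2) + dc_next
            di, df, dg = dc * g, dc * c_prev, dc * i
            da = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dw += x_t.T @ da
            du += h_prev.T @ da
            db += da.sum(axis=0)
            dxs[:, t] = da @ w.T
            dh_next = da @ u.T
            dc_next = dc * f
        self.grads = {"w": dw, "u": du, "b": db}
        return dxs[:, ::-1] if self.reverse else dxs


class BiLSTM(Layer):
    """Bidirectional LSTM: forward and reversed cells, features concatenated.

    ``return_sequences=True`` yields ``(N, T, 2H)`` (time-aligned);
    ``False`` yields ``(N, 2H)``, the pair of final states — the forward
    cell's state at the last step and the reversed cell's state after its
    full pass (time index 0).
    """

    def __init__(
        self,
        d_in: int,
        d_hidden: int,
        rng: np.random.Generator,
        return_sequences: bool = True,
        dtype=np.float32,
    ) -> None:
        super().__init__()
        self.fwd = LSTM(d_in, d_hidden, rng, reverse=False, dtype=dtype)
        self.bwd = LSTM(d_in, d_hidden, rng, reverse=True, dtype=dtype)
        self.return_sequences = return_sequences
        self.d_hidden = d_hidden

    @property
    def params(self):  # type: ignore[override]
        return {f"fwd_{k}": v for k, v in self.fwd.params.items()} | {
            f"bwd_{k}": v for k, v in self.bwd.params.items()
        }

    @params.setter
    def params(self, value) -> None:
        if value:  # allow Layer.__init__'s empty-dict assignment
            for k, v in value.items():
                side, key = k.split("_", 1)
                getattr(self, side).params[key] = v

    @property
    def grads(self):  # type: ignore[override]
        return {f"fwd_{k}": v for k, v in self.fwd.grads.items()} | {
            f"bwd_{k}": v for k, v in self.bwd.grads.items()
        }

    @grads.setter
    def grads(self, value) -> None:
        pass

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        of = self.fwd.forward(x, training)
        ob = self.bwd.forward(x, training)
        self._t_len = x.shape[1]
        if self.return_sequences:
            return np.concatenate([of, ob], axis=2)
        return np.concatenate([of[:, -1], ob[:, 0]], axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        h = self.d_hidden
        if self.return_sequences:
            dof, dob = dy[:, :, :h], dy[:, :, h:]
        else:
            n = dy.shape[0]
            dof = np.zeros((n, self._t_len, h), dtype=dy.dtype)
            dob = np.zeros((n, self._t_len, h), dtype=dy.dtype)
            dof[:, -1] = dy[:, :h]
            dob[:, 0] = dy[:, h:]
        return self.fwd.backward(dof) + self.bwd.backward(dob)
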