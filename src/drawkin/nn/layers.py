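"""Feed-forward layers on (batch, time, channel) arrays.

Each layer owns its parameters and gradient buffers; ``forward`` caches what
``backward`` needs, and ``backward`` returns the input gradient while
accumulating parameter gradients in ``grads``. Convolutions and pooling use
"same" padding with stride 1 so the time axis is preserved end to end.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv1dSame", "MaxPool1dSame", "Dense", "Dropout", "sigmoid"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Parameter bookkeeping shared by all layers."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)

    @property
    def n_parameters(self) -> int:
        return sum(v.size for v in self.params.values())


def uniform_fan_in(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    """Uniform(-1/sqrt(fan_in), +1/sqrt(fan_in)) initialization."""
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Conv1dSame(Layer):
    """1D convolution, stride 1, same-length output.

    Weight shape (k, C_in, C_out); input (B, T, C_in) -> output (B, T, C_out).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        fan_in = kernel * c_in
        self.params["W"] = uniform_fan_in(rng, (kernel, c_in, c_out), fan_in)
        self.params["b"] = uniform_fan_in(rng, (c_out,), fan_in)
        self.zero_grad()
        self._windows: np.ndarray | None = None

    def _pad(self) -> tuple[int, int]:
        left = (self.kernel - 1) // 2
        return left, self.kernel - 1 - left

    def forward(self, x: np.ndarray) -> np.ndarray:
        pl, pr = self._pad()
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        # windows[b, t, c, ki] = xp[b, t + ki, c]
        win = sliding_window_view(xp, self.kernel, axis=1)
        self._windows = win
        return np.einsum("btck,kco->bto", win, self.params["W"]) + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        win = self._windows
        self.grads["W"] += np.einsum("btck,bto->kco", win, dy)
        self.grads["b"] += dy.sum(axis=(0, 1))
        B, T, _ = dy.shape
        pl, pr = self._pad()
        contrib = np.einsum("bto,kco->btck", dy, self.params["W"])
        dxp = np.zeros((B, T + self.kernel - 1, self.c_in))
        for ki in range(self.kernel):
            dxp[:, ki : ki + T, :] += contrib[:, :, :, ki]
        return dxp[:, pl : pl + T, :]


class MaxPool1dSame(Layer):
    """Stride-1 max pooling along time with same-length output."""

    def __init__(self, kernel: int = 3):
        super().__init__()
        self.kernel = kernel
        self._argmax: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        pl = (self.kernel - 1) // 2
        pr = self.kernel - 1 - pl
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)), constant_values=-np.inf)
        win = sliding_window_view(xp, self.kernel, axis=1)  # (B, T, C, k)
        self._argmax = np.argmax(win, axis=3)
        self._in_shape = x.shape
        return np.max(win, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, T, C = self._in_shape
        pl = (self.kernel - 1) // 2
        dxp = np.zeros((B, T + self.kernel - 1, C))
        for ki in range(self.kernel):
            mask = self._argmax == ki
            contrib = np.where(mask, dy, 0.0)
            dxp[:, ki : ki + T, :] += contrib
        return dxp[:, pl : pl + T, :]


class Dense(Layer):
    """Fully connected layer on (B, D_in) -> (B, D_out)."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = uniform_fan_in(rng, (d_in, d_out), d_in)
        self.params["b"] = uniform_fan_in(rng, (d_out,), d_in)
        self.zero_grad()
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] += self._x.T @ dy
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float):
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None = None) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("train-mode dropout needs an RNG")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask
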