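"""Recurrent cells with backpropagation through time.

The GRU follows the standard gated-update formulation: with the input
concatenation c_t = [h_{t-1}, x_t],

    z_t = sigmoid(W_z c_t + b_z)            (update gate)
    r_t = sigmoid(W_r c_t + b_r)            (reset gate)
    g_t = tanh(W_h [r_t*h_{t-1}, x_t] + b_h)  (candidate state)
    h_t = (1 - z_t)*h_{t-1} + z_t*g_t

Weight matrices are H x (H + C), acting on the concatenated vector, so the
free functions ``gru_step``/``bigru_forward`` expose exactly that textbook
parameterization. Tanh-RNN and LSTM cells share the same sequence API so
the recurrent encoder is swappable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import Layer, sigmoid, uniform_fan_in

__all__ = [
    "GRUParameters",
    "gru_step",
    "bigru_forward",
    "GRUCell",
    "RNNCell",
    "LSTMCell",
    "BidirectionalEncoder",
    "make_cell",
]


@dataclass
class GRUParameters:
    """Weights of one GRU direction: three H x (H+C) matrices and biases."""

    W_z: np.ndarray
    W_r: np.ndarray
    W_h: np.ndarray
    b_z: np.ndarray
    b_r: np.ndarray
    b_h: np.ndarray

    def __post_init__(self) -> None:
        H, HC = self.W_z.shape
        for name in ("W_r", "W_h"):
            if getattr(self, name).shape != (H, HC):
                raise ValueError(f"{name} shape {getattr(self, name).shape} != {(H, HC)}")
        for name in ("b_z", "b_r", "b_h"):
            if getattr(self, name).shape != (H,):
                raise ValueError(f"{name} must have shape ({H},)")
        for name in ("W_z", "W_r", "W_h", "b_z", "b_r", "b_h"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite values")

    @property
    def hidden_size(self) -> int:
        return self.W_z.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_z.shape[1] - self.W_z.shape[0]


def gru_step(p: GRUParameters, x_t: np.ndarray, h_prev: np.ndarray) -> np.ndarray:
    """One GRU update h_{t-1} -> h_t for a single input vector."""
    x_t = np.asarray(x_t, dtype=np.float64)
    h_prev = np.asarray(h_prev, dtype=np.float64)
    if x_t.shape != (p.input_size,) or h_prev.shape != (p.hidden_size,):
        raise ValueError(
            f"expected x_t ({p.input_size},) and h_prev ({p.hidden_size},), "
            f"got {x_t.shape} and {h_prev.shape}"
        )
    cat = np.concatenate([h_prev, x_t])
    z = sigmoid(p.W_z @ cat + p.b_z)
    r = sigmoid(p.W_r @ cat + p.b_r)
    cat_c = np.concatenate([r * h_prev, x_t])
    g = np.tanh(p.W_h @ cat_c + p.b_h)
    return (1.0 - z) * h_prev + z * g


def bigru_forward(p_fwd: GRUParameters, p_bwd: GRUParameters, seq: np.ndarray) -> np.ndarray:
    """Bidirectional GRU over a T x C sequence -> T x 2H hidden matrix.

    Row t concatenates the forward state after consuming steps 1..t with the
    backward state after consuming steps T..t; both directions start from
    zero states.
    """
    seq = np.asarray(seq, dtype=np.float64)
    if seq.ndim != 2:
        raise ValueError("seq must be a T x C matrix")
    T = seq.shape[0]
    if T < 1:
        raise ValueError("sequence must have at least one step")
    H = p_fwd.hidden_size
    if p_bwd.hidden_size != H:
        raise ValueError("forward/backward hidden sizes differ")
    out = np.zeros((T, 2 * H))
    h = np.zeros(H)
    for t in range(T):
        h = gru_step(p_fwd, seq[t], h)
        out[t, :H] = h
    h = np.zeros(H)
    for t in range(T - 1, -1, -1):
        h = gru_step(p_bwd, seq[t], h)
        out[t, H:] = h
    return out


class _RecurrentCell(Layer):
    """Shared init/bookkeeping for the three cell types."""

    WEIGHT_NAMES: tuple[str, ...] = ()

    def __init__(self, c_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.hidden = c_in, hidden
        fan_in = hidden + c_in
        for w in self.WEIGHT_NAMES:
            self.params[f"W_{w}"] = uniform_fan_in(rng, (hidden, fan_in), fan_in)
            self.params[f"b_{w}"] = uniform_fan_in(rng, (hidden,), fan_in)
        self.zero_grad()
        self._cache: list = []

    def forward_seq(self, x: np.ndarray) -> np.ndarray:
        """Run over (B, T, C) from a zero initial state -> (B, T, H)."""
        raise NotImplementedError

    def backward_seq(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class GRUCell(_RecurrentCell):
    WEIGHT_NAMES = ("z", "r", "h")

    def as_parameters(self) -> GRUParameters:
        p = self.params
        return GRUParameters(p["W_z"], p["W_r"], p["W_h"], p["b_z"], p["b_r"], p["b_h"])

    def forward_seq(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        H = self.hidden
        p = self.params
        h = np.zeros((B, H))
        out = np.empty((B, T, H))
        self._cache = []
        for t in range(T):
            x_t = x[:, t, :]
            cat = np.concatenate([h, x_t], axis=1)
            z = sigmoid(cat @ p["W_z"].T + p["b_z"])
            r = sigmoid(cat @ p["W_r"].T + p["b_r"])
            cat_c = np.concatenate([r * h, x_t], axis=1)
            g = np.tanh(cat_c @ p["W_h"].T + p["b_h"])
            h_new = (1.0 - z) * h + z * g
            self._cache.append((h, z, r, g, cat, cat_c))
            h = h_new
            out[:, t, :] = h
        return out

    def backward_seq(self, dout: np.ndarray) -> np.ndarray:
        B, T, H = dout.shape
        p, grads = self.params, self.grads
        dx = np.zeros((B, T, self.c_in))
        dh_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            h_prev, z, r, g, cat, cat_c = self._cache[t]
            dh = dout[:, t, :] + dh_next
            dz = dh * (g - h_prev)
            dg = dh * z
            dh_prev = dh * (1.0 - z)
            da_h = dg * (1.0 - g * g)
            grads["W_h"] += da_h.T @ cat_c
            grads["b_h"] += da_h.sum(axis=0)
            dcc = da_h @ p["W_h"]
            drh, dx_t = dcc[:, :H], dcc[:, H:].copy()
            dr = drh * h_prev
            dh_prev = dh_prev + drh * r
            da_z = dz * z * (1.0 - z)
            da_r = dr * r * (1.0 - r)
            grads["W_z"] += da_z.T @ cat
            grads["b_z"] += da_z.sum(axis=0)
            grads["W_r"] += da_r.T @ cat
            grads["b_r"] += da_r.sum(axis=0)
            dcat = da_z @ p["W_z"] + da_r @ p["W_r"]
            dh_prev = dh_prev + dcat[:, :H]
            dx_t += dcat[:, H:]
            dx[:, t, :] = dx_t
            dh_next = dh_prev
        return dx


class RNNCell(_RecurrentCell):
    """Plain tanh recurrence h_t = tanh(W [h_{t-1}, x_t] + b)."""

    WEIGHT_NAMES = ("a",)

    def forward_seq(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        p = self.params
        h = np.zeros((B, self.hidden))
        out = np.empty((B, T, self.hidden))
        self._cache = []
        for t in range(T):
            cat = np.concatenate([h, x[:, t, :]], axis=1)
            h = np.tanh(cat @ p["W_a"].T + p["b_a"])
            self._cache.append((cat, h))
            out[:, t, :] = h
        return out

    def backward_seq(self, dout: np.ndarray) -> np.ndarray:
        B, T, H = dout.shape
        p, grads = self.params, self.grads
        dx = np.zeros((B, T, self.c_in))
        dh_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            cat, h = self._cache[t]
            dh = dout[:, t, :] + dh_next
            da = dh * (1.0 - h * h)
            grads["W_a"] += da.T @ cat
            grads["b_a"] += da.sum(axis=0)
            dcat = da @ p["W_a"]
            dh_next = dcat[:, :H]
            dx[:, t, :] = dcat[:, H:]
        return dx


class LSTMCell(_RecurrentCell):
    """Standard LSTM with input/forget/output gates and tanh cell update."""

    WEIGHT_NAMES = ("i", "f", "o", "g")

    def forward_seq(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        p = self.params
        H = self.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        out = np.empty((B, T, H))
        self._cache = []
        for t in range(T):
            cat = np.concatenate([h, x[:, t, :]], axis=1)
            i = sigmoid(cat @ p["W_i"].T + p["b_i"])
            f = sigmoid(cat @ p["W_f"].T + p["b_f"])
            o = sigmoid(cat @ p["W_o"].T + p["b_o"])
            g = np.tanh(cat @ p["W_g"].T + p["b_g"])
            c_new = f * c + i * g
            h = o * np.tanh(c_new)
            self._cache.append((cat, i, f, o, g, c, c_new))
            c = c_new
            out[:, t, :] = h
        return out

    def backward_seq(self, dout: np.ndarray) -> np.ndarray:
        B, T, H = dout.shape
        p, grads = self.params, self.grads
        dx = np.zeros((B, T, self.c_in))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            cat, i, f, o, g, c_prev, c_new = self._cache[t]
            dh = dout[:, t, :] + dh_next
            tc = np.tanh(c_new)
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di, df, dg = dc * g, dc * c_prev, dc * i
            dc_next = dc * f
            da_i = di * i * (1.0 - i)
            da_f = df * f * (1.0 - f)
            da_o = do * o * (1.0 - o)
            da_g = dg * (1.0 - g * g)
            dcat = np.zeros((B, cat.shape[1]))
            for name, da in (("i", da_i), ("f", da_f), ("o", da_o), ("g", da_g)):
                grads[f"W_{name}"] += da.T @ cat
                grads[f"b_{name}"] += da.sum(axis=0)
                dcat += da @ p[f"W_{name}"]
            dh_next = dcat[:, :H]
            dx[:, t, :] = dcat[:, H:]
        return dx


_CELL_TYPES = {"rnn": RNNCell, "lstm": LSTMCell, "gru": GRUCell}


def make_cell(kind: str, c_in: int, hidden: int, rng: np.random.Generator) -> _RecurrentCell:
    kind = kind.lower()
    if kind not in _CELL_TYPES:
        raise ValueError(f"unknown recurrent cell {kind!r}; choose from {sorted(_CELL_TYPES)}")
    return _CELL_TYPES[kind](c_in, hidden, rng)


class BidirectionalEncoder(Layer):
    """Two independent cells run in opposite time directions, states concatenated."""

    def __init__(self, kind: str, c_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fwd = make_cell(kind, c_in, hidden, rng)
        self.bwd = make_cell(kind, c_in, hidden, rng)
        self.hidden = hidden

    def zero_grad(self) -> None:
        self.fwd.zero_grad()
        self.bwd.zero_grad()

    @property
    def n_parameters(self) -> int:
        return self.fwd.n_parameters + self.bwd.n_parameters

    def sublayers(self):
        return [self.fwd, self.bwd]

    def forward(self, x: np.ndarray) -> np.ndarray:
        out_f = self.fwd.forward_seq(x)
        out_b = self.bwd.forward_seq(x[:, ::-1, :])[:, ::-1, :]
        return np.concatenate([out_f, out_b], axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        H = self.hidden
        dx_f = self.fwd.backward_seq(dy[:, :, :H])
        dx_b = self.bwd.backward_seq(dy[:, ::-1, H:])[:, ::-1, :]
        return dx_f + dx_b
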