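"""The hybrid multi-branch 1D-CNN + bidirectional-recurrent classifier.

Each conv block runs four parallel branches over the (batch, time, channel)
input — 1x1, 1x3 and 1x5 convolutions (each with F filters, ReLU) and a
stride-1 1x3 max pool that passes the input channels through — concatenates
them along channels (C_out = 3F + C_in with all branches on), and adds a
learned 1x1 projection of the block input for residual fusion. All paths
preserve the time axis, so a W-sample window stays W samples deep into the
network. Block 1 uses 8 filters and block 2 uses 16 in the default
configuration.

The branch numbering used by the ablation axis is the conventional one:
Branch 1 = residual projection, Branch 2 = 1x1 conv, Branch 3 = 1x3 conv,
Branch 4 = 1x5 conv, Branch 5 = max pool.

The conv output feeds a bidirectional recurrent encoder (GRU by default,
tanh-RNN and LSTM as drop-in variants; 64 hidden units per direction), whose
full output sequence is flattened, passed through dropout (rate 0.3) and one
fully connected layer to a single logit, then a sigmoid: the per-window
probability of the PD class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

from .nn.cells import BidirectionalEncoder
from .nn.layers import Conv1dSame, Dense, Dropout, MaxPool1dSame, sigmoid

__all__ = [
    "BRANCH_NAMES",
    "ConvBlockConfig",
    "ModelConfig",
    "ConvBlock",
    "SegmentClassifierNet",
    "init_model",
    "count_parameters",
]

#: Branch index (1-based) -> branch name.
BRANCH_NAMES = {1: "residual", 2: "conv1", 3: "conv3", 4: "conv5", 5: "maxpool"}
ALL_BRANCHES = frozenset(BRANCH_NAMES.values())
_CONV_BRANCHES = (("conv1", 1), ("conv3", 3), ("conv5", 5))


@dataclass(frozen=True)
class ConvBlockConfig:
    """One multi-branch block: filter count and which branches are active."""

    filters: int
    kernel_sizes: tuple[int, int, int] = (1, 3, 5)
    pool_size: int = 3
    enabled_branches: frozenset[str] = ALL_BRANCHES

    def __post_init__(self) -> None:
        unknown = set(self.enabled_branches) - ALL_BRANCHES
        if unknown:
            raise ValueError(f"unknown branches: {sorted(unknown)}")
        if not (set(self.enabled_branches) - {"residual"}):
            raise ValueError("at least one non-residual branch must be enabled")
        if self.filters < 1:
            raise ValueError("filters must be positive")

    @property
    def residual(self) -> bool:
        return "residual" in self.enabled_branches

    def c_out(self, c_in: int) -> int:
        n_conv = sum(1 for name, _ in _CONV_BRANCHES if name in self.enabled_branches)
        pool = c_in if "maxpool" in self.enabled_branches else 0
        return n_conv * self.filters + pool


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the whole classifier.

    ``n_channels`` is the feature-set width (4, 6 or 8) and
    ``window_samples`` the segment length W; together with the conv widths
    they fix the flatten width W * 2H of the decision head.
    """

    n_channels: int
    window_samples: int = 32
    n_conv_blocks: int = 2
    block_filters: tuple[int, ...] = (8, 16, 32)
    enabled_branches: frozenset[str] = ALL_BRANCHES
    recurrent_cell: str = "gru"
    bidirectional: bool = True
    hidden_units: int = 64
    dropout_rate: float = 0.3

    def __post_init__(self) -> None:
        if self.n_conv_blocks not in (0, 1, 2, 3):
            raise ValueError("n_conv_blocks must be in {0, 1, 2, 3}")
        if len(self.block_filters) < self.n_conv_blocks:
            raise ValueError("need a filter count per conv block")
        if self.recurrent_cell.lower() not in ("rnn", "lstm", "gru"):
            raise ValueError("recurrent_cell must be one of rnn/lstm/gru")
        if not self.bidirectional:
            raise ValueError("the encoder is bidirectional by construction")
        if self.n_channels < 1 or self.window_samples < 1:
            raise ValueError("n_channels and window_samples must be positive")

    def block_configs(self) -> list[ConvBlockConfig]:
        return [
            ConvBlockConfig(filters=self.block_filters[i], enabled_branches=self.enabled_branches)
            for i in range(self.n_conv_blocks)
        ]

    def without_branch(self, branch: int | str) -> "ModelConfig":
        """Ablation helper: drop one branch (by index 1-5 or by name)."""
        name = BRANCH_NAMES[branch] if isinstance(branch, int) else branch
        if name not in ALL_BRANCHES:
            raise ValueError(f"unknown branch {branch!r}")
        return ModelConfig(
            n_channels=self.n_channels,
            window_samples=self.window_samples,
            n_conv_blocks=self.n_conv_blocks,
            block_filters=self.block_filters,
            enabled_branches=frozenset(self.enabled_branches - {name}),
            recurrent_cell=self.recurrent_cell,
            hidden_units=self.hidden_units,
            dropout_rate=self.dropout_rate,
        )

    @classmethod
    def small(cls, n_channels: int, window_samples: int = 32, **kw) -> "ModelConfig":
        """Compact desk-scale preset: one 4-filter block, 16 hidden units."""
        kw.setdefault("n_conv_blocks", 1)
        kw.setdefault("block_filters", (4,))
        kw.setdefault("hidden_units", 16)
        return cls(n_channels=n_channels, window_samples=window_samples, **kw)


class ConvBlock:
    """Parallel conv/pool branches with channel concat and residual add."""

    def __init__(self, c_in: int, cfg: ConvBlockConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.c_in = c_in
        self.c_out = cfg.c_out(c_in)
        self.convs: dict[str, Conv1dSame] = {}
        for (name, k), size in zip(_CONV_BRANCHES, cfg.kernel_sizes):
            if name in cfg.enabled_branches:
                self.convs[name] = Conv1dSame(c_in, cfg.filters, size, rng)
        self.pool = MaxPool1dSame(cfg.pool_size) if "maxpool" in cfg.enabled_branches else None
        self.proj = Conv1dSame(c_in, self.c_out, 1, rng) if cfg.residual else None
        self._relu_masks: dict[str, np.ndarray] = {}

    def layers(self) -> list:
        out = list(self.convs.values())
        if self.pool is not None:
            out.append(self.pool)
        if self.proj is not None:
            out.append(self.proj)
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        outs = []
        self._slices = []
        start = 0
        self._relu_masks = {}
        for name in ("conv1", "conv3", "conv5"):
            if name in self.convs:
                y = self.convs[name].forward(x)
                mask = y > 0
                self._relu_masks[name] = mask
                outs.append(np.where(mask, y, 0.0))
                self._slices.append((name, start, start + y.shape[2]))
                start += y.shape[2]
        if self.pool is not None:
            y = self.pool.forward(x)
            outs.append(y)
            self._slices.append(("maxpool", start, start + y.shape[2]))
            start += y.shape[2]
        out = np.concatenate(outs, axis=2)
        if self.proj is not None:
            out = out + self.proj.forward(x)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.zeros((dy.shape[0], dy.shape[1], self.c_in))
        if self.proj is not None:
            dx += self.proj.backward(dy)
        for name, a, b in self._slices:
            d = dy[:, :, a:b]
            if name == "maxpool":
                dx += self.pool.backward(d)
            else:
                dx += self.convs[name].backward(d * self._relu_masks[name])
        return dx


class SegmentClassifierNet:
    """Forward/backward network over window batches (B, W, C) -> logits (B,)."""

    def __init__(self, cfg: ModelConfig, seed: int):
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.blocks: list[ConvBlock] = []
        c = cfg.n_channels
        for bc in cfg.block_configs():
            block = ConvBlock(c, bc, rng)
            self.blocks.append(block)
            c = block.c_out
        self.encoder = BidirectionalEncoder(cfg.recurrent_cell, c, cfg.hidden_units, rng)
        self.dropout = Dropout(cfg.dropout_rate)
        flat_width = cfg.window_samples * 2 * cfg.hidden_units
        self.head = Dense(flat_width, 1, rng)

    def layers(self) -> list:
        out: list = []
        for b in self.blocks:
            out.extend(b.layers())
        out.extend(self.encoder.sublayers())
        out.append(self.dropout)
        out.append(self.head)
        return out

    @property
    def n_parameters(self) -> int:
        return sum(l.n_parameters for l in self.layers())

    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        if x.ndim != 3 or x.shape[1] != self.cfg.window_samples or x.shape[2] != self.cfg.n_channels:
            raise ValueError(
                f"expected windows (B, {self.cfg.window_samples}, {self.cfg.n_channels}), got {x.shape}"
            )
        seq = x
        for block in self.blocks:
            seq = block.forward(seq)
        h = self.encoder.forward(seq)
        flat = h.reshape(h.shape[0], -1)
        dropped = self.dropout.forward(flat, train=train, rng=rng)
        return self.head.forward(dropped)[:, 0]

    def backward(self, dlogit: np.ndarray) -> np.ndarray:
        dflat = self.dropout.backward(self.head.backward(dlogit[:, None]))
        dh = dflat.reshape(dflat.shape[0], self.cfg.window_samples, 2 * self.cfg.hidden_units)
        dseq = self.encoder.backward(dh)
        for block in reversed(self.blocks):
            dseq = block.backward(dseq)
        return dseq

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-window PD probability, eval mode (deterministic)."""
        p = sigmoid(self.forward(x, train=False))
        return np.clip(p, 1e-12, 1.0 - 1e-12)

    # -- checkpointing ----------------------------------------------------
    def _named_layers(self) -> list[tuple[str, object]]:
        named = []
        for i, b in enumerate(self.blocks):
            for name, conv in b.convs.items():
                named.append((f"block{i}.{name}", conv))
            if b.proj is not None:
                named.append((f"block{i}.residual", b.proj))
        named.append(("encoder.fwd", self.encoder.fwd))
        named.append(("encoder.bwd", self.encoder.bwd))
        named.append(("head", self.head))
        return named

    def get_weights(self) -> dict[str, np.ndarray]:
        return {
            f"{lname}/{pname}": arr.copy()
            for lname, layer in self._named_layers()
            for pname, arr in layer.params.items()
        }

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for lname, layer in self._named_layers():
            for pname in layer.params:
                key = f"{lname}/{pname}"
                arr = np.asarray(weights[key])
                if arr.shape != layer.params[pname].shape:
                    raise ValueError(f"shape mismatch for {key}")
                layer.params[pname] = arr.copy()

    def save(self, path: str | Path) -> None:
        """Portable checkpoint: YAML config next to an .npz weight bundle."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        cfg = {
            "n_channels": self.cfg.n_channels,
            "window_samples": self.cfg.window_samples,
            "n_conv_blocks": self.cfg.n_conv_blocks,
            "block_filters": list(self.cfg.block_filters),
            "enabled_branches": sorted(self.cfg.enabled_branches),
            "recurrent_cell": self.cfg.recurrent_cell,
            "hidden_units": self.cfg.hidden_units,
            "dropout_rate": self.cfg.dropout_rate,
            "seed": self.seed,
        }
        with open(path / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh)
        np.savez(path / "weights.npz", **self.get_weights())

    @classmethod
    def load(cls, path: str | Path) -> "SegmentClassifierNet":
        path = Path(path)
        with open(path / "config.yaml") as fh:
            raw = yaml.safe_load(fh)
        cfg = ModelConfig(
            n_channels=raw["n_channels"],
            window_samples=raw["window_samples"],
            n_conv_blocks=raw["n_conv_blocks"],
            block_filters=tuple(raw["block_filters"]),
            enabled_branches=frozenset(raw["enabled_branches"]),
            recurrent_cell=raw["recurrent_cell"],
            hidden_units=raw["hidden_units"],
            dropout_rate=raw["dropout_rate"],
        )
        net = cls(cfg, seed=raw.get("seed", 0))
        with np.load(path / "weights.npz") as data:
            net.set_weights({k: data[k] for k in data.files})
        return net


def init_model(cfg: ModelConfig, seed: int) -> SegmentClassifierNet:
    """Deterministically initialized network (uniform fan-in scheme)."""
    return SegmentClassifierNet(cfg, seed)


def count_parameters(cfg: ModelConfig) -> int:
    """Closed-form parameter count as a pure function of the config."""
    total = 0
    c = cfg.n_channels
    for bc in cfg.block_configs():
        for (name, _), k in zip(_CONV_BRANCHES, bc.kernel_sizes):
            if name in bc.enabled_branches:
                total += k * c * bc.filters + bc.filters
        c_out = bc.c_out(c)
        if bc.residual:
            total += 1 * c * c_out + c_out
        c = c_out
    n_gates = {"rnn": 1, "lstm": 4, "gru": 3}[cfg.recurrent_cell.lower()]
    per_dir = n_gates * (cfg.hidden_units * (cfg.hidden_units + c) + cfg.hidden_units)
    total += 2 * per_dir
    flat = cfg.window_samples * 2 * cfg.hidden_units
    total += flat * 1 + 1
    return total
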