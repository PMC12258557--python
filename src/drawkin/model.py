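"""Model/Results interface for the segment classifier.

``HybridDrawingClassifier`` is built from training data (a stack of
fixed-length kinematic windows plus binary subject labels) and a
``ModelConfig``; ``fit`` runs mini-batch Adam on binary cross-entropy and
returns a ``ClassifierResults`` carrying the trained weights, the loss
trace, prediction methods and a ``summary()`` table, in the spirit of the
classic model/results split of statistical modelling packages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .architecture import ModelConfig, SegmentClassifierNet, count_parameters, init_model
from .nn.layers import sigmoid
from .nn.optim import Adam
from .preprocess import FeatureSet, SegmentationConfig, preprocess_recording
from .records import DrawingRecording, Label

__all__ = ["TrainConfig", "HybridDrawingClassifier", "ClassifierResults"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings: Adam, lr 0.001, batch size 4, BCE loss.

    ``epochs`` defaults to 60; ``early_stop_patience`` (optional) stops when
    the training loss has not improved for that many epochs.
    """

    learning_rate: float = 0.001
    batch_size: int = 4
    epochs: int = 60
    seed: int = 0
    early_stop_patience: Optional[int] = None
    early_stop_tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("learning_rate, batch_size and epochs must be positive")
        if self.early_stop_patience is not None and self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1 when set")


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


class HybridDrawingClassifier:
    """Window-level PD/HC classifier model.

    Parameters
    ----------
    windows : (N, W, C) array
        Training segments after the preprocessing pipeline.
    labels : (N,) array of {0, 1}
        Segment labels inherited from the subject (1 = PD).
    config : ModelConfig
        Architecture hyperparameters; its window/channel sizes must match
        the data.
    """

    def __init__(self, windows: np.ndarray, labels: np.ndarray, config: ModelConfig):
        windows = np.asarray(windows, dtype=np.float64)
        labels = np.asarray(labels, dtype=np.float64)
        if windows.ndim != 3:
            raise ValueError("windows must be (N, W, C)")
        if labels.shape != (windows.shape[0],):
            raise ValueError("labels must be one per window")
        if not np.all(np.isin(labels, (0.0, 1.0))):
            raise ValueError("labels must be binary 0/1")
        if np.unique(labels).size < 2:
            raise ValueError("training data must contain both classes")
        if windows.shape[1] != config.window_samples or windows.shape[2] != config.n_channels:
            raise ValueError(
                f"windows {windows.shape[1:]} do not match config "
                f"({config.window_samples}, {config.n_channels})"
            )
        self.windows = windows
        self.labels = labels
        self.config = config

    @classmethod
    def from_recordings(
        cls,
        recordings: list[DrawingRecording],
        config: ModelConfig,
        feature_set: FeatureSet | str = FeatureSet.ALL,
        seg: SegmentationConfig | None = None,
    ) -> "HybridDrawingClassifier":
        """Build training windows from labeled recordings (segment labels
        inherit the subject label)."""
        seg = seg or SegmentationConfig(window_samples=config.window_samples)
        stacks, labels = [], []
        for rec in recordings:
            if rec.label is None:
                raise ValueError(f"recording {rec.subject_id!r} has no label")
            batch = preprocess_recording(rec, feature_set=feature_set, seg=seg)
            stacks.append(batch.windows)
            labels.append(np.full(batch.n_windows, 1.0 if rec.label is Label.PD else 0.0))
        return cls(np.concatenate(stacks), np.concatenate(labels), config)

    def fit(self, train_config: TrainConfig | None = None, init_seed: int | None = None) -> "ClassifierResults":
        """Mini-batch Adam on binary cross-entropy; reproducible given seeds."""
        tc = train_config or TrainConfig()
        net = init_model(self.config, seed=tc.seed if init_seed is None else init_seed)
        rng = np.random.default_rng(np.random.SeedSequence((tc.seed, 0xD12A)))
        opt = Adam(net.layers(), lr=tc.learning_rate)
        N = self.windows.shape[0]
        loss_history: list[float] = []
        best, since_best = np.inf, 0
        for _epoch in range(tc.epochs):
            perm = rng.permutation(N)
            total, seen = 0.0, 0
            for start in range(0, N, tc.batch_size):
                idx = perm[start : start + tc.batch_size]
                xb, yb = self.windows[idx], self.labels[idx]
                logits = net.forward(xb, train=True, rng=rng)
                p = sigmoid(logits)
                loss = _bce(p, yb)
                opt.zero_grad()
                net.backward((p - yb) / xb.shape[0])
                opt.step()
                total += loss * xb.shape[0]
                seen += xb.shape[0]
            epoch_loss = total / seen
            loss_history.append(epoch_loss)
            if tc.early_stop_patience is not None:
                if epoch_loss < best - tc.early_stop_tol:
                    best, since_best = epoch_loss, 0
                else:
                    since_best += 1
                    if since_best >= tc.early_stop_patience:
                        break
        return ClassifierResults(model=self, net=net, train_config=tc, loss_history=np.array(loss_history))


@dataclass
class ClassifierResults:
    """Fitted classifier: weights, optimization trace, prediction methods."""

    model: HybridDrawingClassifier
    net: SegmentClassifierNet
    train_config: TrainConfig
    loss_history: np.ndarray

    @property
    def n_parameters(self) -> int:
        return self.net.n_parameters

    @property
    def final_loss(self) -> float:
        return float(self.loss_history[-1])

    def predict_window_proba(self, windows: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Per-window PD probability in eval mode (dropout off, deterministic)."""
        windows = np.asarray(windows, dtype=np.float64)
        out = [
            self.net.predict_proba(windows[i : i + batch_size])
            for i in range(0, windows.shape[0], batch_size)
        ]
        return np.concatenate(out) if out else np.empty(0)

    def predict_recording_proba(
        self,
        rec: DrawingRecording,
        feature_set: FeatureSet | str,
        seg: SegmentationConfig | None = None,
    ) -> float:
        """Recording-level probability: the mean over its window probabilities."""
        seg = seg or SegmentationConfig(window_samples=self.model.config.window_samples)
        batch = preprocess_recording(rec, feature_set=feature_set, seg=seg)
        probs = self.predict_window_proba(batch.windows)
        return float(np.mean(probs))

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Hybrid 1D-CNN + Bi%s segment classifier" % cfg.recurrent_cell.upper(),
            "=" * 46,
            f"windows (train):       {self.model.windows.shape[0]}",
            f"window length W:       {cfg.window_samples}",
            f"input channels C:      {cfg.n_channels}",
            f"conv blocks:           {cfg.n_conv_blocks} "
            f"(filters {cfg.block_filters[:cfg.n_conv_blocks]})",
            f"branches:              {', '.join(sorted(cfg.enabled_branches))}",
            f"hidden units/dir:      {cfg.hidden_units}",
            f"dropout:               {cfg.dropout_rate}",
            f"parameters:            {self.n_parameters} "
            f"(closed form {count_parameters(cfg)})",
            f"optimizer:             Adam(lr={self.train_config.learning_rate}, "
            f"batch={self.train_config.batch_size})",
            f"epochs run:            {len(self.loss_history)}",
            f"final training BCE:    {self.final_loss:.4f}",
        ]
        return "\n".join(lines)

    def plot_loss(self, ax=None):
        """Training-loss trace (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(np.arange(1, len(self.loss_history) + 1), self.loss_history)
        ax.set_xlabel("epoch")
        ax.set_ylabel("training BCE")
        return ax
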