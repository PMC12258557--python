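"""Four-stage kinematic preprocessing.

1. Derivation — acceleration a = dv/dt and jerk j = da/dt by first
   differences over the recorded (possibly jittered) timestamps, giving the
   8-channel matrix (x, y, vx, vy, ax, ay, jx, jy).
2. Standardization — per-column z-score (population SD), by default within
   each recording so absolute scale and device geometry drop out.
3. Segmentation — sliding windows of W samples (default 32, i.e. 0.53 s at
   60 Hz) with 75% overlap.
4. Padding — the trailing partial window is zero-padded to length W.

Also provided: the named feature subsets used in task-specific ablations,
and a linear-interpolation resampler that maps higher-rate external signals
(e.g. 1000 Hz pen accelerometry) onto the 60 Hz grid, with an adapter that
builds the (ax, ay, jx, jy) feature block from raw accelerations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .records import DrawingRecording

__all__ = [
    "KINEMATIC_COLUMNS",
    "KinematicMatrix",
    "FeatureSet",
    "SegmentationConfig",
    "SegmentBatch",
    "derive_kinematics",
    "zscore_normalize",
    "select_features",
    "segment_windows",
    "n_windows",
    "resample_uniform",
    "acceleration_features_from_external",
    "preprocess_recording",
]

KINEMATIC_COLUMNS = ("x", "y", "vx", "vy", "ax", "ay", "jx", "jy")


class FeatureSet(str, Enum):
    """Named channel subsets of the 8-dim kinematic vector.

    The labels follow the task-ablation naming convention:
    coordinate = (x, y), velocity = (vx, vy), acceleration = (ax, ay),
    jerk = (jx, jy).
    """

    COORDINATE_VELOCITY = "coordinate_velocity"
    ALL = "all"
    VELOCITY_ACCELERATION_JERK = "velocity_acceleration_jerk"
    ACCELERATION_JERK = "acceleration_jerk"
    VELOCITY_ACCELERATION = "velocity_acceleration"
    COORDINATE_VELOCITY_ACCELERATION = "coordinate_velocity_acceleration"

    @property
    def columns(self) -> tuple[str, ...]:
        return _FEATURE_SET_COLUMNS[self]

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(KINEMATIC_COLUMNS.index(c) for c in self.columns)

    @property
    def n_channels(self) -> int:
        return len(self.columns)


_FEATURE_SET_COLUMNS: dict[FeatureSet, tuple[str, ...]] = {
    FeatureSet.COORDINATE_VELOCITY: ("x", "y", "vx", "vy"),
    FeatureSet.ALL: KINEMATIC_COLUMNS,
    FeatureSet.VELOCITY_ACCELERATION_JERK: ("vx", "vy", "ax", "ay", "jx", "jy"),
    FeatureSet.ACCELERATION_JERK: ("ax", "ay", "jx", "jy"),
    FeatureSet.VELOCITY_ACCELERATION: ("vx", "vy", "ax", "ay"),
    FeatureSet.COORDINATE_VELOCITY_ACCELERATION: ("x", "y", "vx", "vy", "ax", "ay"),
}


@dataclass
class KinematicMatrix:
    """T x 8 feature matrix in the fixed column order ``KINEMATIC_COLUMNS``."""

    values: np.ndarray
    recording_id: str
    timestamps_ms: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != 8:
            raise ValueError(f"kinematic matrix must be T x 8, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("kinematic matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return int(self.values.shape[0])


def _dt_seconds(timestamps_ms: np.ndarray, nominal_hz: float = 60.0) -> np.ndarray:
    """Per-step dt in seconds from integer-ms timestamps.

    Millisecond quantization can produce repeated timestamps; zero steps fall
    back to the nominal sampling interval so difference quotients stay finite.
    """
    dt = np.diff(np.asarray(timestamps_ms, dtype=np.float64)) / 1000.0
    if np.any(dt < 0):
        idx = int(np.argmax(dt < 0))
        raise ValueError(f"timestamps decrease at index {idx + 1}")
    dt[dt == 0.0] = 1.0 / nominal_hz
    return dt


def derive_kinematics(rec: DrawingRecording) -> KinematicMatrix:
    """Build the 8-channel matrix, deriving acceleration and jerk.

    a[t] = (v[t] - v[t-1]) / dt[t] with a[0] = 0, per axis; jerk identically
    from acceleration. The leading zeros keep every derivative column at
    length T.
    """
    dt = _dt_seconds(rec.timestamps_ms, rec.sampling_hz_nominal)

    def diffq(sig: np.ndarray) -> np.ndarray:
        out = np.zeros_like(sig)
        out[1:] = np.diff(sig) / dt
        return out

    ax, ay = diffq(rec.vx), diffq(rec.vy)
    jx, jy = diffq(ax), diffq(ay)
    values = np.column_stack([rec.x_px, rec.y_px, rec.vx, rec.vy, ax, ay, jx, jy])
    return KinematicMatrix(values=values, recording_id=rec.subject_id + ":" + rec.task.value, timestamps_ms=rec.timestamps_ms)


def zscore_normalize(mat: np.ndarray, mean: np.ndarray | None = None, std: np.ndarray | None = None) -> np.ndarray:
    """Column-wise z-score with population (divide-by-N) SD.

    By default the statistics come from ``mat`` itself (per-recording scope).
    Passing precomputed ``mean``/``std`` standardizes against an external
    scope, e.g. statistics pooled over a training fold. Zero-variance columns
    map to all zeros.
    """
    mat = np.asarray(mat, dtype=np.float64)
    if mat.shape[0] < 2:
        raise ValueError("z-score needs at least 2 samples")
    if mean is None:
        mean = mat.mean(axis=0)
    if std is None:
        std = mat.std(axis=0)  # population SD
    std = np.asarray(std, dtype=np.float64)
    safe = np.where(std > 0, std, 1.0)
    out = (mat - mean) / safe
    out[:, std == 0] = 0.0
    return out


def select_features(mat: KinematicMatrix | np.ndarray, fs: FeatureSet | str) -> np.ndarray:
    """Restrict the 8-column matrix to a named subset, canonical order kept."""
    fs = FeatureSet(fs)
    values = mat.values if isinstance(mat, KinematicMatrix) else np.asarray(mat)
    if values.shape[1] != 8:
        raise ValueError(f"expected 8 columns, got {values.shape[1]}")
    return values[:, list(fs.indices)]


@dataclass(frozen=True)
class SegmentationConfig:
    """Sliding-window parameters: W samples, fractional overlap.

    The stride s = W * (1 - overlap) must be a positive integer; the default
    (32, 0.75) gives stride 8, i.e. windows of 0.53 s at 60 Hz advancing by
    0.13 s.
    """

    window_samples: int = 32
    overlap_fraction: float = 0.75

    def __post_init__(self) -> None:
        if self.window_samples < 1:
            raise ValueError("window_samples must be positive")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must be in [0, 1)")
        stride = self.window_samples * (1.0 - self.overlap_fraction)
        if abs(stride - round(stride)) > 1e-9 or round(stride) < 1:
            raise ValueError(
                f"stride W*(1-overlap) = {stride} is not a positive integer"
            )

    @property
    def stride(self) -> int:
        return int(round(self.window_samples * (1.0 - self.overlap_fraction)))


@dataclass
class SegmentBatch:
    """K fixed-length windows cut from one recording's feature matrix.

    ``pad_counts[k]`` is the number of zero rows appended to window k; only
    the final window may be padded.
    """

    windows: np.ndarray  # K x W x C
    pad_counts: np.ndarray  # K
    recording_id: str = ""
    feature_set: FeatureSet | None = None

    @property
    def n_windows(self) -> int:
        return int(self.windows.shape[0])


def n_windows(n_samples: int, cfg: SegmentationConfig) -> int:
    """Number of stride-s windows covering T samples: 1 + ceil(max(T-W,0)/s)."""
    if n_samples < 1:
        raise ValueError("need at least one sample")
    extra = max(n_samples - cfg.window_samples, 0)
    return 1 + int(np.ceil(extra / cfg.stride))


def segment_windows(
    mat: np.ndarray,
    cfg: SegmentationConfig = SegmentationConfig(),
    recording_id: str = "",
    feature_set: FeatureSet | None = None,
) -> SegmentBatch:
    """Cut a T x C matrix into half-open windows [k*s, k*s + W), zero-padded.

    Window starts are 0, s, 2s, ...; every input row is covered by at least
    one window and only the final window may extend past T (its tail is
    zero-filled).
    """
    mat = np.asarray(mat, dtype=np.float64)
    if mat.ndim != 2 or mat.shape[0] < 1:
        raise ValueError("expected a T x C matrix with T >= 1")
    T, C = mat.shape
    W, s = cfg.window_samples, cfg.stride
    K = n_windows(T, cfg)
    windows = np.zeros((K, W, C), dtype=np.float64)
    pad_counts = np.zeros(K, dtype=np.int64)
    for k in range(K):
        start = k * s
        stop = min(start + W, T)
        windows[k, : stop - start] = mat[start:stop]
        pad_counts[k] = W - (stop - start)
    return SegmentBatch(windows=windows, pad_counts=pad_counts, recording_id=recording_id, feature_set=feature_set)


def resample_uniform(seq: np.ndarray, src_hz: float, dst_hz: float = 60.0) -> np.ndarray:
    """Linear interpolation of an N x C (or N,) signal onto a uniform grid.

    The output grid spans the original time extent; its length is
    floor((N-1) * dst_hz / src_hz) + 1. Constant signals are preserved
    exactly.
    """
    if src_hz <= 0 or dst_hz <= 0:
        raise ValueError("sampling rates must be positive")
    seq = np.asarray(seq, dtype=np.float64)
    squeeze = seq.ndim == 1
    if squeeze:
        seq = seq[:, None]
    if seq.shape[0] < 2:
        raise ValueError("need at least 2 samples to resample")
    if not np.all(np.isfinite(seq)):
        raise ValueError("non-finite input")
    n = seq.shape[0]
    t_src = np.arange(n) / src_hz
    m = int(np.floor((n - 1) * dst_hz / src_hz)) + 1
    t_dst = np.arange(m) / dst_hz
    out = np.column_stack([np.interp(t_dst, t_src, seq[:, c]) for c in range(seq.shape[1])])
    return out[:, 0] if squeeze else out


def acceleration_features_from_external(
    ax: np.ndarray, ay: np.ndarray, src_hz: float, dst_hz: float = 60.0
) -> np.ndarray:
    """Align external x/y accelerations with the acceleration+jerk feature set.

    Resamples the two acceleration channels to the target rate, then derives
    jerk as their first difference quotient on the resampled grid (leading
    zero keeps length), returning a T x 4 matrix (ax, ay, jx, jy) ready for
    standardization and segmentation.
    """
    acc = resample_uniform(np.column_stack([ax, ay]), src_hz, dst_hz)
    dt = 1.0 / dst_hz
    jerk = np.zeros_like(acc)
    jerk[1:] = np.diff(acc, axis=0) / dt
    return np.column_stack([acc, jerk])


def preprocess_recording(
    rec: DrawingRecording,
    feature_set: FeatureSet | str = FeatureSet.ALL,
    seg: SegmentationConfig = SegmentationConfig(),
    zscore_stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> SegmentBatch:
    """Full pipeline: derive -> z-score -> select -> segment.

    ``zscore_stats``, if given, are (mean, std) over the full 8-column space
    for an external standardization scope; default is per-recording.
    """
    fs = FeatureSet(feature_set)
    kin = derive_kinematics(rec)
    if zscore_stats is None:
        normed = zscore_normalize(kin.values)
    else:
        normed = zscore_normalize(kin.values, mean=zscore_stats[0], std=zscore_stats[1])
    selected = normed[:, list(fs.indices)]
    return segment_windows(selected, seg, recording_id=kin.recording_id, feature_set=fs)
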