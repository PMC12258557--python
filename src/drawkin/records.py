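"""Canonical types and file I/O for finger-drawing recordings.

A recording is one subject performing one drawing task (Archimedean spiral
or two-period sine wave) on a touchscreen: integer-millisecond timestamps,
touch coordinates in the screen's native pixel frame (origin top-left, y
down), and instantaneous velocity components, nominally sampled at 60 Hz.

On disk a recording is a plain CSV with header ``t_ms,x_px,y_px,vx,vy``;
cohorts are described by a JSON manifest mapping each subject to its label
and its per-task recording files. Labels live in the manifest, not in the
recording file, so unlabeled inference reuses the same reader.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Task",
    "Label",
    "DrawingRecording",
    "CohortManifest",
    "ManifestEntry",
    "Violation",
    "validate_recording",
    "read_recording",
    "write_recording",
    "load_cohort",
    "RECORDING_COLUMNS",
]

RECORDING_COLUMNS = ("t_ms", "x_px", "y_px", "vx", "vy")

#: Native pixel frame of the capture device (portrait width x height).
SCREEN_RESOLUTION_PX = (1080, 2340)


class Task(str, Enum):
    SPIRAL = "spiral"
    WAVE = "wave"


class Label(str, Enum):
    PD = "PD"
    HC = "HC"


class RecordingParseError(ValueError):
    """Raised when a recording file does not match the canonical dialect."""


class ManifestError(ValueError):
    """Raised for malformed or unresolvable cohort manifests."""


@dataclass
class DrawingRecording:
    """One subject x task kinematic trace.

    All five channel arrays share length ``T >= 2``. Timestamps are integer
    milliseconds and non-decreasing (60 Hz capture quantized to ms yields
    alternating 16/17 ms steps). Velocities are in pixels/second.
    """

    subject_id: str
    task: Task
    timestamps_ms: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    label: Optional[Label] = None
    sampling_hz_nominal: float = 60.0

    def __post_init__(self) -> None:
        self.task = Task(self.task)
        if self.label is not None:
            self.label = Label(self.label)
        self.timestamps_ms = np.asarray(self.timestamps_ms, dtype=np.int64)
        for name in ("x_px", "y_px", "vx", "vy"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))

    @property
    def n_samples(self) -> int:
        return int(self.timestamps_ms.shape[0])

    @property
    def duration_s(self) -> float:
        """Elapsed time from first to last sample, in seconds."""
        return float(self.timestamps_ms[-1] - self.timestamps_ms[0]) / 1000.0

    def coordinates(self) -> np.ndarray:
        """T x 2 array of (x, y) pixel coordinates."""
        return np.column_stack([self.x_px, self.y_px])

    def with_label(self, label: Optional[Label]) -> "DrawingRecording":
        return replace(self, label=label)


@dataclass(frozen=True)
class Violation:
    """One broken recording invariant: which field, which rule."""

    field: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}: {self.rule}"


def validate_recording(rec: DrawingRecording) -> list[Violation]:
    """Check every recording invariant; return the violations (empty = valid).

    Violations are returned rather than raised so callers can report all
    problems in a file at once.
    """
    out: list[Violation] = []
    lengths = {
        name: getattr(rec, name).shape[0]
        for name in ("timestamps_ms", "x_px", "y_px", "vx", "vy")
    }
    if len(set(lengths.values())) > 1:
        detail = ", ".join(f"{k}={v}" for k, v in lengths.items())
        out.append(Violation("channels", f"length mismatch ({detail})"))
        return out  # remaining checks assume aligned channels
    t = rec.timestamps_ms
    if t.shape[0] < 2:
        out.append(Violation("timestamps_ms", f"need at least 2 samples, got {t.shape[0]}"))
    if t.shape[0] >= 2 and np.any(np.diff(t) < 0):
        idx = int(np.argmax(np.diff(t) < 0))
        out.append(Violation("timestamps_ms", f"not non-decreasing at index {idx + 1}"))
    for name in ("x_px", "y_px"):
        if not np.all(np.isfinite(getattr(rec, name))):
            out.append(Violation(name, "non-finite coordinate"))
    for name in ("vx", "vy"):
        if not np.all(np.isfinite(getattr(rec, name))):
            out.append(Violation(name, "non-finite velocity"))
    return out


def write_recording(rec: DrawingRecording, path: str | Path) -> Path:
    """Write the canonical recording CSV (header ``t_ms,x_px,y_px,vx,vy``)."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "t_ms": rec.timestamps_ms,
            "x_px": rec.x_px,
            "y_px": rec.y_px,
            "vx": rec.vx,
            "vy": rec.vy,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_recording(
    path: str | Path,
    subject_id: str | None = None,
    task: Task | str = Task.SPIRAL,
    label: Label | str | None = None,
    dialect: str = "canonical",
    column_map: dict[str, str] | None = None,
) -> DrawingRecording:
    """Read a recording CSV.

    ``dialect="canonical"`` expects exactly the canonical header. The
    ``"mapped"`` dialect accepts arbitrary column names via ``column_map``
    (canonical name -> file column), for importing third-party layouts whose
    internal naming varies.
    """
    path = Path(path)
    if not path.exists():
        raise RecordingParseError(f"recording file not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise RecordingParseError(f"cannot parse {path}: {exc}") from exc

    if dialect == "canonical":
        mapping = {c: c for c in RECORDING_COLUMNS}
    elif dialect == "mapped":
        if column_map is None:
            raise RecordingParseError("dialect='mapped' requires a column_map")
        mapping = {canon: column_map.get(canon, canon) for canon in RECORDING_COLUMNS}
    else:
        raise RecordingParseError(f"unknown dialect {dialect!r}")

    for canon, col in mapping.items():
        if col not in df.columns:
            raise RecordingParseError(f"missing required column {canon!r} (expected {col!r}) in {path}")

    cols = {}
    for canon, col in mapping.items():
        series = pd.to_numeric(df[col], errors="coerce")
        bad = series.isna() & df[col].notna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise RecordingParseError(f"non-numeric cell in column {col!r} at data row {row} of {path}")
        if series.isna().any():
            row = int(np.argmax(series.isna().to_numpy()))
            raise RecordingParseError(f"empty cell in column {col!r} at data row {row} of {path}")
        cols[canon] = series.to_numpy()

    rec = DrawingRecording(
        subject_id=subject_id if subject_id is not None else path.stem,
        task=Task(task),
        label=None if label is None else Label(label),
        timestamps_ms=np.asarray(cols["t_ms"]),
        x_px=cols["x_px"],
        y_px=cols["y_px"],
        vx=cols["vx"],
        vy=cols["vy"],
    )
    violations = validate_recording(rec)
    if violations:
        msgs = "; ".join(str(v) for v in violations)
        raise RecordingParseError(f"invalid recording {path}: {msgs}")
    return rec


@dataclass(frozen=True)
class ManifestEntry:
    subject_id: str
    label: Optional[Label]
    spiral: Optional[str]
    wave: Optional[str]


@dataclass
class CohortManifest:
    """Cohort index: one entry per subject with label and per-task file paths."""

    entries: list[ManifestEntry]
    provenance: str = ""
    seed: Optional[int] = None
    root: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        ids = [e.subject_id for e in self.entries]
        dupes = {s for s in ids if ids.count(s) > 1}
        if dupes:
            raise ManifestError(f"duplicate subject_id values: {sorted(dupes)}")

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortManifest":
        path = Path(path)
        with open(path) as fh:
            payload = json.load(fh)
        if isinstance(payload, dict):
            raw_entries = payload["subjects"]
            provenance = payload.get("provenance", "")
            seed = payload.get("seed")
        else:
            raw_entries, provenance, seed = payload, "", None
        entries = [
            ManifestEntry(
                subject_id=str(e["subject_id"]),
                label=None if e.get("label") is None else Label(e["label"]),
                spiral=e.get("spiral"),
                wave=e.get("wave"),
            )
            for e in raw_entries
        ]
        return cls(entries=entries, provenance=provenance, seed=seed, root=path.parent)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "provenance": self.provenance,
            "seed": self.seed,
            "subjects": [
                {
                    "subject_id": e.subject_id,
                    "label": None if e.label is None else e.label.value,
                    "spiral": e.spiral,
                    "wave": e.wave,
                }
                for e in self.entries
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        return path


@dataclass(frozen=True)
class CohortSubject:
    subject_id: str
    label: Optional[Label]
    spiral: Optional[DrawingRecording]
    wave: Optional[DrawingRecording]


def load_cohort(
    manifest: str | Path | CohortManifest,
    strict: bool = True,
) -> list[CohortSubject]:
    """Load every subject's spiral and wave recording named by a manifest.

    With ``strict=True`` a subject with a missing task file is an error;
    otherwise such subjects are dropped (and the caller can inspect the
    manifest to see who).
    """
    if not isinstance(manifest, CohortManifest):
        manifest = CohortManifest.from_json(manifest)
    subjects: list[CohortSubject] = []
    for entry in manifest.entries:
        recs: dict[str, Optional[DrawingRecording]] = {}
        missing = []
        for task in (Task.SPIRAL, Task.WAVE):
            rel = getattr(entry, task.value)
            if rel is None:
                recs[task.value] = None
                missing.append(task.value)
                continue
            path = manifest.root / rel
            if not path.exists():
                raise ManifestError(
                    f"subject {entry.subject_id!r}: unresolvable path {path}"
                )
            recs[task.value] = read_recording(
                path, subject_id=entry.subject_id, task=task, label=entry.label
            )
        if missing:
            if strict:
                raise ManifestError(
                    f"subject {entry.subject_id!r} missing task(s): {missing}"
                )
            continue
        subjects.append(
            CohortSubject(
                subject_id=entry.subject_id,
                label=entry.label,
                spiral=recs["spiral"],
                wave=recs["wave"],
            )
        )
    return subjects
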