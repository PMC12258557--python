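"""Reductions over cohort side-data: demographics and completion times.

These helpers summarize a cohort the way a study table would — per-task
completion-time means/SDs per group and combined, with the observed min and
max — and count distinct subjects in a demographics spreadsheet. They
operate on any loaded cohort, including cohorts imported from third-party
layouts via the column-mapped importer below.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .records import CohortSubject, Label, Task, read_recording

__all__ = [
    "cohort_completion_times",
    "summarize_completion_times",
    "distinct_subject_count",
    "import_mapped_cohort",
]


def cohort_completion_times(subjects: list[CohortSubject]) -> pd.DataFrame:
    """Long table (subject_id, label, task, duration_s) from recordings."""
    rows = []
    for s in subjects:
        for task in (Task.SPIRAL, Task.WAVE):
            rec = getattr(s, task.value)
            if rec is None:
                continue
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "label": None if s.label is None else s.label.value,
                    "task": task.value,
                    "duration_s": rec.duration_s,
                }
            )
    return pd.DataFrame(rows)


def summarize_completion_times(times: pd.DataFrame) -> pd.DataFrame:
    """Per-task completion-time table: group and combined mean/SD, min, max."""
    out = []
    for task, grp in times.groupby("task"):
        row = {"task": task}
        for label, sub in grp.groupby("label"):
            row[f"{label}_mean_s"] = float(sub["duration_s"].mean())
            row[f"{label}_sd_s"] = float(sub["duration_s"].std(ddof=1))
        row["combined_mean_s"] = float(grp["duration_s"].mean())
        row["combined_sd_s"] = float(grp["duration_s"].std(ddof=1))
        row["min_s"] = float(grp["duration_s"].min())
        row["max_s"] = float(grp["duration_s"].max())
        out.append(row)
    return pd.DataFrame(out).set_index("task")


def distinct_subject_count(demographics_path: str | Path, subject_column: str | None = None) -> int:
    """Number of distinct subjects in a demographics spreadsheet (XLSX/CSV).

    Defaults to the first column when no subject column is named.
    """
    demographics_path = Path(demographics_path)
    if demographics_path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(demographics_path)
    else:
        df = pd.read_csv(demographics_path)
    col = subject_column or df.columns[0]
    if col not in df.columns:
        raise ValueError(f"column {col!r} not in {list(df.columns)}")
    return int(df[col].dropna().nunique())


def import_mapped_cohort(config_path: str | Path) -> list[CohortSubject]:
    """Import a cohort whose files use arbitrary column names.

    The YAML config names the root directory, a canonical->actual column
    mapping, and one entry per subject (id, label, per-task relative path),
    tolerating third-party layouts whose internal naming varies::

        root: .
        columns: {t_ms: time, x_px: X, y_px: Y, vx: VX, vy: VY}
        subjects:
          - {subject_id: P01, label: PD, spiral: p01_sp.csv, wave: p01_wv.csv}
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    root = (config_path.parent / cfg.get("root", ".")).resolve()
    column_map = cfg.get("columns", {})
    subjects = []
    for entry in cfg["subjects"]:
        recs = {}
        for task in (Task.SPIRAL, Task.WAVE):
            rel = entry.get(task.value)
            recs[task.value] = (
                None
                if rel is None
                else read_recording(
                    root / rel,
                    subject_id=str(entry["subject_id"]),
                    task=task,
                    label=entry.get("label"),
                    dialect="mapped",
                    column_map=column_map,
                )
            )
        subjects.append(
            CohortSubject(
                subject_id=str(entry["subject_id"]),
                label=None if entry.get("label") is None else Label(entry["label"]),
                spiral=recs["spiral"],
                wave=recs["wave"],
            )
        )
    ids = [s.subject_id for s in subjects]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids in import config")
    return subjects
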