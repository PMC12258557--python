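"""Training protocol and evaluation.

Validation follows the subject-confined design: subjects are partitioned by
stratified k-fold (default 10) *before* window extraction, so every window
of a subject lives in exactly one fold and no identity leaks between
training and validation. Per recording, the trained segment classifier's
window probabilities are averaged into one probability; a value strictly
greater than 0.5 is called PD. Dual-task fusion averages the spiral-model
and wave-model probabilities per subject. The protocol is repeated with
re-randomized folds and metrics are reported as mean +/- SD across
repetitions with a normal-approximation 95% CI on the headline accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .architecture import BRANCH_NAMES, ModelConfig
from .model import ClassifierResults, HybridDrawingClassifier, TrainConfig
from .preprocess import FeatureSet, SegmentationConfig, preprocess_recording
from .records import CohortSubject, DrawingRecording, Label, Task

__all__ = [
    "FoldAssignment",
    "make_subject_folds",
    "train_model",
    "predict_recording",
    "classify",
    "fuse_tasks",
    "MetricSet",
    "compute_metrics",
    "EvaluationReport",
    "cross_validate",
    "ablation_variants",
    "ablation_suite",
    "PairedComparison",
    "paired_comparison",
    "DEFAULT_TASK_FEATURES",
]

#: Task-optimized feature sets: velocity+acceleration for the spiral,
#: coordinate+velocity for the wave.
DEFAULT_TASK_FEATURES: dict[Task, FeatureSet] = {
    Task.SPIRAL: FeatureSet.VELOCITY_ACCELERATION,
    Task.WAVE: FeatureSet.COORDINATE_VELOCITY,
}


# --------------------------------------------------------------------------
# fold assignment
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldAssignment:
    """Subject -> fold partition for one repetition."""

    mapping: dict[str, int]
    k: int
    seed: int

    def fold_subjects(self, fold: int) -> list[str]:
        return [s for s, f in self.mapping.items() if f == fold]

    def train_subjects(self, fold: int) -> list[str]:
        return [s for s, f in self.mapping.items() if f != fold]


def make_subject_folds(
    subjects: Sequence[tuple[str, Label]], k: int, seed: int
) -> FoldAssignment:
    """Stratified subject-level partition into k folds.

    Within each label class, subjects are shuffled and dealt round-robin to
    a shuffled fold order, so per-fold class counts differ by at most one
    from perfect stratification. Deterministic given the seed.
    """
    n = len(subjects)
    if k > n:
        raise ValueError(f"k={k} exceeds number of subjects ({n})")
    if k < 2:
        raise ValueError("k must be at least 2")
    ids = [s for s, _ in subjects]
    if len(set(ids)) != n:
        raise ValueError("duplicate subject ids")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xF01D)))
    mapping: dict[str, int] = {}
    for label in (Label.PD, Label.HC):
        members = [s for s, l in subjects if Label(l) is label]
        order = rng.permutation(len(members))
        fold_order = rng.permutation(k)
        for pos, idx in enumerate(order):
            mapping[members[idx]] = int(fold_order[pos % k])
    return FoldAssignment(mapping=mapping, k=k, seed=seed)


# --------------------------------------------------------------------------
# prediction primitives
# --------------------------------------------------------------------------

def train_model(
    windows: np.ndarray,
    labels: np.ndarray,
    model_config: ModelConfig,
    train_config: TrainConfig,
) -> ClassifierResults:
    """Fit the segment classifier on labeled windows (both classes required)."""
    return HybridDrawingClassifier(windows, labels, model_config).fit(train_config)


def predict_recording(
    results: ClassifierResults,
    rec: DrawingRecording,
    feature_set: FeatureSet | str,
    seg: SegmentationConfig | None = None,
) -> float:
    """Recording-level probability: arithmetic mean of window probabilities."""
    return results.predict_recording_proba(rec, feature_set, seg)


def classify(probability: float) -> Label:
    """Strict decision rule: probability > 0.5 is PD, otherwise HC."""
    if not (0.0 <= probability <= 1.0):
        raise ValueError(f"probability {probability} outside [0, 1]")
    return Label.PD if probability > 0.5 else Label.HC


def fuse_tasks(p_spiral: float, p_wave: float) -> float:
    """Dual-task fusion: the mean of the two task probabilities."""
    for name, p in (("p_spiral", p_spiral), ("p_wave", p_wave)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name}={p} outside [0, 1]")
    return (p_spiral + p_wave) / 2.0


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricSet:
    """ACC/SEN/SPE/F1 in percent (PD positive); AUC in [0, 1].

    SEN or SPE is NaN when the corresponding class is absent from the truth.
    """

    acc: float
    sen: float
    spe: float
    f1: float
    auc: float
    n: int

    def as_dict(self) -> dict[str, float]:
        return {"acc": self.acc, "sen": self.sen, "spe": self.spe, "f1": self.f1, "auc": self.auc, "n": self.n}


def _rank_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC with ties averaged."""
    pos = y == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = sps.rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def compute_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray | None = None
) -> MetricSet:
    """Confusion-matrix metrics over binary labels (1 = PD positive)."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    n = tp + fn + tn + fp
    acc = 100.0 * (tp + tn) / n
    sen = 100.0 * tp / (tp + fn) if (tp + fn) else float("nan")
    spe = 100.0 * tn / (tn + fp) if (tn + fp) else float("nan")
    prec = tp / (tp + fp) if (tp + fp) else float("nan")
    rec = tp / (tp + fn) if (tp + fn) else float("nan")
    if np.isnan(prec) or np.isnan(rec) or (prec + rec) == 0:
        f1 = 0.0 if (tp + fn) else float("nan")
    else:
        f1 = 100.0 * 2 * prec * rec / (prec + rec)
    auc = _rank_auc(y_true, np.asarray(scores, dtype=float)) if scores is not None else float("nan")
    return MetricSet(acc=acc, sen=sen, spe=spe, f1=f1, auc=auc, n=n)


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------

@dataclass
class RepetitionResult:
    seed: int
    fold_assignment: FoldAssignment
    subject_probs: dict[str, dict[str, float]]  # sid -> {spiral, wave, fused}
    metrics: dict[str, MetricSet]  # per task + "fused"


@dataclass
class EvaluationReport:
    """Cross-validation outcome: per-repetition metrics plus aggregates."""

    repetitions: list[RepetitionResult]
    k: int
    seed: int
    config_echo: dict
    leakage_overlaps: int = 0

    def metric_matrix(self, scope: str, metric: str) -> np.ndarray:
        """(R,) vector of one metric across repetitions for scope
        ('spiral'|'wave'|'fused')."""
        return np.array([getattr(r.metrics[scope], metric) for r in self.repetitions])

    def mean_sd(self, scope: str, metric: str) -> tuple[float, float]:
        vals = self.metric_matrix(scope, metric)
        return float(np.mean(vals)), float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0

    def accuracy_ci95(self, scope: str = "fused") -> tuple[float, float]:
        """Normal-approximation CI on the mean accuracy across repetitions."""
        vals = self.metric_matrix(scope, "acc")
        m = float(np.mean(vals))
        if vals.size < 2:
            return (m, m)
        half = 1.96 * float(np.std(vals, ddof=1)) / np.sqrt(vals.size)
        return (m - half, m + half)

    def summary(self) -> str:
        lines = [
            f"Subject-confined stratified {self.k}-fold CV, "
            f"{len(self.repetitions)} repetition(s)",
            "=" * 60,
            f"{'scope':<8}{'ACC%':>14}{'SEN%':>14}{'SPE%':>14}{'F1%':>14}{'AUC':>8}",
        ]
        for scope in ("spiral", "wave", "fused"):
            if scope not in self.repetitions[0].metrics:
                continue
            cells = []
            for met in ("acc", "sen", "spe", "f1"):
                m, s = self.mean_sd(scope, met)
                cells.append(f"{m:6.2f}±{s:5.2f}" if len(self.repetitions) > 1 else f"{m:6.2f}")
            auc_m, _ = self.mean_sd(scope, "auc")
            lines.append(f"{scope:<8}" + "".join(f"{c:>14}" for c in cells) + f"{auc_m:>8.3f}")
        lo, hi = self.accuracy_ci95("fused")
        lines.append(f"fused accuracy 95% CI: [{lo:.2f}, {hi:.2f}]%")
        lines.append(f"train/validation subject overlaps observed: {self.leakage_overlaps}")
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "protocol": {"k": self.k, "repetitions": len(self.repetitions), "seed": self.seed},
            "config": self.config_echo,
            "versions": {"numpy": np.__version__, "pandas": pd.__version__},
            "leakage_overlaps": self.leakage_overlaps,
            "aggregate": {
                scope: {
                    met: self.mean_sd(scope, met)
                    for met in ("acc", "sen", "spe", "f1", "auc")
                }
                for scope in self.repetitions[0].metrics
            },
            "fused_accuracy_ci95": self.accuracy_ci95("fused"),
            "repetitions": [
                {
                    "seed": r.seed,
                    "folds": r.fold_assignment.mapping,
                    "subject_probabilities": r.subject_probs,
                    "metrics": {s: m.as_dict() for s, m in r.metrics.items()},
                }
                for r in self.repetitions
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)
        return path

    def plot_roc(self, scope: str = "fused", ax=None):
        """Pooled per-repetition ROC curves (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for rep in self.repetitions:
            labels, scores = [], []
            for sid, probs in rep.subject_probs.items():
                labels.append(probs["label"])
                scores.append(probs[scope])
            y = np.asarray(labels)
            s = np.asarray(scores)
            order = np.argsort(-s)
            tpr = np.concatenate([[0], np.cumsum(y[order] == 1) / max((y == 1).sum(), 1)])
            fpr = np.concatenate([[0], np.cumsum(y[order] == 0) / max((y == 0).sum(), 1)])
            ax.plot(fpr, tpr, alpha=0.5)
        ax.plot([0, 1], [0, 1], "k--", lw=0.5)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        return ax


def _derived_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(parts).generate_state(1)[0] % (2**31))


def cross_validate(
    subjects: Sequence[CohortSubject],
    k: int = 10,
    repetitions: int = 10,
    seed: int = 0,
    task_features: dict[Task, FeatureSet] | None = None,
    model_config: ModelConfig | dict[Task, ModelConfig] | None = None,
    train_config: TrainConfig | None = None,
    seg: SegmentationConfig | None = None,
    tasks: tuple[Task, ...] = (Task.SPIRAL, Task.WAVE),
) -> EvaluationReport:
    """Subject-confined stratified k-fold CV with repetitions and task fusion.

    Per repetition a fresh fold assignment is drawn from a derived seed; per
    fold one model per task is trained on the out-of-fold subjects' windows
    and the held-out subjects are scored by segment aggregation; spiral and
    wave probabilities are fused by averaging. The train/validation subject
    disjointness is asserted on every fold and the (always-zero) overlap
    count is carried in the report.
    """
    task_features = task_features or dict(DEFAULT_TASK_FEATURES)
    subjects = list(subjects)
    labels = {s.subject_id: Label(s.label) for s in subjects}
    y_true = {sid: 1 if lab is Label.PD else 0 for sid, lab in labels.items()}
    if len({*labels.values()}) < 2:
        raise ValueError("cohort must contain both classes")

    def config_for(task: Task) -> ModelConfig:
        fs = task_features[task]
        w = (seg or SegmentationConfig()).window_samples
        if model_config is None:
            return ModelConfig(n_channels=fs.n_channels, window_samples=w)
        if isinstance(model_config, dict):
            return model_config[task]
        return replace(model_config, n_channels=fs.n_channels, window_samples=w)

    seg = seg or SegmentationConfig(window_samples=config_for(tasks[0]).window_samples)
    train_config = train_config or TrainConfig()

    # Preprocess every recording once; windows are reused across folds/reps.
    cache: dict[tuple[str, Task], np.ndarray] = {}
    for s in subjects:
        for task in tasks:
            rec = getattr(s, task.value)
            cache[(s.subject_id, task)] = preprocess_recording(
                rec, feature_set=task_features[task], seg=seg
            ).windows

    reps: list[RepetitionResult] = []
    leakage_overlaps = 0
    id_label_pairs = [(s.subject_id, labels[s.subject_id]) for s in subjects]
    for rep in range(repetitions):
        rep_seed = _derived_seed(seed, rep)
        folds = make_subject_folds(id_label_pairs, k=k, seed=rep_seed)
        probs: dict[str, dict[str, float]] = {
            s.subject_id: {"label": float(y_true[s.subject_id])} for s in subjects
        }
        for fold in range(k):
            train_ids = folds.train_subjects(fold)
            val_ids = folds.fold_subjects(fold)
            overlap = set(train_ids) & set(val_ids)
            leakage_overlaps += len(overlap)
            assert not overlap, f"subject leakage in fold {fold}: {overlap}"
            for task in tasks:
                xs = np.concatenate([cache[(sid, task)] for sid in train_ids])
                ys = np.concatenate(
                    [
                        np.full(cache[(sid, task)].shape[0], float(y_true[sid]))
                        for sid in train_ids
                    ]
                )
                task_idx = tasks.index(task)
                tc = replace(train_config, seed=_derived_seed(rep_seed, fold, task_idx))
                results = train_model(xs, ys, config_for(task), tc)
                for sid in val_ids:
                    probs[sid][task.value] = float(
                        np.mean(results.predict_window_proba(cache[(sid, task)]))
                    )
        metrics: dict[str, MetricSet] = {}
        scopes = [t.value for t in tasks]
        if len(tasks) == 2:
            for sid in probs:
                probs[sid]["fused"] = fuse_tasks(probs[sid]["spiral"], probs[sid]["wave"])
            scopes.append("fused")
        order = [s.subject_id for s in subjects]
        yt = np.array([y_true[sid] for sid in order])
        for scope in scopes:
            ps = np.array([probs[sid][scope] for sid in order])
            yp = (ps > 0.5).astype(int)
            metrics[scope] = compute_metrics(yt, yp, ps)
            assert metrics[scope].n == len(subjects)
        reps.append(
            RepetitionResult(seed=rep_seed, fold_assignment=folds, subject_probs=probs, metrics=metrics)
        )

    echo = {
        "task_features": {t.value: task_features[t].value for t in tasks},
        "segmentation": {"window_samples": seg.window_samples, "overlap": seg.overlap_fraction},
        "train": {
            "lr": train_config.learning_rate,
            "batch_size": train_config.batch_size,
            "epochs": train_config.epochs,
        },
        "model": {t.value: config_for(t).__dict__ for t in tasks},
    }
    echo["model"] = {
        t: {k2: (sorted(v) if isinstance(v, frozenset) else v) for k2, v in d.items()}
        for t, d in echo["model"].items()
    }
    return EvaluationReport(
        repetitions=reps, k=k, seed=seed, config_echo=echo, leakage_overlaps=leakage_overlaps
    )


# --------------------------------------------------------------------------
# ablations
# --------------------------------------------------------------------------

WINDOW_AXIS = (8, 16, 32, 64, 128)


def ablation_variants(axis: str, base: ModelConfig | None = None) -> list[dict]:
    """Enumerate the variants of one ablation axis.

    Axes: ``window_size`` (5 window lengths), ``branch`` (single-block
    baseline plus one variant per removed branch), ``depth`` (0-3 conv
    blocks), ``cell`` (RNN/LSTM/GRU), ``features`` (the six feature
    subsets). Each variant is a dict with a ``name`` and the overrides to
    apply.
    """
    base = base or ModelConfig(n_channels=4)
    if axis == "window_size":
        return [{"name": f"W={w}", "window_samples": w} for w in WINDOW_AXIS]
    if axis == "branch":
        baseline = replace(base, n_conv_blocks=1)
        variants = [{"name": "baseline", "model_config": baseline}]
        for idx in sorted(BRANCH_NAMES):
            variants.append(
                {
                    "name": f"w/o Branch {idx} ({BRANCH_NAMES[idx]})",
                    "model_config": baseline.without_branch(idx),
                }
            )
        return variants
    if axis == "depth":
        return [
            {"name": f"{n} conv block(s)", "model_config": replace(base, n_conv_blocks=n)}
            for n in (0, 1, 2, 3)
        ]
    if axis == "cell":
        return [
            {"name": f"Bi{cell.upper()}", "model_config": replace(base, recurrent_cell=cell)}
            for cell in ("rnn", "lstm", "gru")
        ]
    if axis == "features":
        return [{"name": fs.value, "feature_set": fs} for fs in FeatureSet]
    raise ValueError(f"unknown ablation axis {axis!r}")


def ablation_suite(
    subjects: Sequence[CohortSubject],
    axes: Sequence[str],
    base: ModelConfig | None = None,
    k: int = 10,
    repetitions: int = 10,
    seed: int = 0,
    train_config: TrainConfig | None = None,
    tasks: tuple[Task, ...] = (Task.SPIRAL, Task.WAVE),
) -> pd.DataFrame:
    """One cross-validation run per variant, long-format metric table."""
    rows = []
    base = base or ModelConfig(n_channels=4)
    for axis in axes:
        for var in ablation_variants(axis, base):
            seg = None
            cfg = var.get("model_config", base)
            if "window_samples" in var:
                seg = SegmentationConfig(window_samples=var["window_samples"])
            task_features = None
            if "feature_set" in var:
                task_features = {t: var["feature_set"] for t in (Task.SPIRAL, Task.WAVE)}
            report = cross_validate(
                subjects,
                k=k,
                repetitions=repetitions,
                seed=seed,
                task_features=task_features,
                model_config=cfg,
                train_config=train_config,
                seg=seg,
                tasks=tasks,
            )
            for scope in report.repetitions[0].metrics:
                for met in ("acc", "sen", "spe", "f1", "auc"):
                    m, s = report.mean_sd(scope, met)
                    rows.append(
                        {
                            "axis": axis,
                            "variant": var["name"],
                            "scope": scope,
                            "metric": met,
                            "mean": m,
                            "sd": s,
                        }
                    )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# paired comparison
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedComparison:
    statistic: float
    p_value: float
    mean_difference: float
    degenerate: bool


def paired_comparison(a: Sequence[float], b: Sequence[float]) -> PairedComparison:
    """Two-sided paired t-test on repetition-level metric vectors.

    A zero-variance difference (including a == b) is reported as degenerate
    rather than raising, since the t statistic is undefined there.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.std(d, ddof=1) == 0:
        return PairedComparison(
            statistic=float("nan"),
            p_value=1.0 if np.allclose(d, 0) else 0.0,
            mean_difference=float(np.mean(d)),
            degenerate=True,
        )
    t, p = sps.ttest_rel(a, b)
    return PairedComparison(
        statistic=float(t), p_value=float(p), mean_difference=float(np.mean(d)), degenerate=False
    )
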