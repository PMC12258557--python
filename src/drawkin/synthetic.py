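"""Synthetic finger-drawing cohorts with controllable PD-like impairment.

The generator emulates the statistical structure of guided touchscreen
drawing at 60 Hz: an Archimedean spiral traced periphery-to-center over 2.5
rotations, and a two-period sine wave, both re-parameterized by an
along-path speed profile and perturbed by three disease-like effects:

* rest/action **tremor** — a sinusoid (default 5 Hz, within the clinical
  4-6 Hz band) applied transverse to the local path tangent, the direction
  in which tracing error around a guide line manifests;
* **bradykinesia** — a multiplicative speed reduction (``speed_scale < 1``)
  plus log-normal multiplicative speed noise with a chosen coefficient of
  variation, keeping speeds positive;
* **hesitations** — Poisson-arriving near-zero-speed intervals.

Sampling matches the capture protocol: 60 Hz with integer-millisecond
timestamps (accumulated-remainder rounding, so steps alternate 16/17 ms),
and velocities derived from the sampled coordinates by central differences
so (x, y, vx, vy) are mutually consistent. Everything is deterministic
given the seeds; per-subject parameters and seeds derive from one master
seed via seed-sequence spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .records import (
    CohortManifest,
    CohortSubject,
    DrawingRecording,
    Label,
    ManifestEntry,
    Task,
    validate_recording,
    write_recording,
)

__all__ = [
    "ImpairmentConfig",
    "ImpairmentSampler",
    "DurationModel",
    "CohortConfig",
    "spiral_template",
    "wave_template",
    "apply_impairment",
    "generate_subject",
    "generate_cohort",
    "synthesize_cohort",
    "pd_sampler",
    "hc_sampler",
]

# Screen geometry of the emulated device (landscape orientation).
SPIRAL_CENTER_PX = (1170.0, 540.0)
SPIRAL_RADIUS_PX = 440.0  # ~2.2 inch diameter at ~400 ppi
WAVE_WIDTH_PX = 1600.0
WAVE_AMPLITUDE_PX = 200.0
WAVE_ORIGIN_PX = (370.0, 540.0)

_TEMPLATE_DENSITY = 1500
_HESITATION_SPEED_FACTOR = 0.02


@dataclass(frozen=True)
class ImpairmentConfig:
    """Per-recording impairment parameters.

    tremor_amplitude_px / tremor_hz: transverse oscillation; the frequency
    default sits mid-band of clinical 4-6 Hz tremor.
    speed_scale: multiplies the base along-path speed (< 1 = bradykinetic).
    speed_cv: coefficient of variation of the multiplicative log-normal
    speed noise.
    hesitation_rate_per_s / hesitation_duration_s: Poisson rate and length
    of near-zero-speed pauses.
    path_noise_sd_px: isotropic Gaussian jitter of the touch point.
    """

    seed: int
    tremor_amplitude_px: float = 0.0
    tremor_hz: float = 5.0
    speed_scale: float = 1.0
    speed_cv: float = 0.0
    hesitation_rate_per_s: float = 0.0
    hesitation_duration_s: float = 0.35
    path_noise_sd_px: float = 0.0

    def __post_init__(self) -> None:
        if self.tremor_amplitude_px < 0:
            raise ValueError("tremor_amplitude_px must be >= 0")
        if not (3.0 <= self.tremor_hz <= 8.0):
            raise ValueError("tremor_hz must be in [3, 8]")
        if not (0.0 < self.speed_scale <= 1.5):
            raise ValueError("speed_scale must be in (0, 1.5]")
        if self.speed_cv < 0:
            raise ValueError("speed_cv must be >= 0")
        if self.hesitation_rate_per_s < 0:
            raise ValueError("hesitation_rate_per_s must be >= 0")
        if self.hesitation_duration_s <= 0:
            raise ValueError("hesitation_duration_s must be > 0")
        if self.path_noise_sd_px < 0:
            raise ValueError("path_noise_sd_px must be >= 0")


def spiral_template(
    n_points: int,
    rotations: float = 2.5,
    radius_px: float = SPIRAL_RADIUS_PX,
    center_px: tuple[float, float] = SPIRAL_CENTER_PX,
) -> np.ndarray:
    """Archimedean spiral traced periphery-to-center.

    r(theta) = radius_px * theta / theta_max with theta_max = rotations*2*pi,
    sampled from theta = theta_max down to 0, so the radial distance from the
    center is strictly decreasing along the returned N x 2 point sequence.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if radius_px <= 0:
        raise ValueError("radius_px must be > 0")
    theta_max = rotations * 2.0 * np.pi
    theta = np.linspace(theta_max, 0.0, n_points)
    r = radius_px * theta / theta_max
    x = center_px[0] + r * np.cos(theta)
    y = center_px[1] + r * np.sin(theta)
    return np.column_stack([x, y])


def wave_template(
    n_points: int,
    periods: float = 2.0,
    amplitude_px: float = WAVE_AMPLITUDE_PX,
    width_px: float = WAVE_WIDTH_PX,
    origin_px: tuple[float, float] = WAVE_ORIGIN_PX,
) -> np.ndarray:
    """Sine-wave template spanning ``periods`` full periods across width_px."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if amplitude_px <= 0 or width_px <= 0:
        raise ValueError("amplitude_px and width_px must be > 0")
    u = np.linspace(0.0, 1.0, n_points)
    x = origin_px[0] + u * width_px
    y = origin_px[1] + amplitude_px * np.sin(2.0 * np.pi * periods * u)
    return np.column_stack([x, y])


def _arc_length_param(template: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative arc length and unit tangents at each template point."""
    deltas = np.diff(template, axis=0)
    seg = np.hypot(deltas[:, 0], deltas[:, 1])
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    grads = np.gradient(template, arc, axis=0, edge_order=1)
    norms = np.hypot(grads[:, 0], grads[:, 1])
    norms[norms == 0] = 1.0
    return arc, grads / norms[:, None]


def _quantized_timestamps_ms(n: int, hz: float = 60.0) -> np.ndarray:
    """Integer-ms timestamps 0, 17, 33, 50, ... (accumulated-remainder rounding)."""
    return np.round(np.arange(n) * 1000.0 / hz).astype(np.int64)


def apply_impairment(
    template: np.ndarray,
    cfg: ImpairmentConfig,
    duration_s: float,
    subject_id: str = "synthetic",
    task: Task | str = Task.SPIRAL,
    label: Optional[Label] = None,
    sampling_hz: float = 60.0,
) -> DrawingRecording:
    """Trace a template with the configured impairment, sampled at 60 Hz.

    The template is re-parameterized by an along-path speed profile (base
    speed = total arc length / duration, scaled by ``speed_scale``, with
    log-normal multiplicative noise and hesitation pauses), tremor is added
    transverse to the local tangent, then isotropic jitter; velocities come
    from central differences of the sampled coordinates over the quantized
    timestamps. Independent child RNG streams drive each noise source, so
    switching one effect off leaves the others' draws unchanged.
    """
    template = np.asarray(template, dtype=np.float64)
    n = int(np.floor(duration_s * sampling_hz)) + 1
    if n < 2:
        raise ValueError(f"duration {duration_s} s holds fewer than 2 samples at {sampling_hz} Hz")

    ss = np.random.SeedSequence(cfg.seed)
    rng_speed, rng_hes, rng_tremor, rng_jitter = (np.random.default_rng(s) for s in ss.spawn(4))

    arc, tangents = _arc_length_param(template)
    total_arc = float(arc[-1])
    t = np.arange(n) / sampling_hz

    base_speed = total_arc / duration_s * cfg.speed_scale
    if cfg.speed_cv > 0:
        sigma2 = np.log1p(cfg.speed_cv**2)
        mult = rng_speed.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=n)
    else:
        mult = np.ones(n)
        rng_speed.lognormal(size=n)  # keep the stream advanced identically

    speed = base_speed * mult
    if cfg.hesitation_rate_per_s > 0:
        n_events = rng_hes.poisson(cfg.hesitation_rate_per_s * duration_s)
        starts = np.sort(rng_hes.uniform(0.0, duration_s, size=n_events))
        for t0 in starts:
            mask = (t >= t0) & (t < t0 + cfg.hesitation_duration_s)
            speed[mask] *= _HESITATION_SPEED_FACTOR
    else:
        rng_hes.poisson(1.0)
        rng_hes.uniform(size=1)

    # Integrate speed to arc position (left Riemann sum), clip at path end.
    s_pos = np.concatenate([[0.0], np.cumsum(speed[:-1]) / sampling_hz])
    s_pos = np.clip(s_pos, 0.0, total_arc)

    x = np.interp(s_pos, arc, template[:, 0])
    y = np.interp(s_pos, arc, template[:, 1])
    tx = np.interp(s_pos, arc, tangents[:, 0])
    ty = np.interp(s_pos, arc, tangents[:, 1])
    tnorm = np.hypot(tx, ty)
    tnorm[tnorm == 0] = 1.0
    tx, ty = tx / tnorm, ty / tnorm

    phase = rng_tremor.uniform(0.0, 2.0 * np.pi)
    osc = cfg.tremor_amplitude_px * np.sin(2.0 * np.pi * cfg.tremor_hz * t + phase)
    # transverse = left normal of the tangent
    x = x + osc * (-ty)
    y = y + osc * tx

    jitter = rng_jitter.normal(0.0, 1.0, size=(n, 2))
    if cfg.path_noise_sd_px > 0:
        x = x + cfg.path_noise_sd_px * jitter[:, 0]
        y = y + cfg.path_noise_sd_px * jitter[:, 1]

    t_ms = _quantized_timestamps_ms(n, sampling_hz)
    dt = np.empty(n)
    dt[1:-1] = (t_ms[2:] - t_ms[:-2]) / 1000.0
    dt[0] = (t_ms[1] - t_ms[0]) / 1000.0
    dt[-1] = (t_ms[-1] - t_ms[-2]) / 1000.0
    vx = np.empty(n)
    vy = np.empty(n)
    vx[1:-1] = (x[2:] - x[:-2]) / dt[1:-1]
    vy[1:-1] = (y[2:] - y[:-2]) / dt[1:-1]
    vx[0], vy[0] = (x[1] - x[0]) / dt[0], (y[1] - y[0]) / dt[0]
    vx[-1], vy[-1] = (x[-1] - x[-2]) / dt[-1], (y[-1] - y[-2]) / dt[-1]

    rec = DrawingRecording(
        subject_id=subject_id,
        task=Task(task),
        label=label,
        timestamps_ms=t_ms,
        x_px=x,
        y_px=y,
        vx=vx,
        vy=vy,
        sampling_hz_nominal=sampling_hz,
    )
    violations = validate_recording(rec)
    if violations:  # pragma: no cover - generator bug guard
        raise AssertionError(f"generator produced invalid recording: {violations}")
    return rec


@dataclass(frozen=True)
class ImpairmentSampler:
    """Uniform per-subject parameter ranges for one study group.

    Each field is a (low, high) interval; a subject's ImpairmentConfig is
    drawn once and shared by both of their recordings (with per-recording
    noise seeds).
    """

    tremor_amplitude_px: tuple[float, float] = (0.0, 1.0)
    tremor_hz: tuple[float, float] = (4.0, 6.0)
    speed_scale: tuple[float, float] = (0.9, 1.1)
    speed_cv: tuple[float, float] = (0.05, 0.15)
    hesitation_rate_per_s: tuple[float, float] = (0.0, 0.1)
    hesitation_duration_s: tuple[float, float] = (0.3, 0.4)
    path_noise_sd_px: tuple[float, float] = (0.3, 0.8)

    def sample(self, rng: np.random.Generator, seed: int) -> ImpairmentConfig:
        draw = lambda lohi: float(rng.uniform(*lohi))
        return ImpairmentConfig(
            seed=seed,
            tremor_amplitude_px=draw(self.tremor_amplitude_px),
            tremor_hz=draw(self.tremor_hz),
            speed_scale=draw(self.speed_scale),
            speed_cv=draw(self.speed_cv),
            hesitation_rate_per_s=draw(self.hesitation_rate_per_s),
            hesitation_duration_s=draw(self.hesitation_duration_s),
            path_noise_sd_px=draw(self.path_noise_sd_px),
        )


def hc_sampler() -> ImpairmentSampler:
    """Healthy-control ranges: near-null impairment, mild natural variability."""
    return ImpairmentSampler()


def pd_sampler() -> ImpairmentSampler:
    """Early-PD ranges: 4-6 Hz tremor, bradykinetic slowing, pauses."""
    return ImpairmentSampler(
        tremor_amplitude_px=(3.0, 9.0),
        tremor_hz=(4.0, 6.0),
        speed_scale=(0.55, 0.85),
        speed_cv=(0.2, 0.4),
        hesitation_rate_per_s=(0.3, 0.8),
        hesitation_duration_s=(0.3, 0.5),
        path_noise_sd_px=(0.5, 1.2),
    )


@dataclass(frozen=True)
class DurationModel:
    """Truncated-normal completion-time model (seconds) for one task/group."""

    mean_s: float
    sd_s: float
    min_s: float
    max_s: float

    def __post_init__(self) -> None:
        if not (2.8 <= self.min_s <= self.max_s <= 17.0):
            raise ValueError("duration range must lie within [2.8, 17] s")

    def sample(self, rng: np.random.Generator) -> float:
        for _ in range(100):
            d = rng.normal(self.mean_s, self.sd_s)
            if self.min_s <= d <= self.max_s:
                return float(d)
        return float(np.clip(self.mean_s, self.min_s, self.max_s))


#: Completion-time models per (task, group), matching the observed cohort
#: envelope (spiral ~6.6-7.8 s group means, max 16.63 s; wave ~5.9-6.1 s).
DEFAULT_DURATIONS: dict[tuple[Task, Label], DurationModel] = {
    (Task.SPIRAL, Label.PD): DurationModel(7.77, 2.72, 2.86, 16.63),
    (Task.SPIRAL, Label.HC): DurationModel(6.59, 2.67, 2.86, 16.63),
    (Task.WAVE, Label.PD): DurationModel(6.12, 2.20, 2.80, 11.97),
    (Task.WAVE, Label.HC): DurationModel(5.90, 2.33, 2.80, 11.97),
}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generation settings.

    Defaults mirror the study's class balance (28 PD / 30 HC) and completion
    time envelope; impairment ranges default to the per-group samplers.
    """

    n_pd: int = 28
    n_hc: int = 30
    master_seed: int = 0
    pd_impairment: ImpairmentSampler = field(default_factory=pd_sampler)
    hc_impairment: ImpairmentSampler = field(default_factory=hc_sampler)
    durations: dict[tuple[Task, Label], DurationModel] = field(
        default_factory=lambda: dict(DEFAULT_DURATIONS)
    )

    def __post_init__(self) -> None:
        if self.n_pd < 0 or self.n_hc < 0 or self.n_pd + self.n_hc < 2:
            raise ValueError("need at least 2 subjects in total")


def generate_subject(
    subject_id: str,
    label: Label,
    sampler: ImpairmentSampler,
    durations: dict[tuple[Task, Label], DurationModel],
    seed: np.random.SeedSequence,
) -> CohortSubject:
    """One subject: a shared impairment draw, then one recording per task."""
    param_ss, spiral_ss, wave_ss = seed.spawn(3)
    rng = np.random.default_rng(param_ss)
    recs = {}
    for task, rec_ss in ((Task.SPIRAL, spiral_ss), (Task.WAVE, wave_ss)):
        rec_seed = int(rec_ss.generate_state(1)[0] % (2**31))
        cfg = sampler.sample(rng, seed=rec_seed)
        duration = durations[(task, label)].sample(rng)
        template = (
            spiral_template(_TEMPLATE_DENSITY)
            if task is Task.SPIRAL
            else wave_template(_TEMPLATE_DENSITY)
        )
        recs[task] = apply_impairment(
            template, cfg, duration, subject_id=subject_id, task=task, label=label
        )
    return CohortSubject(
        subject_id=subject_id, label=label, spiral=recs[Task.SPIRAL], wave=recs[Task.WAVE]
    )


def generate_cohort(cfg: CohortConfig) -> list[CohortSubject]:
    """Generate the full labeled cohort in memory, deterministically."""
    master = np.random.SeedSequence(cfg.master_seed)
    seeds = master.spawn(cfg.n_pd + cfg.n_hc)
    subjects = []
    for i in range(cfg.n_pd):
        subjects.append(
            generate_subject(f"PD{i + 1:03d}", Label.PD, cfg.pd_impairment, cfg.durations, seeds[i])
        )
    for i in range(cfg.n_hc):
        subjects.append(
            generate_subject(
                f"HC{i + 1:03d}", Label.HC, cfg.hc_impairment, cfg.durations, seeds[cfg.n_pd + i]
            )
        )
    return subjects


def synthesize_cohort(cfg: CohortConfig, out_dir: str | Path) -> CohortManifest:
    """Generate a cohort and write it to disk (CSV recordings + JSON manifest)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subjects = generate_cohort(cfg)
    entries = []
    for subj in subjects:
        paths = {}
        for task in (Task.SPIRAL, Task.WAVE):
            rel = f"{subj.subject_id}_{task.value}.csv"
            write_recording(getattr(subj, task.value), out_dir / rel)
            paths[task.value] = rel
        entries.append(
            ManifestEntry(
                subject_id=subj.subject_id,
                label=subj.label,
                spiral=paths["spiral"],
                wave=paths["wave"],
            )
        )
    manifest = CohortManifest(
        entries=entries,
        provenance=f"drawkin synthetic cohort (n_pd={cfg.n_pd}, n_hc={cfg.n_hc})",
        seed=cfg.master_seed,
        root=out_dir,
    )
    manifest.to_json(out_dir / "manifest.json")
    return manifest
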