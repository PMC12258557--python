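import numpy as np
import pytest

from drawkin.records import DrawingRecording, Label, Task
from drawkin.synthetic import (
    CohortConfig,
    ImpairmentConfig,
    ImpairmentSampler,
    apply_impairment,
    generate_cohort,
    hc_sampler,
    wave_template,
)


@pytest.fixture
def simple_recording() -> DrawingRecording:
    """Tiny hand-built valid recording (uniform ~60 Hz, straight line)."""
    t = np.array([0, 17, 33, 50, 67, 83])
    x = np.linspace(100.0, 150.0, 6)
    y = np.linspace(200.0, 210.0, 6)
    return DrawingRecording(
        subject_id="S1",
        task=Task.SPIRAL,
        label=Label.HC,
        timestamps_ms=t,
        x_px=x,
        y_px=y,
        vx=np.full(6, 600.0),
        vy=np.full(6, 120.0),
    )


@pytest.fixture
def clean_wave_recording() -> DrawingRecording:
    """Noise-free synthetic wave tracing, 6 s at 60 Hz."""
    return apply_impairment(
        wave_template(2000), ImpairmentConfig(seed=3), 6.0, subject_id="W1", task=Task.WAVE
    )


@pytest.fixture(scope="session")
def small_cohort():
    """10-subject cohort with clearly separated groups (session-cached)."""
    strong_pd = ImpairmentSampler(
        tremor_amplitude_px=(6.0, 9.0),
        speed_scale=(0.5, 0.7),
        speed_cv=(0.2, 0.4),
        hesitation_rate_per_s=(0.3, 0.8),
        path_noise_sd_px=(0.5, 1.2),
    )
    cfg = CohortConfig(n_pd=5, n_hc=5, master_seed=42, pd_impairment=strong_pd)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort_small():
    """8 subjects whose PD/HC groups are generated identically."""
    cfg = CohortConfig(n_pd=4, n_hc=4, master_seed=9, pd_impairment=hc_sampler())
    return generate_cohort(cfg)
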