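# drawkin

Screening for early Parkinson's disease (PD) from **finger drawings on a
smartphone touchscreen**. Subjects trace two guided templates — an
Archimedean spiral (2.5 rotations, periphery to center) and a two-period
sine wave — while the screen records touch coordinates (x, y),
instantaneous velocities (v_x, v_y) and millisecond timestamps at a
nominal 60 Hz. `drawkin` turns those traces into a diagnostic
probability and provides everything around that: a canonical data model,
a seeded synthetic cohort simulator with controllable tremor,
bradykinesia and hesitation effects, the preprocessing pipeline, a
from-scratch hybrid neural classifier, and the subject-confined
cross-validation protocol. It is aimed at researchers working on digital
motor biomarkers who need a reproducible, clinical-data-free reference
implementation of this kind of pipeline.

## Method

Each recording becomes an 8-channel kinematic matrix
(x, y, v_x, v_y, a_x, a_y, j_x, j_y) with acceleration a = Δv/Δt and jerk
j = Δa/Δt taken over the recorded timestamps, is z-scored per channel,
cut into 32-sample windows (0.53 s) with 75% overlap, and zero-padded in
the trailing window. Windows are classified by two multi-branch 1D
convolution blocks (parallel 1×1/1×3/1×5 convolutions plus a 1×3 max
pool, channel concatenation, residual fusion via a learned 1×1
projection; 8 then 16 filters) feeding a bidirectional GRU (64 hidden
units per direction),

    z_t = σ(W_z·[h_{t−1}, x_t] + b_z)
    r_t = σ(W_r·[h_{t−1}, x_t] + b_r)
    h̃_t = tanh(W_h·[r_t ⊙ h_{t−1}, x_t] + b_h)
    h_t = (1 − z_t) ⊙ h_{t−1} + z_t ⊙ h̃_t

whose output sequence is flattened through dropout (0.3) and a dense
layer to a sigmoid PD probability per window. A recording's probability
is the mean over its windows; > 0.5 is called PD; a subject's final score
averages the spiral-model and wave-model probabilities (dual-task
fusion). Evaluation is stratified k-fold cross-validation with all of a
subject's windows confined to one fold, repeated with re-randomized
folds, reporting ACC/SEN/SPE/F1 (PD positive) and rank-statistic AUC.

The network — including backpropagation through time and Adam — is
implemented directly on NumPy arrays and is verified in the test suite
against a scalar-loop oracle of the gate equations, numerical gradients,
and independent scikit-learn cross-checks. Everything is deterministic
given its seeds.

See `docs/methods.md` for the model assumptions, the synthetic
generator's parameter ranges, and numerical choices.

## Worked example

```python
from drawkin import CohortConfig, ModelConfig, TrainConfig, cross_validate
from drawkin.synthetic import ImpairmentSampler, generate_cohort

# 16 subjects; the PD group draws with 6-9 px transverse tremor and
# a bradykinetic speed scale of 0.5-0.7
pd_group = ImpairmentSampler(tremor_amplitude_px=(6, 9), speed_scale=(0.5, 0.7),
                             speed_cv=(0.2, 0.4), hesitation_rate_per_s=(0.3, 0.8),
                             path_noise_sd_px=(0.5, 1.2))
cohort = generate_cohort(CohortConfig(n_pd=8, n_hc=8, master_seed=42,
                                      pd_impairment=pd_group))
report = cross_validate(cohort, k=4, repetitions=2, seed=1,
                        model_config=ModelConfig.small(n_channels=4),
                        train_config=TrainConfig(epochs=4, batch_size=4))
print(report.summary())
```

prints

```
Subject-confined stratified 4-fold CV, 2 repetition(s)
============================================================
scope             ACC%          SEN%          SPE%           F1%     AUC
spiral    100.00± 0.00  100.00± 0.00  100.00± 0.00  100.00± 0.00   1.000
wave       93.75± 0.00   87.50± 0.00  100.00± 0.00   93.33± 0.00   0.992
fused     100.00± 0.00  100.00± 0.00  100.00± 0.00  100.00± 0.00   1.000
fused accuracy 95% CI: [100.00, 100.00]%
train/validation subject overlaps observed: 0
```

With effect sizes this pronounced the spiral model alone separates the
groups perfectly; the wave model misses one PD subject per repetition
(sensitivity 87.5% at n=16), and dual-task fusion recovers it, putting
the fused subject-level score at 100% accuracy and AUC 1.0. The leakage
audit confirms no subject ever appears on both sides of a fold. With
weaker impairment (or identically generated groups) the same protocol
degrades toward chance — that calibration is part of the acceptance
checks.

The same workflows are scriptable from the shell:

```sh
drawkin simulate --n-pd 8 --n-hc 8 --seed 42 --out cohort/
drawkin evaluate --manifest cohort/manifest.json --k 4 --reps 2 \
                 --epochs 4 --small --seed 1 --out results/
drawkin ablate   --manifest cohort/manifest.json --axis features --out abl/
```

plus `preprocess`, `train` and `external-validate` (which resamples
higher-rate acceleration data, e.g. 1000 Hz pen recordings, onto the
60 Hz grid and scores it with a trained checkpoint).

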