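# Methods

## The problem and the pipeline

Early Parkinson's disease (PD) perturbs fine visuomotor control in ways
that surface during guided drawing: 4–6 Hz tremor appears as oscillation
transverse to the intended path, bradykinesia as reduced and fluctuating
along-path speed, and motor blocks as brief near-zero-speed hesitations.
`drawkin` classifies PD vs. healthy control (HC) from two touchscreen
tracing tasks captured at a nominal 60 Hz — an Archimedean spiral traced
over 2.5 rotations from periphery to center, and a sine wave spanning two
periods — using per-sample touch coordinates (x, y), instantaneous
velocities (vx, vy) and integer-millisecond timestamps.

The pipeline has four stages:

1. **Kinematic derivation.** Acceleration and jerk are first difference
   quotients over the recorded timestamps, a[t] = (v[t] − v[t−1])/Δt and
   j[t] = (a[t] − a[t−1])/Δt, giving the 8-channel matrix
   (x, y, vx, vy, ax, ay, jx, jy). The leading entries of each derivative
   column are zero so all columns keep length T; when millisecond
   quantization makes two timestamps equal, Δt falls back to the nominal
   1/60 s. Six named channel subsets (coordinate+velocity, all,
   velocity+acceleration+jerk, acceleration+jerk, velocity+acceleration,
   coordinate+velocity+acceleration) support task-specific feature
   selection; the defaults are velocity+acceleration for the spiral task
   and coordinate+velocity for the wave task.
2. **Standardization.** Per-column z-score with population (divide-by-N)
   standard deviation. The default scope is *per recording*: each trace is
   standardized by its own statistics, which removes absolute scale and
   device geometry and is what makes cross-device transfer plausible. A
   per-training-fold scope (passing pooled mean/SD into
   `zscore_normalize`) is available for leakage-averse experiments; with
   per-recording scope no statistic crosses the train/validation boundary
   by construction. Zero-variance columns map to zeros rather than raising.
3. **Segmentation.** Sliding windows of W = 32 samples (0.53 s at 60 Hz)
   with 75% overlap, i.e. stride s = 8. Window starts are 0, s, 2s, …;
   K = 1 + ceil(max(T−W, 0)/s). Windows are half-open, 0-based.
4. **Padding.** Only the final window may extend past the recording; its
   tail is zero-filled and the pad count is carried alongside.

An adapter for higher-rate external data (e.g. 1000 Hz pen accelerometry)
linearly interpolates the two acceleration channels onto the 60 Hz grid,
derives jerk on the resampled grid, and hands the resulting
(ax, ay, jx, jy) block to the same standardize/segment stages.

## The classifier

Windows are classified by a hybrid multi-branch 1D-CNN + bidirectional GRU
network. Each conv block runs four parallel branches over (batch, time,
channel) input — 1×1, 1×3 and 1×5 convolutions with F filters each, and a
stride-1 1×3 max pool that passes the C_in input channels through —
concatenates them along channels (C_out = 3F + C_in), and adds a learned
1×1 projection of the block input (residual fusion). The default network
stacks two blocks with F = 8 then F = 16. All convolutions and the pool
use "same" padding and stride 1, so the time axis is preserved end to end
and the flatten width of the head is fixed.

Design choices where the architecture was genuinely open:

* **Residual width reconciliation.** The branch concatenation (3F + C_in
  channels) cannot be added to the C_in-channel input directly; we use a
  learned 1×1 projection, the standard residual practice. The "without
  Branch 1" ablation removes the projection-and-add entirely.
* **Pool branch width.** The max-pool branch emits the input channels
  unchanged (no post-pool convolution); the filter count qualifies the
  three conv branches only.
* **Nonlinearity placement.** Each conv branch output passes through a
  ReLU; the pool and residual paths stay linear. This keeps the
  identity-like paths transparent (a constant input re-emerges unchanged
  from the pool branch) while making the conv stack nonlinear.
* **Branch order.** Concatenation order is fixed (conv1, conv3, conv5,
  maxpool) for reproducibility.

The recurrent encoder is a bidirectional GRU with 64 hidden units per
direction (tanh-RNN and LSTM are drop-in variants sharing the sequence
API). The GRU follows the standard update/reset-gate equations with
weights acting on the concatenation [h_{t−1}, x_t]; the from-scratch
implementation is verified against a pure-Python scalar-loop oracle to
1e-6 on random small instances. The encoder's full output sequence
(W × 2H) is flattened — the fixed-window reading; windows are always
exactly W samples — passed through dropout at rate 0.3 and one fully
connected layer to a single logit, then a sigmoid gives the per-window PD
probability.

The whole network, including backpropagation through time and Adam, is
implemented directly on NumPy arrays (`drawkin.nn`). Everything is
float64 and deterministic given its seeds: two eval-mode forward passes
are bit-identical, and training is exactly reproducible. Initialization
is uniform fan-in (±1/√fan_in) from an explicit seed.

## Training and validation protocol

Training minimizes binary cross-entropy (the natural loss for a sigmoid
head) with Adam at learning rate 0.001 and batch size 4. Segment labels
inherit the subject label. Epochs default to 60 with optional
training-loss early stopping (patience on a 1e-4 improvement tolerance).

Validation is subject-confined stratified k-fold (default k = 10) with
repetitions: subjects are partitioned *before* window extraction, each
class shuffled and dealt round-robin to a shuffled fold order, so per-fold
class counts deviate from perfect stratification by at most one. Per fold
and task a model is trained on the out-of-fold subjects' windows; each
held-out recording's probability is the arithmetic mean of its window
probabilities; a value strictly greater than 0.5 is called PD (ties go to
HC). Dual-task fusion averages a subject's spiral and wave probabilities.
Repetitions re-randomize folds via seeds derived from the master seed.
Train/validation subject disjointness is asserted programmatically on
every fold of every run.

Metrics (PD positive): accuracy, sensitivity, specificity and F1 in
percent, plus AUC via the rank (Mann–Whitney) statistic with ties
averaged. Across repetitions we report mean ± SD and a
normal-approximation 95% CI (mean ± 1.96·SD/√R) on the headline accuracy.
Paired model comparisons use a two-sided paired t-test on
repetition-level accuracies; zero-variance differences are reported as
degenerate rather than raising. ROC curves pool subject-level
probabilities within a repetition.

Ablation axes: window length ∈ {8, 16, 32, 64, 128}; branch removal
(single-block baseline plus one variant per removed branch, each with a
distinct parameter count); conv depth 0–3; recurrent cell RNN/LSTM/GRU;
the six feature subsets. `ablation_suite` runs one cross-validation per
variant and emits a long-format table.

## The synthetic cohort generator

The generator emulates the statistical structure of guided finger drawing
so every downstream stage is testable without clinical data. A dense
geometric template (spiral or wave) is re-parameterized by an along-path
speed profile and sampled at 60 Hz with integer-millisecond timestamps
(accumulated-remainder rounding, so steps alternate 16/17 ms). Velocities
come from central differences of the sampled coordinates, keeping all
four raw channels mutually consistent. Impairment parameters per subject:

| parameter | HC range | PD range | units |
| --- | --- | --- | --- |
| tremor amplitude | 0–1 | 3–9 | px |
| tremor frequency | 4–6 | 4–6 | Hz |
| speed scale | 0.9–1.1 | 0.55–0.85 | — |
| speed CV | 0.05–0.15 | 0.2–0.4 | — |
| hesitation rate | 0–0.1 | 0.3–0.8 | events/s |
| hesitation length | 0.3–0.4 | 0.3–0.5 | s |
| path jitter SD | 0.3–0.8 | 0.5–1.2 | px |

Tremor is a sinusoid applied transverse to the local path tangent (the
direction in which tracing error around a guide line manifests), with a
random phase; speed noise is log-normal multiplicative (keeps speed
positive) with the configured coefficient of variation; hesitations
arrive as a Poisson process and scale speed by 0.02 for their duration;
isotropic Gaussian jitter is added last. Each noise source draws from its
own spawned RNG stream, so switching one effect off leaves the others'
draws unchanged — this is what makes the spectral oracle test possible
(the FFT of the perturbed-minus-clean transverse projection peaks at the
configured tremor frequency to within one bin).

Completion times are truncated normals per task and group with means/SDs
7.77 ± 2.72 s (spiral, PD), 6.59 ± 2.67 s (spiral, HC), 6.12 ± 2.20 s and
5.90 ± 2.33 s (wave), clipped to the observed 2.8–16.63 s envelope; the
default class balance is 28 PD / 30 HC. Geometry uses a 440 px spiral
radius and a 1600 × 400 px wave on a 2340 × 1080 landscape frame.

What the generator does **not** emulate: touch pressure/contact area,
pen lifts and stroke restarts, template-following feedback corrections
(the simulated hand never steers back toward the guide line after
drifting), inter-device sampling-rate variation, and within-subject
session-to-session variability. Passing tests therefore demonstrate that
the pipeline recovers the injected effects under these idealized
conditions, not that clinical accuracy would match.

## Problem sizes and numerical choices

Desk-scale defaults used by the test suite and the acceptance script,
chosen so a full run fits comfortably on one CPU core:

* the **small model preset** (`ModelConfig.small`): one conv block with
  4 filters per branch, 16 hidden units per direction — the same
  architecture family at reduced width;
* cross-validation at k = 5 with 2–3 repetitions and 4 training epochs
  for the calibration/separability runs (the subject-confinement audit
  runs the full 10 × 10-fold assignment protocol);
* cohorts of 40 subjects (null calibration) and 60 subjects
  (separability), class-balanced.

Numerical details: sigmoid is evaluated in its numerically stable split
form; probabilities are clipped to [1e-12, 1 − 1e-12] before the
cross-entropy; z-scoring of a constant column yields zeros; equal
consecutive timestamps (ms quantization) fall back to the nominal Δt;
the decision threshold is strict (0.5 ties → HC); fold dealing and all
seeds derive from `numpy.random.SeedSequence` spawning, keeping every
derived seed below 2³¹.

## Known limitations

* The NumPy training engine is single-threaded BLAS-bound; it is built
  for cohort-scale experiments, not large-scale training.
* Null-cohort calibration is a stochastic check: with 40 subjects the
  chance band is wide (binomial SD ≈ 8 percentage points), so individual
  runs fluctuate within it.
* The per-recording z-score scope is a modelling choice; whether the
  original capture app reports raw or smoothed velocities is unknown, and
  synthetic data uses finite differences throughout.
* Clinical accuracies depend on the clinical cohort; the synthetic
  acceptance targets are separability and calibration properties, not
  reproductions of clinical numbers.
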