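# Methods

## Signal model and estimation problem

The package estimates the continuous arterial blood-pressure (ABP)
waveform, in mmHg, from two non-invasive waveforms sampled on a shared
125 Hz clock: the electrocardiogram (ECG) and a fingertip
photoplethysmogram (PPG). The physiological basis is the inverse
relationship between arterial pressure and pulse transit time (PTT):
higher pressure stiffens the arterial wall, the pulse wave travels
faster, and the PPG upstroke follows the ECG R-wave sooner. The
relevant information therefore lives in the relative timing and shape
of the two waveforms, while their absolute amplitudes are nuisance
parameters governed by electrode contact, light coupling, and sensor
gain.

## Preprocessing

Each signal is cut into non-overlapping frames of `window_len = 250`
samples (2 s at 125 Hz); a trailing remainder shorter than one window
is discarded (the corpus sizes of interest are exact multiples, e.g.
203,000 = 812 × 250). Each ECG and PPG frame is multiplied by an
independent random gain, uniform on `[amp_low, amp_high]` =
`[1e-6, 1]`. The lower bound is strictly positive because a zero gain
annihilates the window and leaves its z-score undefined; values this
side of zero do not change the uniform distribution materially. The
full 250-bin DFT of each randomized frame is taken (the
conjugate-redundant half retained so the channel width equals the
window length; a one-sided option exists but is not the default), and
magnitude and principal-value phase are z-scored per frame per
channel, giving the 4 × 250 input (|ECG|, ∠ECG, |PPG|, ∠PPG).

**Exact scale invariance.** For any per-frame constant c > 0,
|F{c·x}| = c·|F{x}| and ∠F{c·x} = ∠F{x}; the per-channel z-score
removes the multiplicative factor from the magnitude and the phase is
unaffected, so the network input is *identical* whatever per-frame
positive gain corrupts the raw signals. The amplitude randomization
during training teaches a model nothing beyond enforcing what the
representation already guarantees; the invariance is a property of
steps 3–5 jointly and is asserted to 1e-6 in the tests (measured
deviations are at the 1e-12 level).

**Numerical choices.** The z-score uses the population (N)
denominator; a channel whose pre-normalization standard deviation
falls below `zscore_tol = 1e-12` is mapped to all zeros with a
degeneracy warning. The DC and Nyquist bins of a real frame are real
up to rounding, and their ±π phase at negative real values is decided
by the sign of ~1e-16 imaginary noise; bins whose imaginary part is
below 1e-9 of their modulus are therefore snapped onto the real axis
before the angle is taken. The criterion is relative, hence itself
scale-invariant, and without it the phase channel of a rescaled frame
can flip between +π and −π at those bins. Phases of other
near-zero-magnitude bins are left exactly as the two-argument
arctangent returns them — deterministic, and their influence is
bounded after z-scoring.

**Labels.** ABP frames are z-scored with ONE global (mean, std) pair
— computed over the training frames — so the inverse transform to
mmHg is well-defined across frames; per-frame label normalization
would destroy the mapping between predicted z-values and absolute
pressure. The pair is stored with the dataset and all reported RMSEs
are computed after inversion to mmHg.

**Randomization policy.** Amplitude gains can be drawn once when a
dataset is materialized (fixed seed, reproducible file) or re-drawn
every epoch as fresh augmentation (`augment=` hook of the trainer /
`fit`). Both modes are exposed; the invariance property makes the
choice immaterial to the trained function's amplitude robustness.

## Networks

**Context aggregation network.** Ten layer groups. Group 1: 2×2
convolution (dilation 1). Groups 2–8: 3×3 convolutions with time-axis
dilation 2, 4, …, 128 and symmetric zero padding equal to the
dilation, so every activation stays 4 × 250 × C; after the ladder the
temporal receptive field spans the whole window (2·(1+2+…+128) > 250).
Dilation is applied along the time axis only: the channel axis has 4
rows, on which paddings of 2–128 would be geometrically impossible.
Every block is convolution → batch normalization → adaptive
normalization → leaky ReLU (slope 0.2). Group 9 is a plain 3×3
convolution block. Group 10 reduces to the output: a 3×3 convolution
to 3 feature maps followed by a learnable linear collapse across the
(4 rows × 3 channels) at each time column, yielding the 250-sample
waveform. The published description of this reduction (4×250×3 →
1×250) underdetermines the operator; the linear collapse is the
simplest differentiable choice and is tested by shape.

**Adaptive normalization** is `y = λ·x + μ·BN(x)` with scalar
learnables initialized to λ=1, μ=0 — the exact identity at
initialization — where BN is a non-affine batch normalization. This
is the standard form in the context-aggregation literature; the layer
is named but not defined in most descriptions.

**Batch normalization** uses mini-batch statistics (population
variance) in training with running-statistic tracking (momentum 0.1)
and running statistics at inference. With mini-batch size 1 the
training-time behaviour coincides with instance normalization;
inference remains deterministic either way.

**LSTM baseline.** One LSTM layer (gate order i, f, g, o; the stacked
input weight matrix has 4·H rows, e.g. 1600 × 2 for 400 hidden units)
followed by a per-timestep linear head, mapping the 2-channel raw
(standardized) ECG/PPG sequence to a 1-channel pressure sequence of
the same length. Forget-gate bias initialized to 1.

**Backend.** Both networks run on a minimal numpy layer library with
hand-written backward passes (`bpwave._nn`), verified against central
finite differences to <1e-6 relative error in the tests. Weight
initialization is variance-scaled uniform (Glorot) from a recorded
seed. Two forward passes in evaluation mode are bitwise identical.

## Training

The optimizer is the adaptive-moment scheme identified by its printed
constants: first/second-moment decay 0.9/0.999, ε = 1e-8, with
classical *coupled* L2 regularization (penalty added to the gradient
before clipping; 1e-4), global L2-norm gradient clipping at threshold
1, and a piecewise schedule that multiplies the learning rate by 0.01
every 125,000 iterations. Published full-scale settings: learning
rate 1e-4, 7000 epochs, mini-batch 1 (convolutional model) and 5e-3,
mini-batch 2, shuffle-once (LSTM). These are bundled as the `paper`
profile.

The `desk` profile is the package's own small-scale configuration —
8 feature channels, 32 hidden units, 40 epochs, mini-batch 8,
learning rate 3e-3 for the convolutional model — chosen so a full
train/evaluate cycle on a ~200-frame synthetic dataset completes in
about two CPU-minutes. Desk-scale accuracy is not expected to match
full-scale accuracy; the properties asserted at desk scale
(optimization makes solvable tasks converge; the robustness contrast
below) do not depend on it.

Per-epoch history records the Eq.-style half-MSE loss, training and
validation RMSE in mmHg (labels inverted with the global statistics),
and the learning rate, which must equal the closed-form schedule
exactly. A non-finite loss aborts with a diagnostic.

## Evaluation protocol

Predictions are inverted to mmHg and summarized per 250-sample frame
by maximum (systolic proxy), minimum (diastolic proxy), mean, and
population standard deviation; the RMSE of each statistic across
frames is reported in the fixed order (max, min, mean, std), alongside
the pointwise RMSE over all samples. The frame maximum/minimum
reading (rather than averaging per-beat peaks inside the window) is
the simplest interpretation consistent with the frame-level protocol
and is noted as a known ambiguity. Resubstitution evaluation scores
the training frames; K-fold cross-validation (default K=5) partitions
frames at random into folds whose sizes differ by at most one, trains
one network per fold on the remainder, and reports per-fold and
arithmetic-mean RMSEs. Folds are frame-level; with real multi-subject
data this admits subject leakage, which is out of scope here.

`compare_pipelines` implements the robustness contrast: both models
are trained on the same record, then evaluated on held-out frames
twice — unperturbed, and with fresh per-frame random gains (uniform on
the amplitude-randomization range) applied to the raw test ECG/PPG
before each pipeline's own input preparation. Because the spectral
input preparation is deterministic given the raw frames and exactly
scale-invariant, the preprocessed pipeline's RMSEs are unchanged to
~1e-14 mmHg; the baseline's inputs change while its weights do not,
and its pointwise RMSE increases (by ~10 mmHg under desk conditions).

## Synthetic data generator

The generator emulates the statistical structure the method assumes,
with defaults chosen as typical resting physiology:

| parameter | default | meaning |
|---|---|---|
| `heart_rate` | 1.2 beats/s | 72 bpm |
| `ptt` | 0.25 s | R-wave → PPG-foot delay |
| `systolic_base` / `diastolic_base` | 120 / 70 mmHg | pressure at the reference transit time |
| `bp_ptt_slope` | −400 mmHg/s | inverse PTT–pressure coupling |
| `drift_amp`, `drift_period` | 0.3, 30 s | multiplicative sensor-gain drift on ECG/PPG |
| `noise_sd` | 0.02 | additive Gaussian noise, fraction of channel amplitude |

The ECG is a train of narrow biphasic wavelets peaking at each beat
time; the ABP is a per-beat raised-cosine upstroke to the systolic
level followed by an exponential decay whose time constant returns the
wave to within a fraction of a mmHg of diastole before the next foot;
the PPG is the (unit-scaled) pressure pulse shape, Gaussian-smoothed
and delayed by the transit time, so its per-beat minimum sits at
R + PTT. Systolic and diastolic levels shift together by
`bp_ptt_slope × (ptt − 0.25 s)`; the 0.25 s anchor is an arbitrary
documented constant. Drift and noise corrupt ECG/PPG only — ABP is
the calibrated label and stays in true mmHg. `sweep_bp_levels` tiles
configured systolic/diastolic ranges linearly (at the anchor transit
time, so configured levels are realized exactly) to cover the
40–180 mmHg band; 1624 s of such data at 125 Hz reproduces the
203,000-sample corpus size.

What the generator does **not** emulate: ECG P/T-wave morphology,
arrhythmia, respiratory modulation, reflected-wave/dicrotic-notch
pressure morphology, movement artifacts, inter-subject variability.
Passing tests on this data therefore demonstrates the pipeline's
mechanics — framing, invariance, optimization, protocol arithmetic,
and the direction of the robustness contrast (which is exact by
construction, not data-dependent) — but not clinical accuracy on
hospital waveforms.

The transit-time estimator used in validation detects R-peaks
(per-beat ECG maxima) and the PPG foot (per-beat minimum after the
R-peak) and takes the median per-beat interval; on noiseless output
it recovers the configured delay within one sample.

## Design choices and limitations

- No deep-learning framework dependency: the numpy backend implements
  exactly the required layers with verified gradients. Full-scale
  (32-channel, 7000-epoch) training is expressible but impractical on
  one CPU; published full-scale accuracies are not reproduced at desk
  scale, by design.
- Whether batch normalization at mini-batch 1 should be read as
  instance normalization is moot here (see above); evaluation uses
  running statistics.
- The 250-vs-500 inconsistency in some printed layer tables is
  resolved to 250 throughout, consistent with every other statement
  of the window size.
- Two dataset-splitting conventions exist in the protocol (sequential
  175k/28k and random 665/35/112 of all 812 frames); both splitters
  are provided (`mode="sequential"` / `"random"`) without adjudicating
  which produced the published numbers.
- The identity-task convergence check uses learning rate 3e-3 with one
  10× step-drop halfway through its 200-epoch run; a constant rate
  leaves a small end-of-run oscillation on that task.
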