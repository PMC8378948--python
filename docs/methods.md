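# Methods

## Problem and model

taskcrnn classifies short clips of task-evoked fMRI into one of seven task
states (Emotion, Gambling, Language, Motor, Relational, Social, Working
Memory). One analysed condition represents each task (Fear, Loss, Story,
LeftHand, Relation, Mental, 2bk_places), with durations 18, 28, 24, 12, 16,
23 and 27.5 s. Input volumes are on the standard 91 × 109 × 91 grid at
TR = 0.72 s and are assumed already registered to template space; the
package does no motion correction, smoothing or alignment.

The classifier is a convolutional-recurrent network. A stack of four
time-distributed 3D convolution blocks (conv → batch-norm → ReLU, valid
padding, no pooling — the first three blocks use stride 2 instead) maps each
of the 20 input frames independently through shared kernels:
7×7×7/32/s2 → 3×3×3/64/s2 → 3×3×3/64/s2, then a *full* convolution 8×10×8/64
whose kernel exactly covers the remaining feature map, giving the shape
chain

    [20,78,93,76,1] → [20,36,44,35,32] → [20,17,21,17,64]
                    → [20,8,10,8,64] → [20,1,1,1,64]

The `[20, 64]` sequence then passes through a single bidirectional LSTM
(64 units per direction, one bias vector per gate, zero initial states,
dropout 0.2 on its outputs during training), additive attention pooling
over the 20 time steps (scores `u_aᵀ·tanh(W_a h_j + b_a)` with a 64-dim
projection, softmax over time, weighted sum → one 128-vector), and a dense
64 (ReLU) → dense 7 (softmax) classifier trained with cross-entropy.

This configuration has 2,882,503 parameters, of which 2,882,055 are
trainable; the 448 non-trainable entries are the batch-norm moving means
and variances (2 × (32+64+64+64)).

### Attention variants

A per-feature "elementwise" pooling variant (`attention="elementwise"`,
parameter-free: softmax over time applied independently per feature,
`c_d = Σ_t softmax_t(h_{·,d}) h_{t,d}`) is available behind a config
switch; additive attention is the default because it is the variant whose
parameter budget matches the totals above (8,320 = 128·64 + 64 + 64).

### Numerical choices

* All tensors are float32; losses and metrics are accumulated in float64.
* Batch-norm normalizes per channel over batch, time and space jointly,
  with ε = 1e−3 and moving-average momentum 0.99; it precedes ReLU.
* Weight initialization is Glorot-uniform from a seeded generator; LSTM and
  batch-norm biases start at zero.
* Cross-entropy uses the log-sum-exp formulation, so probabilities are
  never materialized on the loss path.
* The whole network — forward and backward — is implemented in NumPy, with
  the convolution realized by an im2col/col2im pair so that both passes are
  single matrix multiplications per block.

## Preprocessing

* **Block length.** A block of duration *D* plus an 8 s post-stimulus
  window (covering the hemodynamic lag) spans
  `round((D + 8) / 0.72)` frames, with halves rounded away from zero; this
  is the unique simple rounding rule consistent with the seven published
  frame counts (36, 50, 44, 28, 33, 43, 49). Onsets map to frames by
  `round(onset / TR)`.
* **Crop.** The 91 × 109 × 91 grid is cropped to 78 × 93 × 76 (551,304
  voxels) with leading margins (6, 8, 7) — a centered crop, since the
  discarded border is empty on all sides. Margins are overridable, and
  `proportional_crop` scales them to reduced grids.
* **Augmentation.** Each (subject, task) pair is balanced to exactly 12
  samples: 21-frame windows are drawn with uniformly random start indices,
  with replacement, distributed as evenly as possible across the task's
  blocks (remainder to the earliest blocks; a single-block task contributes
  all 12 windows with re-drawn starts).
* **Differencing and normalization.** Consecutive-frame absolute
  differences turn 21 frames into 20, highlighting temporally changing
  voxels; the result is divided by its scalar maximum over all 20 frames
  (so the global max is exactly 1). The scalar-max reading avoids the
  undefined elementwise division by a frame containing zeros; an all-zero
  clip passes through with a warning.
* **Splits.** All partitioning is by subject: 80/10/10 train/val/test
  (±1 subject when not divisible) and k-fold cross-validation in which
  every subject appears in exactly one test partition. With k = 2 the
  validation subjects are carved out of the non-test half, since rotating a
  whole group would leave no training set.

Open-ended details resolved here: windows are drawn *with* replacement
(re-draws of the same start are legal); the 8 s post-window is extracted
even if it overlaps the next block, exclusion being left to the caller;
0-based indices and half-open windows `[start, start+21)` throughout.

## Training protocol

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−7) at initial learning rate 0.001,
batches of 8. After each epoch validation accuracy is measured; the best
parameters are kept (ties broken by lower validation loss) and training
stops after `patience` (default 10) epochs without improvement, up to
`max_epochs` (default 100). The trainer refuses subject leakage between
train and validation sets. Precision, recall and F1 are macro-averaged
over the seven classes — classes are balanced by construction (12 samples
each), so macro and micro agree up to rounding, and macro is the stricter
convention. Cross-validation summaries are reported as mean ± standard
deviation across folds, rendered "xx.xx% ± y.yy%".

## Synthetic data

The generator emulates exactly the structure the classifier exploits:

* baseline 100 (arbitrary units) everywhere;
* inside one task-specific spherical ROI, a boxcar of the condition's
  blocks convolved with a canonical double-gamma HRF (gamma shapes 6 and
  16, scale 0.9 s, undershoot ratio 1/6; peak ≈ 4.5 s, normalized to 1),
  scaled by `effect_amplitude` (default 3% of baseline, a typical BOLD
  effect);
* Gaussian white noise (`noise_sd`, default 1.0) and a slow sinusoidal
  drift (period 128 s, amplitude 0.5) everywhere.

The seven ROIs sit on a fixed 7-point lattice inside the cropped box, so
spatial signatures are distinct by construction. Block counts per run
follow the canonical table (2, 2, 4, 2, 3, 2, 1); the analysed condition's
blocks are laid out evenly spaced (first onset 7.2 s, separated by the
block duration + 8 s post-window + 8 s rest), which preserves the published
per-block frame counts while keeping simulated runs short. Per-run seeds
are spawned deterministically from the study seed and the (subject, task)
index.

Not emulated: anatomy, spatially correlated or physiological noise, motion,
inter-subject variability of ROI placement, and condition interleaving
within a run. Consequently, passing tests demonstrate that the pipeline
and optimizer work — that preprocessing preserves the activation signal and
the network can localize and use it across subjects — not that the reported
real-data accuracy would be attained.

## Reduced desk-scale profile

Full-size training (91 × 109 × 91 inputs, 2.9 M parameters) is exercised
only analytically. Learning tests and examples use a reduced profile chosen
once as this package's standard small configuration: raw grids of
24 × 28 × 24 voxels cropped proportionally to 20 × 24 × 20, a three-block
conv stack (5³/16/s2 → 3³/32/s2 → full 3×4×3/32) mirroring the full stack's
large-field → conventional → full-conv progression, a 32-unit-per-direction
BiLSTM, 32-dim attention and dense 32 (≈ 74 k trainable parameters); 10
subjects with 4 windows per task each (280 samples, split 8/1/1 subjects).
The separability experiment raises the effect amplitude to 25% of baseline
and lowers the noise to 0.1 with ROI radius 3 — a deliberately
high-contrast regime in which the mean ROI time course alone separates the
tasks, so failure to learn would indicate a defect rather than an SNR
limitation. A shuffled-label control trained identically stays within the
binomial 3σ band of chance (1/7) on held-out subjects, guarding against
leakage through the pipeline.

## Known limitations

* No GPU path; full-size training is impractical in NumPy and out of scope.
* Batch-norm statistics need a few hundred updates to converge; very short
  trainings evaluate with partially converged moving statistics.
* Elementwise attention is implemented for completeness but is not the
  configuration whose parameter count matches the published total.
* Determinism guarantees hold for single-threaded BLAS; across BLAS
  implementations results may differ in the last float32 ulp.
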