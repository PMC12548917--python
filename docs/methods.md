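# Methods

## The decoding problem

Motor-imagery (MI) brain-computer interfaces ask a subject to imagine a
movement (left hand, right hand, feet, tongue) and decode which one from
multichannel EEG. The physical signature is event-related
desynchronization/synchronization (ERD/ERS): imagining a movement
attenuates or amplifies band-limited oscillatory power — mu (~8-12 Hz) and
beta (~18-26 Hz) rhythms — over specific sensorimotor electrodes. A decoder
therefore has to be sensitive to *which frequency band changed power on
which electrodes*, and to how that modulation evolves over the trial.

`midecode` implements a hybrid convolution/attention decoder for epoched
trials `X ∈ R^{C×T}` (C electrodes, T samples; the default geometry is 22
channels, 250 Hz, 4-second epochs, four classes).

## Architecture

The model composes five stages; with `F1` temporal filters and depth
multiplier `D`, the working depth is `F2 = D·F1` (defaults F1=32, D=2,
F2=64).

1. **Spatiotemporal convolution (SC).** A temporal convolution (F1 kernels
   of width 16 samples, same padding, no bias) learns band-pass-like
   filters shared across electrodes; a depthwise spatial convolution of
   kernel (C, 1) with multiplier D then collapses the electrode axis into
   learned spatial patterns. Batch-norm, ELU, average pooling of width 8
   and dropout 0.5 follow, giving a (F2, 1, T/8) map.

2. **Multi-branch separable convolution (MSC).** Three parallel
   depthwise-separable branches with first-layer kernels of 8, 16 and 32
   samples (0.25/0.5/1 s at the post-pooling rate) and pointwise second
   layers; branch filter counts F2/4, F2/4 and F2/2 so the concatenated
   depth is exactly F2. Per-branch BN+ELU, then a shared BN+ELU, a second
   width-8 pooling and dropout produce a (F2, 1, T/64) map — a length-15
   feature sequence for T=1000.

3. **Multi-head self-attention (MSA).** The sequence is layer-normalized
   and passed through m=8 heads of scaled dot-product attention
   (`softmax(QKᵀ/√d_h)` with attention dropout 0.3), concatenated, projected
   by `W^o` and passed through ELU. Sequence length and embedding width are
   unchanged. No residual connection is added by default (`msa_residual`
   restores the transformer-conventional variant); this follows the layer
   table's row sequence, which lists no addition.

4. **Feature fusion + windowed TCN.** The MSC sequence and the attention
   output are concatenated along depth (MSC first) to a (15, 2F2)
   sequence. Three overlapping sliding windows of length 13 pass through a
   *shared-weight* temporal convolutional network: L=2 residual blocks of
   two dilated causal convolutions each (kernel Kt=4, dilation 2^(i-1) in
   block i, no bias, BN/ELU/dropout 0.5 per convolution, identity residual).
   The receptive field is `RFS = 1 + 2(Kt−1)(2^L − 1) = 19 > 13`, so every
   window's final time step sees the whole window. The three last-step
   vectors (2F2 each) concatenate to a 6F2 vector. The window construction
   is the only reading we found consistent with a last-element TCN output of
   size 2F2 and a concatenated feature of size 6F2; the window count is
   configurable (`n_windows`).

5. **Decision fusion.** Two linear heads with max-norm 0.25 — FC1 on the
   flattened MSC map, FC2 on the windowed TCN vector — produce per-class
   logits that are summed element-wise and softmaxed. Element-wise summation
   is the only combination matching the declared Nc-sized output of the
   fusion stage; a literal concat+linear variant is available
   (`decision_fusion_mode="concat_linear"`).

Ablation switches remove one block at a time: `msc` (branch convolutions
bypassed, pooling kept so downstream extents are unchanged), `msa` (the MSC
sequence is fused with itself), `tcn` (MSC head only), `feature_fusion`
(the TCN sees the attention output alone), `decision_fusion` (TCN head
only), `mff` (both fusions off).

## Training protocol

Z-score normalization is fit per channel on training data only and applied
unchanged to validation/test data. The printed form of the normalization
equation divides by the variance δ²; since the procedure is named Z-score
normalization and dividing by variance is unit-inconsistent, the default
divides by the standard deviation; `denominator="variance"` preserves the
literal reading.

The loss is mean cross-entropy on the fused pre-softmax logits. The
optimizer is Adam with learning rate 1e-3, β1=0.9, β2=0.99 and weight decay
1e-3 (L2 coupled into the gradient). After every step the max-norm
constraints are re-projected: linear-head weight columns to 0.25, TCN
kernels to 0.5. Early stopping monitors validation loss once per epoch and
halts after `patience` evaluations without an improvement larger than
`min_delta = 1e-4`, restoring the best-validation weights. Batch size
defaults to 64 (not specified by the protocol source; exposed in
`TrainConfig`).

Within-subject evaluation uses stratified 5-fold cross-validation per
subject: the held-out fold is the test set and a stratified 20% of the
remaining trials is carved out for early stopping (using the test fold
itself for early stopping would leak). Cross-subject evaluation is
leave-one-subject-out: the model trains on the pooled remaining subjects
with a stratified 20% validation carve-out. Per-subject training seeds
derive from the subject id, not the cohort order, so results are
order-independent. Kappa is reported both pooled (over the summed confusion
matrix, the default headline value) and as the mean of per-subject kappas.

## The synthetic cohort

No public EEG download is required: the generator emulates exactly the
structure the decoder exploits. Each class k owns a `ClassSignature`
(center frequency, bandwidth, electrode subset, modulation depth d). A
class-k trial carries the class-k oscillation at amplitude (1+d)×base and
every other signature at (1−d)×base, an amplitude-modulated sinusoid with
per-trial random frequency (within the band) and phase and a ~1 Hz
envelope. Background noise is 60% 1/f-shaped plus 40% white at
`noise_sd`. A row-normalized mixing matrix leaks 10% of every channel into
the others, and per-subject log-normal channel gains (sd
`subject_scale_sd = 0.1`) emulate between-subject variability. Every trial
draws from an independent `SeedSequence(seed, spawn_key=(subject, trial))`
stream, making generation bit-reproducible and order-independent.

At d=0 the classes are statistically identical (verified spectrally and by
a chance-level oracle); own-band power is monotone in d. The default
four-class preset mirrors the 22-channel benchmark geometry; a two-class,
three-channel preset mirrors the smaller benchmark.

What the generator does *not* emulate: volume-conduction head geometry,
EOG/EMG artifacts, non-stationary drifts, inter-session variability and
the heavy class overlap of real MI data. Passing the learning tests
therefore demonstrates that the architecture, gradients and protocol are
correct and that the model can learn genuine band-power/spatial structure
— not that it reaches any particular accuracy on real recordings.

A band-power + nearest-centroid `separability_oracle` (Welch PSD in the
signature bands, 5-fold CV) certifies learnability before any network
result is interpreted: the learning tests require oracle accuracy ≥ 0.90
on the data they train on.

## Numerical implementation

The network and its training loop run on a small reverse-mode autograd
engine over numpy arrays (`midecode.nn`): broadcasting arithmetic, batched
matmul, a generic two-operand einsum, a grouped/dilated 1-D convolution
primitive with an im2col GEMM fast path, fused batch/layer normalization
with an analytic backward, and ELU. Every primitive's gradient is checked
against central finite differences in the test suite, and the attention and
TCN blocks are additionally checked against independent brute-force
evaluations with hand-set weights. All model arithmetic is float32 (Adam
moments in float64); python-scalar operands adopt the tensor dtype so
graphs never silently promote.

Choices where the source is silent: batch-norm momentum 0.1 and eps 1e-5
(framework convention), biased variance for both normalization and running
estimates; Glorot-uniform fan-based initialization from a seeded generator;
stratified folds with a fixed seed; pooling uses floor division (T=1000
gives 125 and then 15 steps; the nominal "32 Hz" post-pooling rate is
250/8 = 31.25 Hz). Strict TCN causality holds in evaluation mode; in
training mode batch-norm's batch statistics couple time positions, as in
any batch-normalized TCN.

## Desk-scale study sizes

The default test run and the acceptance checks must finish on one CPU, so
the learning experiments use reduced problem sizes chosen once: a reduced
model (F1=8, D=2), one synthetic subject with 18 trials per class,
high-SNR conditions (modulation depth 0.8, noise sd 0.5), 100-epoch budget
with early-stopping patience 15 for the learning criterion (within the
stated 200-epoch envelope), and the two-class three-channel preset with a
60-epoch budget for the paired ablation comparison (3 seeds, single
stratified train/val/test split per seed). The structural suites (shape
contract, causality, conservation, oracle equivalence) run the full-size
default architecture, which is cheap in forward mode.

## Known limitations

- Training on the full 22-channel geometry at F1=32 is slow in pure numpy
  (minutes per fold); the package is a faithful reference implementation,
  not a performance-tuned trainer.
- The GDF reader wraps `mne.io.read_raw_gdf`; GDF files cannot be written
  offline, so the round-trip test exercises the same epoch-cutting path
  through an in-memory `RawArray` instead.
- The Wilcoxon comparison delegates to scipy; its zero-difference/tie
  policy ("wilcox" zero handling, exact distribution for small samples
  without ties) applies.
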