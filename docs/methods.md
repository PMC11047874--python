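# Methods

## Overview

`ecgcycle` implements a two-stage pipeline for ambulatory ECG analysis on
8-lead recordings:

1. **Denoising** by unpaired domain translation: a cycle-consistent
   adversarial model whose generators are denoising autoencoders (DAE),
   with an unsupervised DAE pre-training stage that initialises the
   generators and accelerates convergence.
2. **Multi-label arrhythmia classification** over a 34-class vocabulary by a
   parallel-branch temporal convolutional network (TCN) with a 2-D
   convolutional, residual front end spanning all leads.

Because no clinical corpus ships with the package, a synthetic signal module
generates the study data: quasi-periodic 8-lead ECG with controllable rhythm
classes, multi-hot labels, configurable class imbalance, and three noise
families (Gaussian white noise, baseline wander, impulse noise) scalable to
an exact target SNR.

## Synthetic data model

Each beat is a sum of five Gaussian bumps — one per P, Q, R, S, T wave — with
per-wave centre (s, relative to the R peak), width (s) and amplitude (mV).
Defaults: P (−0.20, 0.030, 0.15), Q (−0.035, 0.012, −0.12), R (0, 0.014,
1.0), S (0.035, 0.013, −0.25), T (0.26, 0.060, 0.35). Beats repeat at RR
intervals 60/HR · (1 + v·z), z ~ N(0,1) clipped to ±0.45, where HR is the
heart rate (bpm) and v the RR-jitter coefficient. The single source waveform
is projected to the 8 independent leads (I, II, V1–V6) by a fixed, seeded
per-lead gain vector with leads I and II anchored at 1.0 and 1.1, so the
augmented-lead identities (III = II − I, aVR = −(I+II)/2, aVL = I − II/2,
aVF = II − I/2) remain meaningful. Everything is a pure function of
(spec, seed).

Label vocabulary (34 slots): six slots are mechanistically synthesisable —
sinus rhythm, sinus tachycardia (>100 bpm), sinus bradycardia (<60 bpm),
sinus arrhythmia (RR coefficient of variation > 0.12), T-wave change
(inverted/attenuated T), low-voltage QRS (Q, R, S amplitudes × 0.35). The
remaining 28 slots perturb the amplitude and width of two seeded-randomly
chosen waves; they exercise the 34-way head without claiming clinical
realism. Rate-class samples draw rates inside their defining band; all other
classes draw 65–95 bpm so the rate-derived label bits stay consistent. The
default sampling weights decay geometrically (0.8^k), emulating the strong
class imbalance of real arrhythmia corpora.

Noise: white Gaussian; baseline wander as a sum of low-frequency sinusoids
(default 0.15 and 0.3 Hz, random phases per lead); impulse noise as sparse
random-sign spikes (default probability 0.01); and composites. When a target
SNR (dB) is requested the noise is rescaled **per lead** so that
10·log10(ΣX²/Σn²) hits the target exactly.

What the generator does *not* emulate: real PQRST morphology variation
within a record, ectopic beats, electrode artefacts, inter-patient
variability, or realistic 12-lead spatial structure (the projection is
rank-1). Passing tests therefore demonstrate that the algorithms behave as
designed under controlled conditions, not clinical performance.

## Denoiser

**Generators** (G_N2C noisy→clean, G_C2N clean→noisy) are mirror-symmetric
encoder/decoders over single-lead segments: five down-sampling blocks
(1-D convolution, stride 2, kernel 16 → instance norm → tanh) with channels
doubling from a base width (default 16), and five mirrored up-sampling
blocks (1-D transposed convolution → instance norm → tanh). The output block
omits the instance norm: normalising the final layer would pin every
denoised window to a single fixed mean/std, making per-window amplitude
unrepresentable (in development this single change raised window-level SNR
after denoising from ~1 dB to ~6 dB). Input lengths must be divisible by
2^5 = 32.

**Discriminators** are five such down-sampling blocks plus one final 1-D
convolution producing a patch-style realness score map; probabilities are
sigmoid scores averaged over the map.

**Losses.** The reported total is

    Loss = Loss_GAN + α·Loss_cycle + β·Loss_identity,    α = 10, β = 5,

with Loss_GAN the two-direction saturating log value function (log terms
clamped at 1e-7; a maximally uncertain discriminator scores 4·log 0.5),
Loss_cycle the mean L1 of both round trips, and Loss_identity the mean L1 of
each generator applied to its *output*-domain samples. α and β follow
standard cycle-consistency weighting and are exposed in the config.

**Parameter updates** use the least-squares adversarial surrogate on the raw
score maps (real → 1, fake → 0) rather than the clamped log form: once the
discriminator wins, the clamped log gives the generators a zero adversarial
gradient and the cycle + identity terms then collapse both generators toward
the identity map. The least-squares surrogate keeps the gradient informative
at every discriminator confidence. Optimiser: Adam, lr 1e-3 for both sides
(at desk-scale step budgets a smaller rate cannot traverse the required
parameter displacement), batch 16.

**Normalisation convention.** Segments enter the generator in *corrupted-
window coordinates*: u = (x − mean(ref)) / span(ref), where ref is the
corrupted signal whose window is being processed (for the clean-domain
training corpus, ref is the segment plus simulated noise at the study level).
Two reasons:

- the instance-normalised stack cannot propagate absolute window means, and
  under zero-mean noise the corrupted window's mean estimates the clean
  window's mean to ~1% of the span — so the mean is carried around the
  network instead of through it;
- the adversarially learned clean domain then has the same amplitude
  convention that inference uses when restoring a denoised window, removing
  a systematic scale error.

Consequence: baseline components slower than one window are treated as
signal and are not corrected; wander removal acts only on within-window
variation.

**Pre-training.** Each generator is pre-trained as a denoising autoencoder
on its output domain (G_N2C on clean segments, G_C2N on noisy segments):
reconstruct the segment from a copy corrupted with simulated noise, L1
objective, default 20 epochs. This is the initialisation stage the model
comparison isolates: with identical evaluation batches, median initial total
loss over three seeds is markedly lower with pre-training than with either
fan-in-uniform or N(0, 0.02²) initialisation.

**Training** alternates a generator step (least-squares adversarial +
α·cycle + β·identity) and a discriminator step per batch, with unpaired,
independently shuffled corpora. A divergence guard aborts if the total loss
exceeds ten times its initial value for three consecutive epochs. Inference
denoises records lead by lead in non-overlapping windows of the training
segment length (stored on the model), each mapped through the window
coordinates above.

## Classifier

Input is an (8 × T) record, per-lead z-scored. The front end is a causal
convolution spanning all 8 leads with temporal kernel 50 inside a residual
block (1×1 projection skip, ReLU). Causal (left-only) padding is used
throughout — including the front end — so that no feature at position t
depends on samples after t; this is verified by perturbation, not assumed.

Three parallel TCN branches (kernels 3, 5, 7; default width 64) each stack
three blocks with dilation factors 1, 2, 4; a block holds two
weight-normalised dilated causal convolutions (ReLU, dropout 0.1) and a
residual skip with 1×1 projection when widths differ. The receptive field
of a branch is

    field = (k − 1) · Σd · n + 1

giving 29, 57 and 85 samples for the three default branches; 85 is the
model's maximum, and shorter-range features are captured repeatedly by the
narrower branches. The head applies global average pooling over time per
branch, concatenates, and maps through one linear layer of width 34.
Presets `model_1` … `model_5` reproduce the architecture sweep (single
branches k = 3/5/7; the parallel default; parallel with dilations 1, 4, 8).

**Imbalance handling.** Training minimises the class-weighted binary cross
entropy, loss_n = −w_n[y_n log x_n + (1−y_n) log(1−x_n)], computed from
logits in the numerically stable form. Default weights are inverse-frequency
(w_c ∝ total/count_c), capped at 100× the smallest weight, mean-normalised;
zero-count classes receive the cap. A literal "proportional to the class
count" policy is also selectable, but up-weighting majority classes works
against the stated purpose of countering imbalance, so it is not the
default. Focal (γ=2, α=0.25) and MSE objectives are available for the loss
comparison. Reported metrics include subset accuracy and micro/macro
precision/recall/F1, since "accuracy" is ambiguous for multi-label output.

## Desk-scale study conditions

The heavy properties run the full method end to end at sizes chosen for a
single CPU:

- denoiser corpus: 500 single-lead segments of 512 samples at 250 Hz, drawn
  from 30 synthetic records; the window length (2.05 s) covers the slowest
  synthesised RR interval (1.5 s at 40 bpm) so every window contains a beat;
- compact widths (base 8 channels) for the scaled denoiser runs; public
  defaults stay at base 16;
- adversarial budget 20 epochs, DAE pre-training 30 epochs, study corruption
  0 dB Gaussian; evaluation on 40 held-out records;
- classifier properties use 2.56 s records at 125 Hz, 16-channel branches:
  an 80/20 imbalanced two-class task (160 training, 120 held-out records,
  3 seeds) for the weighted-loss comparison, and a three-class separable
  task for the learning check.

## Numerical choices and degenerate inputs

- float32 throughout the networks; seeded numpy everywhere, so training
  trajectories are bitwise reproducible on a fixed BLAS.
- SNR of identical signals is reported as +inf, never an exception; SNR of
  multi-lead records is the mean of per-lead values.
- log terms in losses and metrics are clamped at 1e-7.
- Constant leads normalise to zero (z-score and minmax); zero-span windows
  pass through the denoiser unscaled.
- Segmentation uses 0-based, half-open windows; `drop_tail` yields
  ⌊(T − window)/hop⌋ + 1 segments.
- R-peak detection (used by label-consistency checks) requires peaks to
  clear half the lead maximum, be 250 ms apart, and be QRS-narrow — the
  width bound keeps broad T waves out of the count on low-voltage records.

## Known limitations

- Leads are denoised independently; joint multi-lead denoising is untested.
- The denoiser treats sub-window-frequency baseline as signal (see above).
- Only six label slots have mechanistic synthesis; conclusions about the
  remaining 28 concern the training machinery, not arrhythmia biology.
- The unpaired translation cannot recover absolute amplitude beyond the
  window-coordinate convention; amplitude fidelity rests on the corrupted
  window's minmax being signal-dominated.
- Training budgets here are orders of magnitude below a clinical study;
  the properties verified are directional (pre-training lowers initial loss,
  denoising raises SNR, weighting protects minority recall), not absolute
  performance claims.
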