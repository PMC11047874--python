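# ecgcycle

Cycle-consistent ECG denoising and multi-label arrhythmia classification for
8-lead recordings, with a synthetic signal simulator standing in for
clinical data.

Ambulatory and at-home ECG sensors pick up noise — white sensor noise,
respiration-driven baseline wander, motion impulses — that corrupts the
morphology downstream rhythm analysis depends on, and clean/noisy signal
pairs cannot be collected from a living subject. `ecgcycle` addresses both
problems for researchers and engineers prototyping m-health ECG pipelines:

- **`CycleGanDenoiser`** learns noisy→clean translation *without paired
  examples*: two denoising-autoencoder generators G_N2C and G_C2N and two
  patch discriminators D_N2C, D_C2N are trained on the combined objective

      Loss = Loss_GAN + α·Loss_cycle + β·Loss_identity      (α=10, β=5)

  where Loss_cycle = E‖G_C2N(G_N2C(n)) − n‖₁ + E‖G_N2C(G_C2N(c)) − c‖₁ and
  Loss_identity penalises each generator for altering samples already in its
  output domain. An unsupervised DAE pre-training stage (reconstruct a
  segment from a simulated-noise-corrupted copy) initialises the generators
  and demonstrably lowers the initial loss.

- **`TcnClassifier`** maps an (8 × T) record to 34 per-class probabilities
  through a causal residual front end (temporal kernel 50 across all leads)
  and three parallel temporal-convolutional branches with kernels k = 3, 5,
  7, dilation factors d = 1, 2, 4 and n = 2 causal convolutions per block.
  Each branch sees a receptive field of

      field = (k − 1) · Σd · n + 1   →   29, 57, 85 samples,

  and class imbalance is countered by a class-weighted binary cross entropy
  loss_n = −w_n[y_n log x_n + (1−y_n) log(1−x_n)] with inverse-frequency
  weights.

- **`ecgcycle.ecgsynth`** generates the study data: sum-of-Gaussians PQRST
  beats at controlled heart rates, 34-slot multi-hot labels with
  configurable imbalance, and Gaussian / baseline-wander / impulse noise
  scaled to an exact target SNR (10·log₁₀ ΣX²/Σ(X−Y)², in dB).

Both estimators follow scikit-learn conventions (`fit`/`transform` or
`fit`/`predict_proba`, `get_params`, fitted attributes with trailing
underscores) and compose with sklearn tooling; the neural networks run on a
compact numpy autodiff core bundled with the package, so there is no GPU or
deep-learning-framework dependency.

## Worked example

```python
import numpy as np
from ecgcycle import (
    RhythmSpec, NoiseSpec, generate_clean, corrupt, make_dataset, snr,
    receptive_field, TcnBranchConfig,
)
from ecgcycle import denoise_gan as dg
from ecgcycle.metrics import evaluate_denoiser

# a 10 s, 250 Hz clean record at 60 bpm, corrupted at exactly 0 dB
record = generate_clean(RhythmSpec(heart_rate_bpm=60), 10.0, 250.0, seed=1)
noisy, _ = corrupt(record, NoiseSpec(target_snr_db=0.0, seed=2))
print(f"SNR of corrupted record: {snr(record.signal, noisy.signal):.2f} dB")

# receptive fields of the three default classifier branches
print([receptive_field(TcnBranchConfig(k)) for k in (3, 5, 7)])

# pre-train a compact denoising generator on 16 synthetic records and
# measure before/after quality on 5 held-out records
train = make_dataset(16, noise=NoiseSpec(target_snr_db=0.0, seed=3), seed=3,
                     duration_s=10.0, fs=250.0)
clean_corpus = dg.prepare_segments(
    [c for c, _, _ in train], window=512,
    noise=NoiseSpec(target_snr_db=0.0, seed=4), seed=4,
)
model = dg.build_denoiser(dg.GeneratorConfig(base_channels=8),
                          dg.DiscriminatorConfig(base_channels=8), seed=0)
dg.pretrain_generator(model.g_n2c, clean_corpus,
                      NoiseSpec(target_snr_db=0.0, seed=0), epochs=10)
model.window = 512

test = make_dataset(5, noise=NoiseSpec(target_snr_db=0.0, seed=9), seed=9,
                    duration_s=10.0, fs=250.0)
report = evaluate_denoiser(lambda r: dg.denoise(model, r),
                           [(c, n) for c, n, _ in test])
print(f"mean SNR before: {report.mean_snr_before_db:.2f} dB, "
      f"after: {report.mean_snr_after_db:.2f} dB")
print(f"mean MSE before: {report.mean_mse_before:.4f}, "
      f"after: {report.mean_mse_after:.4f}")
```

prints

```
SNR of corrupted record: 0.00 dB
[29, 57, 85]
mean SNR before: -0.00 dB, after: 8.41 dB
mean MSE before: 0.0468, after: 0.0070
```

The corruption hits its 0 dB target exactly (noise power equals signal
power); the three parallel branches span 29, 57 and 85 samples; and ten
epochs of DAE pre-training alone recover ~8 dB of signal quality on
held-out records corrupted at 0 dB. A command-line interface (`ecgcycle simulate / pretrain /
train-denoiser / denoise / train-classifier / classify / evaluate`) wraps
the same functions for shell use.

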