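"""Cycle-consistent adversarial ECG denoiser with denoising-autoencoder generators.

Two mirror-symmetric encoder/decoder generators translate between the noisy
domain N and the clean domain C without paired examples; two patch-style
discriminators judge each domain.  Training combines the adversarial value
function, a cycle-consistency L1 term and an identity L1 term,

    Loss = Loss_GAN + alpha * Loss_cycle + beta * Loss_identity,

and the generators can be initialised by unsupervised denoising-autoencoder
pre-training: each generator learns to reconstruct samples of its *output*
domain from copies corrupted with simulated noise, which lowers the initial
total loss and speeds convergence.

Generators: five down-sampling blocks (conv1d -> instancenorm1d -> tanh) and
five mirrored up-sampling blocks (convtranspose1d -> instancenorm1d -> tanh).
Discriminators: five such down-sampling blocks plus one final 1-D convolution
producing a realness score map.  Leads are denoised independently through the
single-channel generator.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from ._autograd import Tensor
from ._nn import Adam, Conv1d, ConvTranspose1d, InstanceNorm1d, Module, Sequential, Tanh
from .ecgsynth import EcgRecord, NoiseSpec, ParameterError, sample_noise

_EPS = 1e-7  # clamping floor for the saturating log terms


class TrainingDiverged(RuntimeError):
    """Raised when the total loss blows past the divergence guard."""


@dataclass
class GeneratorConfig:
    n_blocks: int = 5
    base_channels: int = 16
    kernel_size: int = 16
    stride: int = 2

    def __post_init__(self):
        if self.n_blocks < 1:
            raise ParameterError("generator needs at least one block")
        if (self.kernel_size - self.stride) % 2 != 0:
            raise ParameterError(
                "kernel_size - stride must be even for mirror-symmetric lengths"
            )

    @property
    def divisor(self) -> int:
        return self.stride**self.n_blocks


@dataclass
class DiscriminatorConfig:
    n_blocks: int = 5
    base_channels: int = 16
    kernel_size: int = 16
    stride: int = 2

    def __post_init__(self):
        if self.n_blocks < 1:
            raise ParameterError("discriminator needs at least one block")
        if (self.kernel_size - self.stride) % 2 != 0:
            raise ParameterError("kernel_size - stride must be even")


@dataclass
class DenoiserTrainConfig:
    alpha: float = 10.0  # cycle-consistency weight
    beta: float = 5.0  # identity weight
    lr: float = 1e-3
    batch_size: int = 16
    epochs: int = 20
    seed: int = 0
    pretrain: str = "dae_pretrain"  # or "none"
    pretrain_epochs: int = 20
    pretrain_noise: NoiseSpec | None = None
    init: str = "uniform"  # or "normal"

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ParameterError("loss weights must be non-negative")
        if self.pretrain not in ("none", "dae_pretrain"):
            raise ParameterError(f"unknown pretrain mode {self.pretrain!r}")
        if self.pretrain_noise is None:
            self.pretrain_noise = NoiseSpec(
                kind="gaussian_white", target_snr_db=5.0, seed=self.seed
            )


@dataclass
class LossBreakdown:
    """The loss components tracked per epoch (generator-side aggregation)."""

    loss_gan: float
    loss_cycle: float
    loss_identity: float
    loss_G: float
    loss_D: float
    total: float


class Generator(Module):
    """Mirror-symmetric DAE generator: (N, 1, T) -> (N, 1, T)."""

    def __init__(self, cfg: GeneratorConfig, rng=None, init: str = "uniform"):
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        k, s = cfg.kernel_size, cfg.stride
        pad = (k - s) // 2
        channels = [1] + [cfg.base_channels * 2**i for i in range(cfg.n_blocks)]
        self.down_blocks = [
            Sequential(
                Conv1d(channels[i], channels[i + 1], k, stride=s,
                       padding=(pad, pad), rng=rng, init=init),
                InstanceNorm1d(channels[i + 1]),
                Tanh(),
            )
            for i in range(cfg.n_blocks)
        ]
        rev = channels[::-1]
        # the output block skips instance norm: normalising the final layer
        # would pin every output window to one fixed mean/std, making
        # per-window amplitude unrepresentable
        self.up_blocks = [
            Sequential(
                ConvTranspose1d(rev[i], rev[i + 1], k, stride=s, padding=pad,
                                rng=rng, init=init),
                *([] if i == cfg.n_blocks - 1 else [InstanceNorm1d(rev[i + 1])]),
                Tanh(),
            )
            for i in range(cfg.n_blocks)
        ]

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] % self.cfg.divisor != 0:
            raise ValueError(
                f"input length {x.shape[-1]} must be divisible by "
                f"{self.cfg.divisor} (stride^n_blocks)"
            )
        for blk in self.down_blocks:
            x = blk(x)
        for blk in self.up_blocks:
            x = blk(x)
        return x


class Discriminator(Module):
    """Five down-sampling blocks plus one final 1-D convolution (score map)."""

    def __init__(self, cfg: DiscriminatorConfig, rng=None, init: str = "uniform"):
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        k, s = cfg.kernel_size, cfg.stride
        pad = (k - s) // 2
        channels = [1] + [cfg.base_channels * 2**i for i in range(cfg.n_blocks)]
        self.blocks = [
            Sequential(
                Conv1d(channels[i], channels[i + 1], k, stride=s,
                       padding=(pad, pad), rng=rng, init=init),
                InstanceNorm1d(channels[i + 1]),
                Tanh(),
            )
            for i in range(cfg.n_blocks)
        ]
        self.final_conv = Conv1d(channels[-1], 1, 3, padding=(1, 1), rng=rng, init=init)

    def forward(self, x: Tensor) -> Tensor:
        for blk in self.blocks:
            x = blk(x)
        return self.final_conv(x)


@dataclass
class DenoiserModel:
    """Paired generators and discriminators plus their configs.

    ``window`` records the segment length the model was trained on; record
    denoising processes leads in windows of that length so the normalisation
    statistics match training.
    """

    g_n2c: object
    g_c2n: object
    d_n2c: object
    d_c2n: object
    gen_config: GeneratorConfig = field(default_factory=GeneratorConfig)
    disc_config: DiscriminatorConfig = field(default_factory=DiscriminatorConfig)
    window: int | None = None


def build_generator(cfg: GeneratorConfig | None = None, seed: int = 0,
                    init: str = "uniform") -> Generator:
    return Generator(cfg or GeneratorConfig(), np.random.default_rng(seed), init)


def build_discriminator(cfg: DiscriminatorConfig | None = None, seed: int = 0,
                        init: str = "uniform") -> Discriminator:
    return Discriminator(cfg or DiscriminatorConfig(), np.random.default_rng(seed), init)


def build_denoiser(
    gen_config: GeneratorConfig | None = None,
    disc_config: DiscriminatorConfig | None = None,
    seed: int = 0,
    init: str = "uniform",
) -> DenoiserModel:
    gen_config = gen_config or GeneratorConfig()
    disc_config = disc_config or DiscriminatorConfig()
    ss = np.random.SeedSequence(seed).spawn(4)
    return DenoiserModel(
        g_n2c=Generator(gen_config, np.random.default_rng(ss[0]), init),
        g_c2n=Generator(gen_config, np.random.default_rng(ss[1]), init),
        d_n2c=Discriminator(disc_config, np.random.default_rng(ss[2]), init),
        d_c2n=Discriminator(disc_config, np.random.default_rng(ss[3]), init),
        gen_config=gen_config,
        disc_config=disc_config,
    )


# -- losses -----------------------------------------------------------------------


def _as_batch(batch: np.ndarray) -> Tensor:
    batch = np.asarray(batch, dtype=float)
    if batch.ndim != 2 or batch.shape[0] == 0:
        raise ParameterError("batch must be a nonempty (n_segments, T) matrix")
    return Tensor(batch[:, None, :])


def _prob(disc, x: Tensor) -> Tensor:
    """Per-sample realness probability: score map -> sigmoid -> mean."""
    return disc(x).sigmoid().mean(axis=(1, 2))


def adversarial_loss(model: DenoiserModel, batch_n, batch_c) -> float:
    """Two-direction saturating GAN value function (log terms clamped at 1e-7).

    Discriminator log-likelihood on real samples plus log(1 - D(G(.))) on
    generated samples, summed over both translation directions.  A maximally
    uncertain discriminator (0.5 everywhere) yields 4*log(0.5).
    """
    tn, tc = _as_batch(batch_n), _as_batch(batch_c)
    fake_c = model.g_n2c(tn)
    fake_n = model.g_c2n(tc)
    terms = (
        _prob(model.d_n2c, tc),
        1.0 - _prob(model.d_n2c, fake_c),
        _prob(model.d_c2n, tn),
        1.0 - _prob(model.d_c2n, fake_n),
    )
    return float(sum(t.clamp(_EPS, 1.0).log().mean().item() for t in terms))


def cycle_loss(model: DenoiserModel, batch_n, batch_c) -> float:
    """Mean L1 of the two round-trip residuals (both directions)."""
    tn, tc = _as_batch(batch_n), _as_batch(batch_c)
    back_n = model.g_c2n(model.g_n2c(tn))
    back_c = model.g_n2c(model.g_c2n(tc))
    return float(
        (back_n - tn).abs().mean().item() + (back_c - tc).abs().mean().item()
    )


def identity_loss(model: DenoiserModel, batch_n, batch_c) -> float:
    """Mean L1 of G_C2N on noise samples plus G_N2C on clean samples."""
    tn, tc = _as_batch(batch_n), _as_batch(batch_c)
    return float(
        (model.g_c2n(tn) - tn).abs().mean().item()
        + (model.g_n2c(tc) - tc).abs().mean().item()
    )


def total_loss(parts: LossBreakdown, cfg: DenoiserTrainConfig) -> float:
    """Weighted total: Loss_GAN + alpha*Loss_cycle + beta*Loss_identity."""
    return parts.loss_gan + cfg.alpha * parts.loss_cycle + cfg.beta * parts.loss_identity


def loss_breakdown(model: DenoiserModel, batch_n, batch_c,
                   cfg: DenoiserTrainConfig) -> LossBreakdown:
    """Evaluate all loss components of the current model on one batch pair."""
    gan = adversarial_loss(model, batch_n, batch_c)
    cyc = cycle_loss(model, batch_n, batch_c)
    idt = identity_loss(model, batch_n, batch_c)
    parts = LossBreakdown(gan, cyc, idt, loss_G=np.nan, loss_D=np.nan, total=np.nan)
    parts.total = total_loss(parts, cfg)
    return parts


# -- corpus preparation -----------------------------------------------------------


def prepare_segments(records, window: int, noise: NoiseSpec | None = None,
                     seed: int = 0) -> np.ndarray:
    """Single-lead training segments in [-1, 1] from multi-lead records.

    Records are cut into non-overlapping windows; every lead contributes its
    windows independently.  Without `noise`, each segment is scaled by its own
    minmax (the convention for the noisy-domain corpus, whose samples *are*
    corrupted signals).  With `noise`, each segment is scaled by the minmax of
    a simulated-noise-corrupted copy of itself — corrupted-signal coordinates,
    the convention for the clean-domain corpus, so that the clean domain the
    adversary learns matches the amplitude convention used when a denoised
    window is restored at inference time.
    """
    from .signal_io import SegmentationConfig, segment

    cfg = SegmentationConfig(window_samples=window, hop_samples=window)
    rows = [seg.signal for rec in records for seg in segment(rec, cfg)]
    if not rows:
        raise ParameterError("no complete windows: records shorter than `window`")
    x = np.concatenate(rows, axis=0)
    if noise is None:
        ref = x
    else:
        rng = np.random.default_rng(seed)
        ref = x + sample_noise(x, noise, rng=rng)
    return _to_window_coords(x, ref)[0]


def _to_window_coords(x: np.ndarray, ref: np.ndarray):
    """Mean-centred, span-scaled coordinates: u = (x - mean(ref)) / span(ref).

    The reference is the corrupted signal whose window is being denoised; its
    mean is a near-unbiased estimator of the clean window mean under
    zero-mean noise, so the generator never has to represent absolute
    baseline level (the instance-normalised stack discards means anyway).
    """
    mu = ref.mean(axis=1, keepdims=True)
    span = ref.max(axis=1, keepdims=True) - ref.min(axis=1, keepdims=True)
    span = np.where(span > 0, span, 1.0)
    return (x - mu) / span, (mu, span)


def _from_window_coords(u: np.ndarray, params) -> np.ndarray:
    mu, span = params
    return u * span + mu


# -- training ---------------------------------------------------------------------


def pretrain_generator(
    gen: Generator,
    corpus: np.ndarray,
    noise: NoiseSpec,
    epochs: int,
    seed: int = 0,
    lr: float = 1e-3,
    batch_size: int = 16,
) -> Generator:
    """Denoising-autoencoder pre-training: reconstruct each corpus segment
    from a simulated-noise-corrupted copy under an L1 objective.

    Each corrupted copy is affinely rescaled to [-1, 1] and the
    reconstruction target is expressed in the *same* coordinates — the exact
    convention used when a raw noisy window is normalised at inference time,
    so the pre-trained generator and the deployment pipeline agree on
    amplitude scale.
    """
    corpus = np.asarray(corpus, dtype=float)
    if corpus.ndim != 2 or corpus.shape[0] == 0:
        raise ParameterError("pre-training corpus must be a nonempty (n, T) matrix")
    if epochs == 0:
        return gen
    rng = np.random.default_rng(seed)
    opt = Adam(gen.parameters(), lr=lr)
    n = corpus.shape[0]
    bs = min(batch_size, n)
    for _ in range(epochs):
        perm = rng.permutation(n)
        for start in range(0, n - bs + 1, bs):
            target = corpus[perm[start : start + bs]]
            corrupted = target + sample_noise(target, noise, rng=rng)
            x_in, params = _to_window_coords(corrupted, corrupted)
            x_tgt, _ = _to_window_coords(target, corrupted)
            out = gen(Tensor(x_in[:, None, :]))
            loss = (out - Tensor(x_tgt[:, None, :])).abs().mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
    return gen


def train_denoiser(
    noisy_segments: np.ndarray,
    clean_segments: np.ndarray,
    cfg: DenoiserTrainConfig | None = None,
    model: DenoiserModel | None = None,
    gen_config: GeneratorConfig | None = None,
    disc_config: DiscriminatorConfig | None = None,
) -> tuple[DenoiserModel, list[LossBreakdown]]:
    """Adversarial training on unpaired noisy/clean corpora.

    The corpora are (n, T) matrices of single-lead segments scaled to [-1, 1];
    they need not be paired or equally sized.  Returns the trained model and a
    per-epoch trace of all loss components.  Raises :class:`TrainingDiverged`
    if the total loss exceeds ten times its initial value for three
    consecutive epochs.
    """
    cfg = cfg or DenoiserTrainConfig()
    noisy = np.asarray(noisy_segments, dtype=float)
    clean = np.asarray(clean_segments, dtype=float)
    for name, arr in (("noisy", noisy), ("clean", clean)):
        if arr.ndim != 2 or arr.shape[0] == 0:
            raise ParameterError(f"{name} corpus must be a nonempty (n, T) matrix")
    rng = np.random.default_rng(cfg.seed)
    if model is None:
        model = build_denoiser(gen_config, disc_config, seed=cfg.seed, init=cfg.init)
    if cfg.pretrain == "dae_pretrain" and cfg.pretrain_epochs > 0:
        # each generator learns to project noise-perturbed inputs onto its
        # output domain: G_N2C onto clean, G_C2N onto noisy
        pretrain_generator(model.g_n2c, clean, cfg.pretrain_noise,
                           cfg.pretrain_epochs, seed=cfg.seed + 101, lr=cfg.lr,
                           batch_size=cfg.batch_size)
        pretrain_generator(model.g_c2n, noisy, cfg.pretrain_noise,
                           cfg.pretrain_epochs, seed=cfg.seed + 202, lr=cfg.lr,
                           batch_size=cfg.batch_size)

    opt_g = Adam(model.g_n2c.parameters() + model.g_c2n.parameters(), lr=cfg.lr)
    opt_d = Adam(model.d_n2c.parameters() + model.d_c2n.parameters(), lr=cfg.lr)
    bs = min(cfg.batch_size, len(noisy), len(clean))
    n_batches = max(1, min(len(noisy), len(clean)) // bs)
    trace: list[LossBreakdown] = []
    over_guard = 0
    for _ in range(cfg.epochs):
        perm_n = rng.permutation(len(noisy))
        perm_c = rng.permutation(len(clean))
        sums = np.zeros(5)  # gan, cycle, identity, loss_G, loss_D
        for b in range(n_batches):
            bn = noisy[perm_n[b * bs : (b + 1) * bs]]
            bc = clean[perm_c[b * bs : (b + 1) * bs]]
            tn, tc = _as_batch(bn), _as_batch(bc)

            # generator update; least-squares adversarial surrogate on the raw
            # score maps (gradient does not vanish when the discriminator wins)
            fake_c = model.g_n2c(tn)
            fake_n = model.g_c2n(tc)
            s_fc = model.d_n2c(fake_c)
            s_fn = model.d_c2n(fake_n)
            adv_g = ((s_fc - 1.0) ** 2).mean() + ((s_fn - 1.0) ** 2).mean()
            cyc = (
                (model.g_c2n(fake_c) - tn).abs().mean()
                + (model.g_n2c(fake_n) - tc).abs().mean()
            )
            idt = (
                (model.g_c2n(tn) - tn).abs().mean()
                + (model.g_n2c(tc) - tc).abs().mean()
            )
            g_obj = adv_g + cfg.alpha * cyc + cfg.beta * idt
            opt_g.zero_grad()
            g_obj.backward()
            opt_g.step()

            # discriminator update on detached fakes (least-squares targets)
            fc = Tensor(fake_c.data)
            fn = Tensor(fake_n.data)
            s_rc = model.d_n2c(tc)
            s_fc2 = model.d_n2c(fc)
            s_rn = model.d_c2n(tn)
            s_fn2 = model.d_c2n(fn)
            d_obj = 0.5 * (
                ((s_rc - 1.0) ** 2).mean() + (s_fc2**2).mean()
                + ((s_rn - 1.0) ** 2).mean() + (s_fn2**2).mean()
            )
            opt_d.zero_grad()
            d_obj.backward()
            opt_d.step()

            # saturating log-form adversarial value (the reported quantity),
            # from the pre-update discriminator pass
            def _logmean(scores, flip):
                p = 1.0 / (1.0 + np.exp(-scores.data))
                p = p.mean(axis=(1, 2))
                p = (1.0 - p) if flip else p
                return float(np.log(np.clip(p, _EPS, 1.0)).mean())

            gan_value = (
                _logmean(s_rc, False) + _logmean(s_fc2, True)
                + _logmean(s_rn, False) + _logmean(s_fn2, True)
            )
            sums += (gan_value, cyc.item(), idt.item(), adv_g.item(), d_obj.item())

        gan_m, cyc_m, idt_m, g_m, d_m = sums / n_batches
        parts = LossBreakdown(gan_m, cyc_m, idt_m, g_m, d_m,
                              total=gan_m + cfg.alpha * cyc_m + cfg.beta * idt_m)
        trace.append(parts)
        initial = trace[0].total
        if abs(parts.total) > 10.0 * max(abs(initial), 1e-6) and len(trace) > 1:
            over_guard += 1
            if over_guard >= 3:
                raise TrainingDiverged(
                    f"total loss {parts.total:.3g} exceeded 10x initial "
                    f"{initial:.3g} for 3 consecutive epochs"
                )
        else:
            over_guard = 0
    model.window = noisy.shape[1]
    return model, trace


# -- inference -----------------------------------------------------------------------


def denoise_segments(model: DenoiserModel, segments: np.ndarray) -> np.ndarray:
    """Apply G_N2C to (n, T) segments already scaled to [-1, 1]."""
    t = _as_batch(segments)
    return model.g_n2c(t).data[:, 0, :].astype(float)


def denoise(model: DenoiserModel, record: EcgRecord,
            window: int | None = None) -> EcgRecord:
    """Denoise a record lead by lead through the single-channel generator.

    Leads are processed in non-overlapping windows (the training segment
    length by default, so normalisation statistics match training).  Each
    window is mean-centred and span-scaled, passed through G_N2C (edge-padded
    up to the generator's length divisor), and mapped back through the same
    affine to its original amplitude range.
    """
    win = window or model.window or record.n_samples
    div = model.gen_config.divisor
    x = record.signal
    out = np.empty_like(x)
    for start in range(0, x.shape[1], win):
        chunk = x[:, start : start + win]
        scaled, params = _to_window_coords(chunk, chunk)
        t = chunk.shape[1]
        pad = (-t) % div
        if pad:
            scaled = np.pad(scaled, ((0, 0), (0, pad)), mode="edge")
        y = denoise_segments(model, scaled)[:, :t]
        out[:, start : start + t] = _from_window_coords(y, params)
    return record.copy(signal=out, denoised=True)


# -- persistence ---------------------------------------------------------------------


def save_denoiser(model: DenoiserModel, path) -> None:
    """Self-describing checkpoint: configs embedded beside the weights."""
    arrays: dict[str, np.ndarray] = {}
    for name in ("g_n2c", "g_c2n", "d_n2c", "d_c2n"):
        for i, a in enumerate(getattr(model, name).state_arrays()):
            arrays[f"{name}__{i:03d}"] = a
    arrays["config_json"] = np.frombuffer(
        json.dumps(
            {"gen": asdict(model.gen_config), "disc": asdict(model.disc_config),
             "window": model.window}
        ).encode(),
        dtype=np.uint8,
    )
    np.savez(Path(path), **arrays)


def load_denoiser(path) -> DenoiserModel:
    with np.load(Path(path)) as data:
        cfg = json.loads(bytes(data["config_json"].tobytes()).decode())
        model = build_denoiser(
            GeneratorConfig(**cfg["gen"]), DiscriminatorConfig(**cfg["disc"]), seed=0
        )
        model.window = cfg.get("window")
        for name in ("g_n2c", "g_c2n", "d_n2c", "d_c2n"):
            keys = sorted(k for k in data.files if k.startswith(f"{name}__"))
            getattr(model, name).load_state_arrays([data[k] for k in keys])
    return model


# -- sklearn-style estimator -----------------------------------------------------------


class CycleGanDenoiser(TransformerMixin, BaseEstimator):
    """Unpaired ECG denoiser with a fit/transform interface.

    ``fit(X, y)`` takes the noisy-domain corpus ``X`` and the clean-domain
    corpus ``y``, both (n_segments, T) matrices of single-lead segments scaled
    to [-1, 1]; the corpora need not be paired or equally sized.
    ``transform(X)`` maps noisy segments through the trained denoising
    generator.

    Parameters mirror the generator/discriminator configs and the training
    schedule; ``alpha`` and ``beta`` weight the cycle and identity terms of
    the total loss.
    """

    def __init__(
        self,
        n_blocks: int = 5,
        base_channels: int = 16,
        kernel_size: int = 16,
        stride: int = 2,
        alpha: float = 10.0,
        beta: float = 5.0,
        lr: float = 1e-3,
        batch_size: int = 16,
        epochs: int = 20,
        pretrain: str = "dae_pretrain",
        pretrain_epochs: int = 20,
        pretrain_snr_db: float = 5.0,
        init: str = "uniform",
        random_state: int | None = None,
    ):
        self.n_blocks = n_blocks
        self.base_channels = base_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.alpha = alpha
        self.beta = beta
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.pretrain = pretrain
        self.pretrain_epochs = pretrain_epochs
        self.pretrain_snr_db = pretrain_snr_db
        self.init = init
        self.random_state = random_state

    def _configs(self):
        seed = 0 if self.random_state is None else int(self.random_state)
        gen = GeneratorConfig(self.n_blocks, self.base_channels, self.kernel_size,
                              self.stride)
        disc = DiscriminatorConfig(self.n_blocks, self.base_channels,
                                   self.kernel_size, self.stride)
        train = DenoiserTrainConfig(
            alpha=self.alpha, beta=self.beta, lr=self.lr,
            batch_size=self.batch_size, epochs=self.epochs, seed=seed,
            pretrain=self.pretrain, pretrain_epochs=self.pretrain_epochs,
            pretrain_noise=NoiseSpec(kind="gaussian_white",
                                     target_snr_db=self.pretrain_snr_db, seed=seed),
            init=self.init,
        )
        return gen, disc, train

    def fit(self, X, y=None):
        if y is None:
            raise ValueError(
                "CycleGanDenoiser.fit requires the clean-domain corpus as y"
            )
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or y.ndim != 2 or X.shape[1] != y.shape[1]:
            raise ValueError("X and y must be (n, T) matrices with equal T")
        gen_cfg, disc_cfg, train_cfg = self._configs()
        self.model_, self.loss_trace_ = train_denoiser(
            X, y, train_cfg, gen_config=gen_cfg, disc_config=disc_cfg
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        return denoise_segments(self.model_, X)

    def denoise_record(self, record: EcgRecord) -> EcgRecord:
        check_is_fitted(self, "model_")
        return denoise(self.model_, record)
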