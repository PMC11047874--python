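"""Denoiser architecture, loss identities, pre-training and training contracts."""
from types import SimpleNamespace

import numpy as np
import pytest

from ecgcycle import denoise_gan as dg
from ecgcycle import ecgsynth as es
from ecgcycle._autograd import Tensor
from ecgcycle._nn import Conv1d, ConvTranspose1d, InstanceNorm1d, Tanh

COMPACT_GEN = dg.GeneratorConfig(base_channels=4)
COMPACT_DISC = dg.DiscriminatorConfig(base_channels=4)


def identity(x):
    return x


def shift_by(delta):
    return lambda x: x + delta


class ConstantScoreDisc:
    """Discriminator stub emitting a constant raw score map (0 -> prob 0.5)."""

    def __init__(self, score=0.0, map_len=4):
        self.score = score
        self.map_len = map_len

    def __call__(self, x):
        n = x.shape[0]
        return Tensor(np.full((n, 1, self.map_len), self.score))


def stub_model(g_n2c=identity, g_c2n=identity, score=0.0):
    return SimpleNamespace(
        g_n2c=g_n2c, g_c2n=g_c2n,
        d_n2c=ConstantScoreDisc(score), d_c2n=ConstantScoreDisc(score),
    )


class TestGeneratorStructure:
    def test_default_block_counts(self):
        gen = dg.build_generator(seed=0)
        assert len(gen.down_blocks) == 5
        assert len(gen.up_blocks) == 5

    def test_down_block_composition(self):
        gen = dg.build_generator(seed=0)
        conv, norm, act = gen.down_blocks[0].layers
        assert isinstance(conv, Conv1d)
        assert isinstance(norm, InstanceNorm1d)
        assert isinstance(act, Tanh)
        assert isinstance(gen.up_blocks[0].layers[0], ConvTranspose1d)

    @pytest.mark.parametrize("length", [32, 256, 1024])
    def test_output_length_mirrors_input(self, length, rng):
        gen = dg.build_generator(COMPACT_GEN, seed=0)
        out = gen(Tensor(rng.uniform(-1, 1, (2, 1, length))))
        assert out.shape == (2, 1, length)

    def test_indivisible_length_names_divisor(self, rng):
        gen = dg.build_generator(COMPACT_GEN, seed=0)
        with pytest.raises(ValueError, match="32"):
            gen(Tensor(rng.uniform(-1, 1, (1, 1, 100))))

    def test_output_bounded_by_tanh(self, rng):
        gen = dg.build_generator(COMPACT_GEN, seed=0)
        out = gen(Tensor(np.zeros((1, 1, 64)))).data
        assert np.all(out > -1) and np.all(out < 1)

    def test_odd_kernel_stride_parity_rejected(self):
        with pytest.raises(es.ParameterError):
            dg.GeneratorConfig(kernel_size=15, stride=2)


class TestDiscriminatorStructure:
    def test_default_block_and_final_conv_counts(self):
        disc = dg.build_discriminator(seed=0)
        assert len(disc.blocks) == 5
        assert isinstance(disc.final_conv, Conv1d)

    def test_deterministic_score(self, rng):
        disc = dg.build_discriminator(COMPACT_DISC, seed=3)
        x = Tensor(rng.uniform(-1, 1, (1, 1, 64)))
        assert np.array_equal(disc(x).data, disc(x).data)

    def test_amplitude_sensitivity(self, rng):
        disc = dg.build_discriminator(COMPACT_DISC, seed=3)
        x = rng.uniform(-1, 1, (1, 1, 64))
        assert not np.allclose(disc(Tensor(x)).data, disc(Tensor(2 * x)).data)


class TestLosses:
    def test_uncertain_discriminator_gives_four_log_half(self, rng):
        batch = rng.uniform(-1, 1, (6, 32))
        loss = dg.adversarial_loss(stub_model(), batch, batch)
        assert loss == pytest.approx(4 * np.log(0.5), abs=1e-6)

    def test_perfect_discriminator_limit_is_zero(self):
        """D(real) -> 1 and D(fake) -> 0 drives the value function to 0
        (finite thanks to the clamping floor)."""

        class MeanScoreDisc:
            def __call__(self, x):
                return Tensor(100.0 * x.data.mean(axis=2, keepdims=True))

        flip = lambda x: x * (-1.0)
        model = SimpleNamespace(g_n2c=flip, g_c2n=flip,
                                d_n2c=MeanScoreDisc(), d_c2n=MeanScoreDisc())
        batch = np.full((3, 16), 0.5)
        assert dg.adversarial_loss(model, batch, batch) == pytest.approx(0.0, abs=1e-5)

    def test_adversarial_matches_direct_formula(self, rng):
        model = dg.build_denoiser(COMPACT_GEN, COMPACT_DISC, seed=5)
        batch_n = rng.uniform(-1, 1, (3, 64))
        batch_c = rng.uniform(-1, 1, (3, 64))

        def prob(disc, arr):
            scores = disc(Tensor(arr[:, None, :])).data
            return (1 / (1 + np.exp(-scores))).mean(axis=(1, 2))

        fake_c = model.g_n2c(Tensor(batch_n[:, None, :])).data[:, 0, :]
        fake_n = model.g_c2n(Tensor(batch_c[:, None, :])).data[:, 0, :]
        expected = (
            np.log(prob(model.d_n2c, batch_c)).mean()
            + np.log(1 - prob(model.d_n2c, fake_c)).mean()
            + np.log(prob(model.d_c2n, batch_n)).mean()
            + np.log(1 - prob(model.d_c2n, fake_n)).mean()
        )
        assert dg.adversarial_loss(model, batch_n, batch_c) == pytest.approx(
            expected, abs=1e-5
        )

    def test_cycle_zero_for_identity_generators(self, rng):
        batch = rng.uniform(-1, 1, (4, 16))
        assert dg.cycle_loss(stub_model(), batch, batch) == 0.0

    def test_cycle_hand_value_for_unit_shift(self):
        """G_N2C identity, G_C2N adds 1: each direction's round-trip residual
        is exactly 1 on zero batches."""
        model = stub_model(g_n2c=identity, g_c2n=shift_by(1.0))
        zeros = np.zeros((3, 8))
        assert dg.cycle_loss(model, zeros, zeros) == pytest.approx(2.0, abs=1e-6)

    def test_identity_zero_for_identity_generators(self, rng):
        batch = rng.uniform(-1, 1, (4, 16))
        assert dg.identity_loss(stub_model(), batch, batch) == 0.0

    def test_identity_hand_value_for_shift(self, rng):
        delta = 0.25
        model = stub_model(g_n2c=shift_by(delta), g_c2n=shift_by(delta))
        batch = rng.uniform(-0.5, 0.5, (5, 16))
        assert dg.identity_loss(model, batch, batch) == pytest.approx(
            2 * delta, abs=1e-6
        )

    def test_losses_nonnegative(self, rng):
        model = dg.build_denoiser(COMPACT_GEN, COMPACT_DISC, seed=1)
        batch = rng.uniform(-1, 1, (2, 32))
        assert dg.cycle_loss(model, batch, batch) >= 0
        assert dg.identity_loss(model, batch, batch) >= 0

    def test_total_is_weighted_sum(self):
        parts = dg.LossBreakdown(1.0, 2.0, 3.0, 0.0, 0.0, 0.0)
        cfg = dg.DenoiserTrainConfig(alpha=10.0, beta=5.0)
        assert dg.total_loss(parts, cfg) == pytest.approx(36.0)
        assert dg.total_loss(parts, dg.DenoiserTrainConfig(alpha=0, beta=0)) == 1.0

    def test_total_linear_in_alpha(self):
        parts = dg.LossBreakdown(0.5, 1.5, 0.0, 0.0, 0.0, 0.0)
        t1 = dg.total_loss(parts, dg.DenoiserTrainConfig(alpha=1, beta=0))
        t2 = dg.total_loss(parts, dg.DenoiserTrainConfig(alpha=2, beta=0))
        t3 = dg.total_loss(parts, dg.DenoiserTrainConfig(alpha=3, beta=0))
        assert t3 - t2 == pytest.approx(t2 - t1, abs=1e-9)

    def test_empty_batch_rejected(self):
        with pytest.raises(es.ParameterError):
            dg.adversarial_loss(stub_model(), np.empty((0, 8)), np.zeros((2, 8)))


@pytest.fixture(scope="module")
def tiny_corpus():
    triples = es.make_dataset(4, noise=es.NoiseSpec(target_snr_db=0.0, seed=3),
                              seed=3, duration_s=2.048, fs=125.0)
    noisy = dg.prepare_segments([ny for _, ny, _ in triples], window=128)
    clean = dg.prepare_segments(
        [cl for cl, _, _ in triples], window=128,
        noise=es.NoiseSpec(target_snr_db=0.0, seed=4), seed=4,
    )
    return noisy, clean


class TestPretrain:
    def test_zero_epochs_leave_parameters_unchanged(self, tiny_corpus):
        _, clean = tiny_corpus
        gen = dg.build_generator(COMPACT_GEN, seed=2)
        before = gen.state_arrays()
        dg.pretrain_generator(gen, clean, es.NoiseSpec(target_snr_db=0.0, seed=0),
                              epochs=0)
        after = gen.state_arrays()
        assert all(np.array_equal(a, b) for a, b in zip(before, after))

    def test_seeded_trajectory_reproducible(self, tiny_corpus):
        _, clean = tiny_corpus
        noise = es.NoiseSpec(target_snr_db=0.0, seed=0)
        gens = []
        for _ in range(2):
            gen = dg.build_generator(COMPACT_GEN, seed=2)
            dg.pretrain_generator(gen, clean, noise, epochs=2, seed=9)
            gens.append(gen.state_arrays())
        assert all(np.array_equal(a, b) for a, b in zip(*gens))

    def test_reconstruction_improves(self, tiny_corpus):
        _, clean = tiny_corpus
        noise = es.NoiseSpec(target_snr_db=0.0, seed=0)
        rng = np.random.default_rng(8)
        corrupted = clean + es.sample_noise(clean, noise, rng=rng)

        def recon_l1(gen):
            out = gen(Tensor(corrupted[:, None, :])).data[:, 0, :]
            return np.abs(out - clean).mean()

        gen = dg.build_generator(COMPACT_GEN, seed=2)
        before = recon_l1(gen)
        dg.pretrain_generator(gen, clean, noise, epochs=8, seed=9)
        assert recon_l1(gen) < before

    def test_empty_corpus_rejected(self):
        gen = dg.build_generator(COMPACT_GEN, seed=2)
        with pytest.raises(es.ParameterError):
            dg.pretrain_generator(gen, np.empty((0, 32)),
                                  es.NoiseSpec(amplitude=1.0), epochs=1)


class TestTrainDenoiser:
    def test_single_epoch_trace_length(self, tiny_corpus):
        noisy, clean = tiny_corpus
        cfg = dg.DenoiserTrainConfig(epochs=1, pretrain="none", seed=0)
        _, trace = dg.train_denoiser(noisy[:8], clean[:8], cfg,
                                     gen_config=COMPACT_GEN,
                                     disc_config=COMPACT_DISC)
        assert len(trace) == 1

    def test_trace_total_matches_weighted_sum(self, tiny_corpus):
        noisy, clean = tiny_corpus
        cfg = dg.DenoiserTrainConfig(epochs=2, pretrain="none", seed=0)
        _, trace = dg.train_denoiser(noisy[:8], clean[:8], cfg,
                                     gen_config=COMPACT_GEN,
                                     disc_config=COMPACT_DISC)
        for parts in trace:
            expected = (parts.loss_gan + cfg.alpha * parts.loss_cycle
                        + cfg.beta * parts.loss_identity)
            assert parts.total == pytest.approx(expected, abs=1e-6)

    def test_seeded_training_reproducible(self, tiny_corpus):
        noisy, clean = tiny_corpus
        totals = []
        for _ in range(2):
            cfg = dg.DenoiserTrainConfig(epochs=1, pretrain="none", seed=4)
            _, trace = dg.train_denoiser(noisy[:8], clean[:8], cfg,
                                         gen_config=COMPACT_GEN,
                                         disc_config=COMPACT_DISC)
            totals.append(trace[0].total)
        assert totals[0] == totals[1]

    def test_cycle_loss_decreases_from_cold_start(self):
        """Without pre-training the round-trip residual starts high and
        shrinks as adversarial training proceeds."""
        triples = es.make_dataset(
            6, noise=es.NoiseSpec(target_snr_db=0.0, seed=3), seed=3,
            duration_s=4.096, fs=125.0,
        )
        noisy = dg.prepare_segments([ny for _, ny, _ in triples], 128)
        clean = dg.prepare_segments(
            [cl for cl, _, _ in triples], 128,
            noise=es.NoiseSpec(target_snr_db=0.0, seed=4), seed=4,
        )
        cfg = dg.DenoiserTrainConfig(epochs=6, pretrain="none", seed=0)
        _, trace = dg.train_denoiser(noisy, clean, cfg,
                                     gen_config=COMPACT_GEN,
                                     disc_config=COMPACT_DISC)
        assert trace[-1].loss_cycle < trace[0].loss_cycle

    def test_records_training_window(self, tiny_corpus):
        noisy, clean = tiny_corpus
        cfg = dg.DenoiserTrainConfig(epochs=1, pretrain="none", seed=0)
        model, _ = dg.train_denoiser(noisy[:8], clean[:8], cfg,
                                     gen_config=COMPACT_GEN,
                                     disc_config=COMPACT_DISC)
        assert model.window == 128


class TestDenoiseInference:
    def test_identity_generator_round_trips_record(self, clean_record):
        model = dg.build_denoiser(COMPACT_GEN, COMPACT_DISC, seed=0)
        model.g_n2c = identity
        out = dg.denoise(model, clean_record, window=500)
        assert out.signal.shape == clean_record.signal.shape
        assert out.fs == clean_record.fs
        assert np.allclose(out.signal, clean_record.signal, atol=1e-5)

    def test_shape_preserved_for_untrained_model(self, clean_record):
        model = dg.build_denoiser(COMPACT_GEN, COMPACT_DISC, seed=0)
        out = dg.denoise(model, clean_record)
        assert out.signal.shape == clean_record.signal.shape

    def test_save_load_round_trip(self, tmp_path, rng):
        model = dg.build_denoiser(COMPACT_GEN, COMPACT_DISC, seed=6)
        model.window = 128
        dg.save_denoiser(model, tmp_path / "m.npz")
        back = dg.load_denoiser(tmp_path / "m.npz")
        assert back.window == 128
        x = rng.uniform(-1, 1, (2, 64))
        assert np.allclose(dg.denoise_segments(model, x),
                           dg.denoise_segments(back, x), atol=1e-7)


class TestEstimatorInterface:
    def test_get_set_params_round_trip(self):
        est = dg.CycleGanDenoiser(alpha=7.0, epochs=1)
        params = est.get_params()
        assert params["alpha"] == 7.0
        est.set_params(beta=2.0)
        assert est.beta == 2.0

    def test_sklearn_clone(self):
        from sklearn.base import clone
        est = dg.CycleGanDenoiser(epochs=2, random_state=3)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_fit_requires_clean_corpus(self, rng):
        with pytest.raises(ValueError, match="clean"):
            dg.CycleGanDenoiser(epochs=1).fit(rng.uniform(-1, 1, (4, 32)))

    def test_fit_transform_shapes(self, tiny_corpus):
        noisy, clean = tiny_corpus
        est = dg.CycleGanDenoiser(base_channels=4, epochs=1, pretrain="none",
                                  batch_size=4, random_state=0)
        est.fit(noisy[:8], clean[:8])
        out = est.transform(noisy[:5])
        assert out.shape == (5, 128)
        assert len(est.loss_trace_) == 1
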