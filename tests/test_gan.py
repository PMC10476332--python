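"""Generator/discriminator contracts, loss decomposition, and smoothing."""

import numpy as np
import pytest

from gaitforge.core import DataError, GaitPattern, InvalidSpecError
from gaitforge.gan import (
    DiscriminatorSpec,
    GANConfig,
    GeneratorSpec,
    build_discriminator,
    build_generator,
    discriminate,
    gan_loss,
    generate,
    load_gan,
    save_gan,
    smooth_output,
    train,
)
from gaitforge.nn import bce_with_logits
from gaitforge.synthetic import make_corpus


class TestGeneratorArchitecture:
    def test_output_shape_and_range(self, rng):
        gen = build_generator(seed=0)
        x = rng.uniform(0.2, 0.8, size=(5, 200, 4))
        out = gen.forward(x)
        assert out.shape == (5, 200, 4)
        assert np.all(out > 0) and np.all(out < 1)

    def test_internal_sequence_lengths(self, rng):
        gen = build_generator(seed=0)
        x = rng.uniform(size=(2, 200, 4))
        lengths = []
        h = x
        for layer in gen.layers:
            h = layer.forward(h)
            lengths.append(h.shape[1])
        assert lengths == [100, 50, 25, 50, 100, 200, 200]

    def test_parameter_count_reproducible(self):
        a = build_generator(seed=0)
        b = build_generator(seed=99)
        assert a.n_params() == b.n_params() > 0

    def test_length_not_divisible_by_8_rejected(self):
        with pytest.raises(InvalidSpecError):
            GeneratorSpec(input_len=201)


class TestDiscriminatorArchitecture:
    def test_scalar_score_per_item(self, rng):
        disc = build_discriminator(seed=0)
        cond = rng.uniform(size=(6, 200, 4))
        cand = rng.uniform(size=(6, 200, 4))
        out = discriminate(disc, cond, cand)
        assert out.shape == (6, 1)

    def test_deterministic_and_batch_independent(self, rng):
        disc = build_discriminator(seed=0)
        cond = rng.uniform(size=(4, 200, 4))
        cand = rng.uniform(size=(4, 200, 4))
        a = discriminate(disc, cond, cand)
        b = discriminate(disc, cond, cand)
        assert np.array_equal(a, b)
        perm = [2, 0, 3, 1]
        c = discriminate(disc, cond[perm], cand[perm])
        assert np.allclose(c, a[perm])

    def test_shape_mismatch_rejected(self, rng):
        disc = build_discriminator(seed=0)
        with pytest.raises(DataError):
            discriminate(disc, rng.uniform(size=(2, 200, 4)),
                         rng.uniform(size=(3, 200, 4)))


class TestGanLoss:
    def test_identical_fake_leaves_adversarial_only(self, rng):
        real = rng.uniform(size=(3, 200, 4))
        logits = rng.normal(size=(3, 1))
        g, _ = gan_loss(real, real.copy(), logits, logits, GANConfig())
        adv, _ = bce_with_logits(logits, 1.0)
        assert g == pytest.approx(adv)

    def test_lambda_zero_is_purely_adversarial(self, rng):
        real = rng.uniform(size=(2, 200, 4))
        fake = rng.uniform(size=(2, 200, 4))
        logits = rng.normal(size=(2, 1))
        g, _ = gan_loss(real, fake, logits, logits, GANConfig(lambda_l1=0.0))
        adv, _ = bce_with_logits(logits, 1.0)
        assert g == pytest.approx(adv)

    def test_constant_error_reconstruction_term(self, rng):
        real = rng.uniform(0.2, 0.7, size=(2, 200, 4))
        c = 0.03
        fake = real + c
        logits = np.zeros((2, 1))
        cfg = GANConfig(lambda_l1=1000.0)
        g, _ = gan_loss(real, fake, logits, logits, cfg)
        adv, _ = bce_with_logits(logits, 1.0)
        assert g - adv == pytest.approx(1000.0 * c)

    def test_loss_decomposition_identity(self, rng):
        real = rng.uniform(size=(3, 200, 4))
        fake = rng.uniform(size=(3, 200, 4))
        logits = rng.normal(size=(3, 1))
        cfg = GANConfig()
        g, _ = gan_loss(real, fake, logits, logits, cfg)
        adv, _ = bce_with_logits(logits, 1.0)
        mae = float(np.mean(np.abs(real - fake)))
        assert g == pytest.approx(adv + cfg.lambda_l1 * mae, abs=1e-6)


@pytest.fixture(scope="module")
def tiny_corpus():
    return make_corpus(("lgw",), subjects=2, reps=2, rng_seed=0)


class TestTraining:
    def test_epoch_count_and_determinism(self, tiny_corpus):
        cfg = GANConfig(epochs=3, batch_size=4, seed=1)
        _, _, state_a = train(tiny_corpus, cfg)
        _, _, state_b = train(tiny_corpus, cfg)
        assert state_a.epochs == 3
        assert state_a.g_loss == state_b.g_loss
        assert state_a.d_loss == state_b.d_loss

    def test_reconstruction_decreases_on_single_pair(self, tiny_corpus):
        cfg = GANConfig(epochs=50, batch_size=1, seed=2)
        _, _, state = train(tiny_corpus[:1], cfg)
        assert state.recon_mae[49] < state.recon_mae[0]

    def test_empty_corpus_rejected(self):
        with pytest.raises(DataError):
            train([], GANConfig(epochs=1))


class TestGenerate:
    def test_output_contract(self, lgw_sketch):
        gen = build_generator(seed=3)
        out = generate(lgw_sketch, gen)
        assert out.n_rows == 200
        assert out.units == "normalized"
        assert np.all(out.values > 0) and np.all(out.values < 1)

    def test_deterministic_without_noise_input(self, lgw_sketch):
        gen = build_generator(seed=3)
        a = generate(lgw_sketch, gen)
        b = generate(lgw_sketch, gen)
        assert np.array_equal(a.values, b.values)

    def test_missing_generator_rejected(self, lgw_sketch):
        with pytest.raises(DataError):
            generate(lgw_sketch, None)

    def test_checkpoint_roundtrip(self, tmp_path, lgw_sketch):
        gen = build_generator(seed=4)
        disc = build_discriminator(seed=5)
        path = tmp_path / "gan.npz"
        save_gan(path, gen, disc)
        gen2, disc2 = load_gan(path)
        assert np.array_equal(generate(lgw_sketch, gen).values,
                              generate(lgw_sketch, gen2).values)
        assert disc2 is not None


class TestHeldOutSketch:
    def test_interpolated_sketch_generates_bounded_periodic_pattern(
        self, tiny_corpus
    ):
        # a sketch inside the training family's convex hull (midpoint of two
        # training sketches) must still yield values in (0,1), and bridging
        # the cycle boundary must halve the raw end-start gap
        from gaitforge.core import DiscretizedPattern
        from gaitforge.metrics import discontinuity

        cfg = GANConfig(epochs=5, batch_size=4, seed=4)
        gen, _, _ = train(tiny_corpus, cfg)
        mid = DiscretizedPattern(
            0.5 * (tiny_corpus[0][0].values + tiny_corpus[1][0].values)
        )
        out = generate(mid, gen)
        assert np.all(out.values > 0) and np.all(out.values < 1)
        raw = discontinuity(out, "generated_raw")
        interp = discontinuity(out, "generated_interp")
        assert np.all(interp <= raw / 2 + 1e-12)


class TestSmoothOutput:
    def test_interpolating_limit_preserves_nodes(self, rng):
        p = GaitPattern(rng.uniform(0.3, 0.7, size=(200, 4)),
                        units="normalized")
        out = smooth_output(p, smoothing=1.0)
        assert np.allclose(out.values, p.values, atol=1e-8)

    def test_strong_penalty_tends_to_line(self, rng):
        x = np.arange(200) * 0.5
        line = 0.3 + 0.002 * x
        noisy = line + rng.normal(0, 0.02, size=200)
        p = GaitPattern(np.tile(noisy[:, None], (1, 4)), units="normalized")
        out = smooth_output(p, smoothing=1e-9)
        fit = np.polynomial.polynomial.polyfit(x, noisy, 1)
        expected = fit[0] + fit[1] * x
        assert np.allclose(out.values[:, 0], expected, atol=1e-3)

    def test_reduces_noise_rmse(self, rng):
        x = np.arange(200) * 0.5
        clean = 0.5 + 0.2 * np.sin(2 * np.pi * x / 100)
        noisy = clean + rng.normal(0, 0.05, size=200)
        p = GaitPattern(np.tile(noisy[:, None], (1, 4)), units="normalized")
        out = smooth_output(p, smoothing=0.1)
        rmse_raw = np.sqrt(np.mean((noisy - clean) ** 2))
        rmse_smooth = np.sqrt(np.mean((out.values[:, 0] - clean) ** 2))
        assert rmse_smooth < rmse_raw
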