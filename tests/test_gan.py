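"""Adversarial corrector: losses, training behaviour, estimator facade."""

import numpy as np
import pytest
from sklearn.base import clone

from mrimotion.gan import (GANCorrector, TrainConfig, TrainedCorrector,
                           UNetConfig, build_discriminator, build_generator,
                           correct, data_loss, discriminator_loss, finetune,
                           generator_loss, pretrain_generator, train)
from mrimotion.phantom import generate_phantom


def tiny_pairs(n=24, size=16, noise=0.1, seed=0):
    """Cheap paired task: clean phantoms vs noise-corrupted versions."""
    rng = np.random.default_rng(seed)
    clean = np.stack([generate_phantom(size, seed=int(rng.integers(2 ** 31)),
                                       n_ellipses=3) for _ in range(n)])
    corrupted = np.clip(clean + noise * rng.standard_normal(clean.shape), 0, 1)
    return corrupted, clean


class TestArchitecture:
    def test_generator_preserves_shape(self):
        cfg = UNetConfig(n_blocks=2, base_features=8, input_size=16)
        gen = build_generator(cfg, rng=0)
        x = np.random.default_rng(0).random((2, 1, 16, 16)).astype(np.float32)
        out = gen.forward(x)
        assert out.shape == x.shape
        assert np.all(np.isfinite(out))
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_capacity_grows_with_width(self):
        small = build_generator(UNetConfig(2, 8, 16), rng=0)
        large = build_generator(UNetConfig(2, 16, 16), rng=0)
        assert large.n_parameters() > small.n_parameters()

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ValueError):
            UNetConfig(n_blocks=3, base_features=8, input_size=20)

    def test_block_layer_count_fixed(self):
        with pytest.raises(ValueError):
            UNetConfig(n_blocks=2, base_features=8, input_size=16,
                       layers_per_block=3)

    def test_discriminator_probability_output(self):
        disc = build_discriminator(UNetConfig(2, 8, 16), rng=0)
        x = np.random.default_rng(1).random((2, 1, 16, 16)).astype(np.float32)
        p = disc.forward(x)
        assert p.shape == (2,)
        assert np.all((p > 0) & (p < 1))
        assert np.array_equal(p, disc.forward(x))  # deterministic inference

    def test_discriminator_input_gradient_nonzero(self):
        disc = build_discriminator(UNetConfig(2, 8, 16), rng=0)
        x = np.random.default_rng(2).random((1, 1, 16, 16)).astype(np.float32)
        disc.forward(x)
        g = disc.backward(np.ones(1))
        assert np.all(np.isfinite(g))
        assert np.abs(g).max() > 0


class TestLosses:
    def test_generator_loss_reduces_to_data_term(self):
        """With zero adversarial weight the loss is the batch L2 norm."""
        clean = np.random.default_rng(0).random((4, 8, 8))
        corrupted = np.random.default_rng(1).random((4, 8, 8))
        pred = np.random.default_rng(2).random((4, 8, 8))
        loss = generator_loss(clean, corrupted, lambda x: pred, None, 0.0)
        assert loss == pytest.approx(data_loss(clean, pred), abs=1e-12)

    def test_perfect_generator_zero_loss(self):
        clean = np.random.default_rng(3).random((2, 8, 8))
        loss = generator_loss(clean, clean, lambda x: x[:, 0], None, 0.0)
        assert loss == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_two_by_two(self):
        clean = np.array([[[1.0, 0.0], [0.0, 1.0]]])
        pred = np.array([[[0.5, 0.0], [0.0, 1.0]]])
        loss = generator_loss(clean, clean, lambda x: pred, None, 0.0)
        assert loss == pytest.approx(0.5, abs=1e-12)

    def test_adversarial_term_added(self):
        clean = np.random.default_rng(4).random((2, 8, 8))
        loss0 = generator_loss(clean, clean, lambda x: x[:, 0],
                               lambda g: np.full(len(g), 0.5), 0.0)
        loss1 = generator_loss(clean, clean, lambda x: x[:, 0],
                               lambda g: np.full(len(g), 0.5), 0.6)
        assert loss1 == pytest.approx(loss0 + 0.6 * np.log(0.5), abs=1e-9)

    def test_negative_weight_rejected(self):
        clean = np.zeros((1, 8, 8))
        with pytest.raises(ValueError):
            generator_loss(clean, clean, lambda x: x[:, 0], None, -0.1)

    def test_indifferent_discriminator_closed_form(self):
        """D == 0.5 everywhere gives the 2 log 2 equilibrium value."""
        batch = np.zeros((4, 8, 8))
        loss = discriminator_loss(batch, batch,
                                  lambda x: np.full(len(x), 0.5))
        assert loss == pytest.approx(2 * np.log(2.0), abs=1e-9)

    def test_perfect_discriminator_near_zero(self):
        batch = np.zeros((4, 8, 8))

        def perfect(x):
            # first call sees real, second sees fake in discriminator_loss
            perfect.calls += 1
            return np.ones(len(x)) if perfect.calls == 1 else np.zeros(len(x))

        perfect.calls = 0
        loss = discriminator_loss(batch, batch, perfect)
        assert loss == pytest.approx(0.0, abs=1e-5)

    def test_inverted_discriminator_large_loss(self):
        batch = np.zeros((4, 8, 8))

        def inverted(x):
            inverted.calls += 1
            return np.zeros(len(x)) if inverted.calls == 1 else np.ones(len(x))

        inverted.calls = 0
        assert discriminator_loss(batch, batch, inverted) > 20.0


class TestTraining:
    def test_pretraining_descends(self):
        corrupted, clean = tiny_pairs(n=32, size=16)
        cfg = TrainConfig(seed=0, pretrain_steps=60, batch_size=8)
        model = pretrain_generator((corrupted, clean), cfg,
                                   UNetConfig(2, 8, 16))
        losses = [e["data_loss"] for e in model.log]
        assert np.mean(losses[-10:]) < np.mean(losses[:10])

    def test_identity_pairs_reach_low_loss(self):
        _, clean = tiny_pairs(n=16, size=16)
        cfg = TrainConfig(seed=0, pretrain_steps=40, batch_size=8)
        model = pretrain_generator((clean, clean), cfg, UNetConfig(2, 8, 16))
        # identity is representable through the global shortcut
        assert model.log[-1]["data_loss"] < 0.5 * model.log[0]["data_loss"]

    def test_deterministic_per_seed(self):
        corrupted, clean = tiny_pairs(n=16, size=16)
        cfg = TrainConfig(seed=7, pretrain_steps=10, max_steps=10, batch_size=4)
        a = train((corrupted, clean), cfg, UNetConfig(2, 8, 16))
        b = train((corrupted, clean), cfg, UNetConfig(2, 8, 16))
        assert [e["g_loss"] for e in a.log] == [e["g_loss"] for e in b.log]
        x = corrupted[:2]
        assert np.array_equal(correct(a, x), correct(b, x))

    def test_adversarial_losses_logged(self):
        corrupted, clean = tiny_pairs(n=16, size=16)
        cfg = TrainConfig(seed=0, pretrain=False, max_steps=5, batch_size=4)
        model = train((corrupted, clean), cfg, UNetConfig(2, 8, 16))
        gan_steps = [e for e in model.log if e["phase"] == "gan"]
        assert len(gan_steps) == 5
        assert all(np.isfinite(e["d_loss"]) for e in gan_steps)
        assert all(np.isfinite(e["adv_loss"]) for e in gan_steps)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            pretrain_generator((np.zeros((0, 8, 8)), np.zeros((0, 8, 8))),
                               TrainConfig())


@pytest.fixture(scope="module")
def small_model():
    corrupted, clean = tiny_pairs(n=24, size=16)
    cfg = TrainConfig(seed=0, pretrain_steps=30, max_steps=20, batch_size=8)
    return train((corrupted, clean), cfg, UNetConfig(2, 8, 16))


class TestCorrectAndFinetune:
    def test_correct_shape_range_determinism(self, small_model):
        x = tiny_pairs(n=2, size=16, seed=5)[0]
        out = correct(small_model, x)
        assert out.shape == x.shape
        assert out.min() >= 0.0 and out.max() <= 1.0
        assert np.array_equal(out, correct(small_model, x))
        single = correct(small_model, x[0])
        assert single.shape == (16, 16)
        assert np.array_equal(single, out[0])

    def test_correct_size_mismatch(self, small_model):
        with pytest.raises(ValueError):
            correct(small_model, np.zeros((32, 32)))

    def test_finetune_zero_steps_is_identity(self, small_model):
        before = small_model.generator.state_list()
        out = finetune(small_model, tiny_pairs(n=8, size=16),
                       TrainConfig(seed=0, max_steps=0))
        after = out.generator.state_list()
        assert all(np.array_equal(a, b) for a, b in zip(before, after))

    def test_finetune_same_distribution_no_worse(self, small_model):
        corrupted, clean = tiny_pairs(n=24, size=16)
        val_before = data_loss(clean, correct(small_model, corrupted))
        tuned = finetune(small_model, (corrupted, clean),
                         TrainConfig(seed=1, max_steps=30, batch_size=8))
        val_after = data_loss(clean, correct(tuned, corrupted))
        assert val_after <= val_before * 1.05

    def test_finetune_shape_mismatch(self, small_model):
        with pytest.raises(ValueError):
            finetune(small_model, tiny_pairs(n=4, size=32),
                     TrainConfig(max_steps=1))

    def test_checkpoint_round_trip_bit_identical(self, small_model, tmp_path):
        path = tmp_path / "model.npz"
        small_model.save(path)
        loaded = TrainedCorrector.load(path)
        x = tiny_pairs(n=3, size=16, seed=9)[0]
        assert np.array_equal(correct(small_model, x), correct(loaded, x))
        assert loaded.train_config == small_model.train_config
        assert loaded.unet_config == small_model.unet_config

    def test_load_missing_checkpoint(self, tmp_path):
        with pytest.raises(IOError):
            TrainedCorrector.load(tmp_path / "missing.npz")


class TestEstimatorFacade:
    def test_sklearn_contract(self):
        est = GANCorrector(max_steps=3, pretrain_steps=2, base_features=8)
        params = est.get_params()
        assert params["base_features"] == 8
        cloned = clone(est)
        assert cloned.get_params() == params
        cloned.set_params(max_steps=5)
        assert cloned.max_steps == 5

    def test_fit_predict_score(self):
        corrupted, clean = tiny_pairs(n=16, size=16)
        est = GANCorrector(n_blocks=2, base_features=8, pretrain_steps=30,
                           max_steps=10, batch_size=8, random_state=0)
        est.fit(corrupted, clean)
        assert hasattr(est, "generator_") and hasattr(est, "history_")
        pred = est.predict(corrupted[:4])
        assert pred.shape == (4, 16, 16)
        assert np.isfinite(est.score(corrupted[:4], clean[:4]))

    def test_unfitted_predict_raises(self):
        with pytest.raises(RuntimeError):
            GANCorrector().predict(np.zeros((1, 16, 16)))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(adversarial_weight=-0.5)
        with pytest.raises(ValueError):
            TrainConfig(batch_size=0)
        with pytest.raises(ValueError):
            TrainConfig(d_updates_per_g=0)
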