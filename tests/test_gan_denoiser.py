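import numpy as np
import pytest

from eegadgan import contamination as cn
from eegadgan.errors import FormatError, ValidationError
from eegadgan.evaluation import rrmse_temporal
from eegadgan.gan_denoiser import (
    DiscriminatorSpec,
    Generator,
    GeneratorSpec,
    TrainConfig,
    build_discriminator,
    build_generator,
    denoise,
    discriminator_loss,
    generator_loss,
    generator_parameter_count,
    kfold_split,
    load_checkpoint,
    save_checkpoint,
    train_gan,
)
from eegadgan.types import NormalizationInfo, SnrGrid


@pytest.fixture(scope="module")
def identity_datasets():
    """λ=0 pairs: the noisy input *is* the clean target."""
    clean = cn.generate_clean_eeg(60, 640, 160.0, seed=40)
    pairs = [cn.mix_pair(x, np.zeros_like(x), 0.0, "mains", clean_index=i)
             for i, x in enumerate(clean.segments)]
    from eegadgan.types import PairedDataset
    from eegadgan.contamination import normalize_dataset
    train = normalize_dataset(
        PairedDataset(pairs=pairs[:50], split="train", fs=160.0))
    test = normalize_dataset(
        PairedDataset(pairs=pairs[50:], split="test", fs=160.0))
    return train, test


class TestGeneratorContract:
    def test_shape_contract(self):
        gen = build_generator(GeneratorSpec(input_len=512), seed=0)
        out = gen.forward(np.zeros((4, 512)))
        assert out.shape == (4, 512)

    def test_seeded_builds_are_identical(self):
        probe = np.random.default_rng(0).standard_normal((3, 640))
        a = build_generator(GeneratorSpec(input_len=640), seed=5).forward(probe)
        b = build_generator(GeneratorSpec(input_len=640), seed=5).forward(probe)
        np.testing.assert_array_equal(a, b)

    def test_parameter_count_closed_form(self):
        for spec in (GeneratorSpec(input_len=640),
                     GeneratorSpec(input_len=512, frame_size=8),
                     GeneratorSpec(input_len=1024, recurrent_layers=3)):
            gen = build_generator(spec, seed=0)
            assert gen.n_parameters == generator_parameter_count(spec)

    def test_wrong_length_rejected(self):
        gen = build_generator(GeneratorSpec(input_len=512), seed=0)
        with pytest.raises(ValidationError, match="512"):
            gen.forward(np.zeros((2, 640)))

    def test_indivisible_frame_size_rejected(self):
        with pytest.raises(ValidationError, match="divisible"):
            GeneratorSpec(input_len=641)

    def test_zero_weight_head_outputs_zero(self):
        gen = build_generator(GeneratorSpec(input_len=640), seed=0)
        gen.head.W[...] = 0.0
        gen.head.b[...] = 0.0
        out = gen.forward(np.random.default_rng(1).standard_normal((2, 640)))
        np.testing.assert_array_equal(out, np.zeros((2, 640)))

    def test_batch_equals_one_at_a_time(self):
        gen = build_generator(GeneratorSpec(input_len=640), seed=2)
        batch = np.random.default_rng(3).standard_normal((5, 640))
        together = denoise(gen, batch)
        singly = np.stack([denoise(gen, seg) for seg in batch])
        np.testing.assert_allclose(together, singly, atol=1e-12)

    def test_denormalization_constants_applied(self):
        gen = build_generator(GeneratorSpec(input_len=640), seed=2)
        batch = np.random.default_rng(4).standard_normal((2, 640))
        raw = denoise(gen, batch)
        info = NormalizationInfo(scheme="noisy_zscore", offset=1.5, scale=2.0)
        np.testing.assert_allclose(denoise(gen, batch, constants=info),
                                   raw * 2.0 + 1.5)


class TestDiscriminatorContract:
    def test_scores_in_unit_interval(self):
        disc = build_discriminator(DiscriminatorSpec(input_len=640), seed=0)
        scores = disc.forward(np.random.default_rng(0).standard_normal((8, 640)))
        assert scores.shape == (8,)
        assert np.all((scores > 0) & (scores < 1))

    def test_indivisible_length_names_pool_factor(self):
        with pytest.raises(ValidationError, match="16"):
            DiscriminatorSpec(input_len=641)

    def test_seed_determinism(self):
        probe = np.random.default_rng(1).standard_normal((4, 640))
        a = build_discriminator(DiscriminatorSpec(input_len=640), seed=9)
        b = build_discriminator(DiscriminatorSpec(input_len=640), seed=9)
        np.testing.assert_array_equal(a.forward(probe), b.forward(probe))


class TestLosses:
    def test_discriminator_loss_examples(self):
        assert discriminator_loss(np.array([1.0]), np.array([0.0])) == 0.0
        assert discriminator_loss(np.array([0.5]), np.array([0.5])) == \
            pytest.approx(0.25)
        assert discriminator_loss(np.array([1.0, 0.0]), np.array([0.0])) == \
            pytest.approx(0.25)

    def test_generator_loss_examples(self):
        assert generator_loss(np.array([1.0]), c=1.0) == 0.0
        assert generator_loss(np.array([0.0]), c=1.0) == pytest.approx(0.5)
        assert generator_loss(np.array([0.2, 0.6]), c=1.0) == pytest.approx(0.2)

    def test_losses_match_scalar_brute_force(self):
        rng = np.random.default_rng(0)
        d_real = rng.uniform(size=17)
        d_fake = rng.uniform(size=13)
        a, b, c = 0.1, 0.9, 0.8
        bd = 0.5 * sum((v - b) ** 2 for v in d_real) / len(d_real) \
            + 0.5 * sum((v - a) ** 2 for v in d_fake) / len(d_fake)
        bg = 0.5 * sum((v - c) ** 2 for v in d_fake) / len(d_fake)
        assert discriminator_loss(d_real, d_fake, a, b) == pytest.approx(bd, rel=1e-12)
        assert generator_loss(d_fake, c) == pytest.approx(bg, rel=1e-12)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValidationError):
            generator_loss(np.array([]))

    def test_equal_labels_rejected(self):
        with pytest.raises(ValidationError):
            TrainConfig(a=1.0, b=1.0)


class TestTraining:
    def test_identity_task_held_out_error_descends(self, identity_datasets):
        train, test = identity_datasets
        cfg = TrainConfig(epochs=5, seed=3, recon_weight=10.0, lr_g=3e-3)
        _, history = train_gan(train, cfg, val=test)
        assert len(history) == 5
        assert history.val_rrmse_t[-1] < history.val_rrmse_t[0]

    def test_identity_task_reaches_near_identity_mapping(self, identity_datasets):
        train, test = identity_datasets
        cfg = TrainConfig(epochs=50, seed=3, recon_weight=10.0, lr_g=3e-3)
        gen, history = train_gan(train, cfg, val=test)
        assert history.val_rrmse_t[-1] < 0.2

    def test_seeded_histories_are_bitwise_equal(self, identity_datasets):
        train, _ = identity_datasets
        cfg = TrainConfig(epochs=2, seed=11)
        _, h1 = train_gan(train, cfg)
        _, h2 = train_gan(train, cfg)
        assert h1.g_loss == h2.g_loss
        assert h1.d_loss == h2.d_loss

    def test_conditional_variant_runs(self, identity_datasets):
        train, _ = identity_datasets
        cfg = TrainConfig(epochs=1, seed=1, conditional=True)
        gen, history = train_gan(train, cfg)
        assert len(history) == 1


class TestCheckpoints:
    def test_round_trip_probe_equality(self, tmp_path):
        gen = build_generator(GeneratorSpec(input_len=640), seed=7)
        path = str(tmp_path / "gen.h5")
        save_checkpoint(gen, path)
        back = load_checkpoint(path)
        probe = np.random.default_rng(8).standard_normal((3, 640))
        np.testing.assert_array_equal(gen.forward(probe), back.forward(probe))

    def test_spec_mismatch_rejected(self, tmp_path):
        gen = build_generator(GeneratorSpec(input_len=640), seed=7)
        path = str(tmp_path / "gen.h5")
        save_checkpoint(gen, path)
        with pytest.raises(FormatError, match="spec"):
            load_checkpoint(path, spec=GeneratorSpec(input_len=512))

    def test_corrupt_file_rejected(self, tmp_path):
        path = tmp_path / "junk.h5"
        path.write_bytes(b"not an hdf5 file")
        with pytest.raises(FormatError):
            load_checkpoint(str(path))

    def test_mid_training_checkpoint_resumes(self, tmp_path, identity_datasets):
        train, _ = identity_datasets
        path = str(tmp_path / "mid.h5")
        cfg = TrainConfig(epochs=2, seed=5, checkpoint_every=1, checkpoint_path=path)
        _, h1 = train_gan(train, cfg)
        resumed = load_checkpoint(path)
        _, h2 = train_gan(train, TrainConfig(epochs=1, seed=6), generator=resumed)
        assert len(h1) + len(h2) == 3


class TestKFold:
    def test_folds_partition_indices(self):
        folds = kfold_split(23, k=5, seed=1)
        assert len(folds) == 5
        all_val = np.concatenate([v for _, v in folds])
        assert sorted(all_val.tolist()) == list(range(23))
        for tr, v in folds:
            assert not set(tr) & set(v)
            assert len(tr) + len(v) == 23

    def test_invalid_k(self):
        with pytest.raises(ValidationError):
            kfold_split(4, k=5)
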