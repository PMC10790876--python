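import numpy as np
import pytest

from eegadgan import contamination
from eegadgan.types import Recording, SnrGrid


@pytest.fixture(scope="session")
def recording_160hz() -> Recording:
    """60 s two-channel synthetic recording at 160 Hz."""
    rng = np.random.default_rng(7)
    t = np.arange(60 * 160) / 160.0
    ch0 = 30 * np.sin(2 * np.pi * 2.0 * t) + 10 * np.sin(2 * np.pi * 10.0 * t) \
        + rng.normal(0, 3, t.size)
    ch1 = 20 * np.sin(2 * np.pi * 6.0 * t) + rng.normal(0, 3, t.size)
    return Recording(samples=np.stack([ch0, ch1]), fs=160.0,
                     channel_labels=["C3", "C4"], subject_id="synthetic")


@pytest.fixture(scope="session")
def trained_mains_model():
    """A denoiser trained at the desk-scale study conditions: 500 synthetic
    mains-contaminated training pairs over the ten-level SNR grid, 40 epochs,
    fixed seed; returns (generator, train, test) with 130 held-out pairs."""
    from eegadgan.gan_denoiser import TrainConfig, train_gan

    clean = contamination.generate_clean_eeg(63, 640, 160.0, seed=11)
    mains = contamination.generate_mains_artifact(200, 640, 160.0, seed=12)
    train, test = contamination.build_mixed_dataset(
        clean, mains, SnrGrid(), seed=13, normalization="noisy_zscore")
    gen, _ = train_gan(train, TrainConfig(epochs=40, seed=1))
    return gen, train, test


@pytest.fixture(scope="session")
def small_mixed_datasets():
    """A compact normalized mains-contaminated train/test split (20 clean
    segments × ten SNR levels)."""
    clean = contamination.generate_clean_eeg(20, 640, 160.0, seed=11)
    mains = contamination.generate_mains_artifact(40, 640, 160.0, seed=12)
    return contamination.build_mixed_dataset(
        clean, mains, SnrGrid(), split_fraction=0.8, seed=13,
        normalization="noisy_zscore",
    )
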