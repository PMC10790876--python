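import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegadgan import contamination as cn
from eegadgan import evaluation as ev
from eegadgan.errors import ValidationError
from eegadgan.types import Recording, SnrGrid


class TestSegmentation:
    @pytest.mark.parametrize(
        "duration_s, window_s, overlap_s, expected",
        [(60.0, 4.0, 2.0, 29), (4.0, 4.0, 0.0, 1), (10.0, 2.0, 0.0, 5)],
    )
    def test_window_counts(self, duration_s, window_s, overlap_s, expected):
        fs = 160.0
        rec = Recording(samples=np.random.default_rng(0).normal(
            size=(1, int(duration_s * fs))), fs=fs, channel_labels=["C3"])
        bank = cn.segment_recording(rec, "C3", window_s, overlap_s)
        assert bank.n_segments == expected
        assert bank.length_N == int(window_s * fs)

    def test_windows_are_half_open_strides(self, recording_160hz):
        bank = cn.segment_recording(recording_160hz, "C3", 4.0, 2.0)
        np.testing.assert_array_equal(bank.segments[1],
                                      recording_160hz.samples[0][320:960])

    def test_too_short_recording_warns_and_is_empty(self):
        rec = Recording(samples=np.zeros((1, 480)), fs=160.0, channel_labels=["C3"])
        with pytest.warns(UserWarning, match="shorter"):
            bank = cn.segment_recording(rec, "C3", 4.0, 2.0)
        assert bank.n_segments == 0

    def test_invalid_overlap(self, recording_160hz):
        with pytest.raises(ValidationError):
            cn.segment_recording(recording_160hz, "C3", 2.0, 2.0)


class TestSyntheticGenerators:
    def test_clean_eeg_deterministic_per_seed(self):
        a = cn.generate_clean_eeg(10, 512, 256.0, seed=42)
        b = cn.generate_clean_eeg(10, 512, 256.0, seed=42)
        np.testing.assert_array_equal(a.segments, b.segments)

    def test_clean_eeg_band_ratios_normalized(self):
        bank = cn.generate_clean_eeg(100, 512, 256.0, seed=1)
        for seg in bank.segments:
            assert abs(sum(ev.band_power_ratios(seg, 256.0).vector) - 1.0) < 1e-9

    def test_clean_eeg_gamma_disabled(self):
        bank = cn.generate_clean_eeg(30, 512, 256.0, seed=2, include_gamma=False)
        assert all(ev.band_power_ratios(s, 256.0).gamma < 0.01 for s in bank.segments)

    def test_mains_rms_closed_form(self):
        A = 7.5
        bank = cn.generate_mains_artifact(5, 640, 160.0, amplitude_range=(A, A),
                                          freq_jitter=0.0, seed=3)
        for seg in bank.segments:
            assert abs(ev.rms(seg) - A / np.sqrt(2)) < 1e-6

    def test_mains_above_nyquist_rejected(self):
        with pytest.raises(ValidationError, match="Nyquist"):
            cn.generate_mains_artifact(5, 640, 90.0, f0=50.0)

    def test_mains_power_sits_in_gamma(self):
        bank = cn.generate_mains_artifact(5, 640, 160.0, seed=4)
        assert all(ev.band_power_ratios(s, 160.0).gamma > 0.99 for s in bank.segments)

    def test_eog_is_delta_dominated(self):
        bank = cn.generate_eog_artifact(20, 512, 256.0, seed=5)
        assert all(ev.band_power_ratios(s, 256.0).delta > 0.6 for s in bank.segments)

    def test_emg_is_high_frequency(self):
        bank = cn.generate_emg_artifact(20, 1024, 512.0, seed=6)
        for seg in bank.segments:
            r = ev.band_power_ratios(seg, 512.0)
            assert r.beta + r.gamma > 0.7

    def test_artifact_generators_deterministic(self):
        for gen in (cn.generate_eog_artifact, cn.generate_emg_artifact):
            a = gen(5, 512, 256.0, seed=9)
            b = gen(5, 512, 256.0, seed=9)
            np.testing.assert_array_equal(a.segments, b.segments)


class TestLambdaAndMixing:
    def test_equal_rms_zero_db_gives_unit_lambda(self):
        x = np.sin(np.linspace(0, 20, 256))
        n = np.cos(np.linspace(0, 20, 256))
        assert cn.lambda_for_snr(x, x, 0.0) == pytest.approx(1.0)
        assert cn.lambda_for_snr(x, n, 0.0) == pytest.approx(ev.rms(x) / ev.rms(n))

    def test_minus_ten_db_means_tenfold_noise(self):
        x = np.ones(100)
        n = np.ones(100)
        assert cn.lambda_for_snr(x, n, -10.0) == pytest.approx(10.0)

    def test_plus_four_db_closed_form(self):
        x = 2 * np.ones(64)
        n = np.ones(64)
        lam = cn.lambda_for_snr(x, n, 4.0)
        assert lam == pytest.approx(2 * 10 ** (-0.4), rel=1e-12)
        assert ev.snr_db(x, lam * n) == pytest.approx(4.0, abs=1e-9)

    def test_silent_artifact_rejected(self):
        with pytest.raises(ValidationError, match="RMS"):
            cn.lambda_for_snr(np.ones(10), np.zeros(10), 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(snr=st.floats(-20, 10), seed=st.integers(0, 1000))
    def test_snr_round_trip_property(self, snr, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=64)
        n = rng.normal(size=64)
        lam = cn.lambda_for_snr(x, n, snr)
        assert ev.snr_db(x, lam * n) == pytest.approx(snr, abs=1e-9)

    def test_lambda_monotone_in_target_snr(self):
        rng = np.random.default_rng(1)
        x, n = rng.normal(size=128), rng.normal(size=128)
        lams = [cn.lambda_for_snr(x, n, s) for s in np.arange(-14, 5, 2)]
        assert all(b < a for a, b in zip(lams, lams[1:]))

    def test_mix_pair_examples(self):
        x = np.array([1.0, 2.0])
        n = np.array([1.0, -1.0])
        pair = cn.mix_pair(x, n, 0.5, "mains")
        np.testing.assert_allclose(pair.y, [1.5, 1.5])
        np.testing.assert_array_equal(cn.mix_pair(x, n, 0.0, "mains").y, x)
        zeros = cn.mix_pair(np.zeros(2), n, 1.0, "mains")
        np.testing.assert_array_equal(zeros.y, n)

    def test_mix_pair_length_mismatch(self):
        with pytest.raises(ValidationError, match="mismatch"):
            cn.mix_pair(np.ones(4), np.ones(5), 1.0, "eog")


class TestDatasetAssembly:
    def test_tenfold_expansion_and_split(self):
        clean = cn.generate_clean_eeg(20, 640, 160.0, seed=1)
        art = cn.generate_mains_artifact(7, 640, 160.0, seed=2)
        train, test = cn.build_mixed_dataset(clean, art, SnrGrid(), 0.8, seed=3)
        assert (len(train), len(test)) == (160, 40)

    def test_single_level_single_segment(self):
        clean = cn.generate_clean_eeg(1, 640, 160.0, seed=4)
        art = cn.generate_mains_artifact(1, 640, 160.0, seed=5)
        train, test = cn.build_mixed_dataset(clean, art, SnrGrid((0.0,)), 1.0, seed=6)
        assert (len(train), len(test)) == (1, 0)
        pair = train.pairs[0]
        assert ev.snr_db(pair.x, pair.lam * pair.n) == pytest.approx(0.0, abs=1e-9)

    def test_split_sources_disjoint(self):
        clean = cn.generate_clean_eeg(17, 640, 160.0, seed=7)
        art = cn.generate_mains_artifact(5, 640, 160.0, seed=8)
        train, test = cn.build_mixed_dataset(clean, art, SnrGrid(), 0.8, seed=9)
        assert not ({p.clean_index for p in train.pairs}
                    & {p.clean_index for p in test.pairs})

    def test_determinism(self):
        clean = cn.generate_clean_eeg(6, 640, 160.0, seed=10)
        art = cn.generate_mains_artifact(3, 640, 160.0, seed=11)
        a_train, _ = cn.build_mixed_dataset(clean, art, SnrGrid(), 0.8, seed=12)
        b_train, _ = cn.build_mixed_dataset(clean, art, SnrGrid(), 0.8, seed=12)
        for p, q in zip(a_train.pairs, b_train.pairs):
            assert p.lam == q.lam
            np.testing.assert_array_equal(p.y, q.y)

    def test_mismatched_banks_rejected(self):
        clean = cn.generate_clean_eeg(4, 640, 160.0, seed=1)
        art = cn.generate_eog_artifact(4, 512, 256.0, seed=1)
        with pytest.raises(ValidationError):
            cn.build_mixed_dataset(clean, art, SnrGrid())


class TestNormalization:
    @pytest.fixture()
    def pair(self):
        rng = np.random.default_rng(0)
        x = rng.normal(5.0, 2.0, size=256)
        n = rng.normal(size=256)
        return cn.mix_pair(x, n, cn.lambda_for_snr(x, n, -2.0), "mains")

    def test_noisy_member_becomes_standard(self, pair):
        norm = cn.normalize_pair(pair)
        assert abs(np.mean(norm.y)) < 1e-9
        assert abs(np.std(norm.y) - 1.0) < 1e-9

    def test_round_trip_restores_amplitudes(self, pair):
        back = cn.denormalize_pair(cn.normalize_pair(pair))
        np.testing.assert_allclose(back.x, pair.x, rtol=1e-9)
        np.testing.assert_allclose(back.y, pair.y, rtol=1e-9)

    def test_shared_constants_keep_mixing_algebra(self, pair):
        norm = cn.normalize_pair(pair)
        np.testing.assert_allclose(norm.y - norm.x,
                                   pair.lam * pair.n / np.std(pair.y), atol=1e-9)

    def test_constant_noisy_segment_rejected(self):
        x = np.zeros(64)
        pair = cn.mix_pair(x, np.zeros(64), 0.0, "mains")
        with pytest.raises(ValidationError):
            cn.normalize_pair(pair)
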