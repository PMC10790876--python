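"""Quantitative evaluation of denoised EEG.

Metric definitions (all on single-channel segments):

* ``RMS(a) = sqrt(mean(a_i^2))``
* ``SNR = 10·log10(RMS(x)/RMS(λ·n))`` in dB — note this is an *amplitude*
  ratio under a 10·log10, the convention used consistently throughout this
  package (and inverted by the contamination module to derive λ).
* ``RRMSE_temporal = RMS(f(y) − x) / RMS(x)``
* ``RRMSE_spectral = RMS(PSD(f(y)) − PSD(x)) / RMS(PSD(x))``
* ``CC`` — Pearson correlation between the denoised segment and the clean
  target.

The PSD is a single Hann-tapered one-sided periodogram with FFT length equal
to the segment length (no averaging).  Band powers integrate that periodogram
over the conventional clinical bands; ratios are normalized by the sum over
the five bands, so they always sum to one.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .errors import ValidationError
from .types import PairedDataset

#: Clinical band edges in Hz; the gamma band is capped at min(100, fs/2).
DEFAULT_BAND_EDGES: Dict[str, tuple] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 100.0),
}

BAND_NAMES = tuple(DEFAULT_BAND_EDGES)

#: Metric values reported for the original full-scale training runs of this
#: denoising approach (external benchmark data, full training budget).  They
#: are kept as context for interpreting desk-scale results and are *not*
#: reproducible from the synthetic generators in this package.
FULL_SCALE_REFERENCE: Dict[str, float] = {
    "toy_mains_rrmse_temporal": 0.05,
    "toy_mains_rrmse_spectral": 0.1,
    "toy_mains_cc": 0.89,
    "classifier_f1_clean_vs_noisy": 0.8987,
    "classifier_accuracy_clean_vs_noisy": 0.8875,
    "classifier_f1_denoised_vs_noisy": 0.7799,
    "classifier_accuracy_denoised_vs_noisy": 0.7794,
}


def rms(a: np.ndarray) -> float:
    """Root of the mean square of a segment."""
    a = np.asarray(a, dtype=np.float64)
    if a.size == 0:
        raise ValidationError("RMS of an empty segment is undefined")
    return float(np.sqrt(np.mean(a * a)))


def snr_db(x: np.ndarray, scaled_noise: np.ndarray) -> float:
    """Amplitude-ratio SNR in dB between a clean segment and the scaled
    artefact actually added to it."""
    rn = rms(scaled_noise)
    if rn == 0.0:
        raise ValidationError("scaled noise has zero RMS; SNR undefined (infinite)")
    with np.errstate(divide="ignore"):
        return float(10.0 * np.log10(rms(x) / rn))


@dataclass
class PSDEstimate:
    """One-sided periodogram of a segment."""

    freqs: np.ndarray
    power: np.ndarray
    window: str = "hann"
    nfft: int = 0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.power = np.asarray(self.power, dtype=np.float64)
        if self.freqs.shape != self.power.shape:
            raise ValidationError("freqs and power must have equal length")


def psd(a: np.ndarray, fs: float) -> PSDEstimate:
    """Single Hann-tapered periodogram, FFT length = segment length."""
    a = np.asarray(a, dtype=np.float64)
    if a.size == 0:
        raise ValidationError("cannot estimate the PSD of an empty segment")
    freqs, power = sp_signal.periodogram(
        a, fs=fs, window="hann", nfft=len(a), detrend=False, scaling="density"
    )
    return PSDEstimate(freqs=freqs, power=power, window="hann", nfft=len(a))


def rrmse_temporal(denoised: np.ndarray, x: np.ndarray) -> float:
    """Time-domain relative RMSE against the clean target."""
    denoised = np.asarray(denoised, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    if denoised.shape != x.shape:
        raise ValidationError(f"shape mismatch: {denoised.shape} vs {x.shape}")
    rx = rms(x)
    if rx == 0.0:
        raise ValidationError("clean segment has zero RMS; relative error undefined")
    return rms(denoised - x) / rx


def rrmse_spectral(denoised: np.ndarray, x: np.ndarray, fs: float) -> float:
    """Relative RMSE between the two periodograms on their shared grid."""
    p_d = psd(denoised, fs)
    p_x = psd(x, fs)
    rx = rms(p_x.power)
    if rx == 0.0:
        raise ValidationError("clean PSD has zero RMS; relative error undefined")
    return rms(p_d.power - p_x.power) / rx


def pearson_cc(denoised: np.ndarray, x: np.ndarray) -> float:
    """Pearson correlation coefficient; affine-invariant in each argument."""
    denoised = np.asarray(denoised, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    if denoised.shape != x.shape:
        raise ValidationError(f"shape mismatch: {denoised.shape} vs {x.shape}")
    vd = np.var(denoised)
    vx = np.var(x)
    if vd == 0.0 or vx == 0.0:
        raise ValidationError("zero-variance segment; correlation undefined")
    cov = np.mean((denoised - denoised.mean()) * (x - x.mean()))
    return float(cov / np.sqrt(vd * vx))


@dataclass
class BandPowerRatios:
    """Fractions of (five-band) power per canonical EEG band; sum to one."""

    delta: float
    theta: float
    alpha: float
    beta: float
    gamma: float
    band_edges: Dict[str, tuple] = field(default_factory=dict)

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.delta, self.theta, self.alpha, self.beta, self.gamma])

    def __iter__(self):
        return iter(self.vector)


def band_power_ratios(a: np.ndarray, fs: float,
                      edges: Optional[Dict[str, tuple]] = None) -> BandPowerRatios:
    """Integrated periodogram power per band, normalized over the five bands.

    Bands are half-open ``[lo, hi)`` except the top band, which is closed at
    ``min(hi, fs/2)`` so the Nyquist bin is counted once.
    """
    edges = dict(edges or DEFAULT_BAND_EDGES)
    nyq = fs / 2.0
    lo_gamma = edges["gamma"][0]
    if nyq <= lo_gamma:
        raise ValidationError(
            f"fs/2 = {nyq} Hz is not above the gamma band floor ({lo_gamma} Hz)"
        )
    est = psd(a, fs)
    powers = {}
    used_edges = {}
    names = list(edges)
    for i, name in enumerate(names):
        lo, hi = edges[name]
        hi = min(hi, nyq)
        used_edges[name] = (lo, hi)
        if i == len(names) - 1:
            mask = (est.freqs >= lo) & (est.freqs <= hi)
        else:
            mask = (est.freqs >= lo) & (est.freqs < hi)
        powers[name] = float(np.sum(est.power[mask]))
    total = sum(powers.values())
    if total == 0.0:
        raise ValidationError("segment has no power inside the EEG bands")
    return BandPowerRatios(**{k: v / total for k, v in powers.items()},
                           band_edges=used_edges)


def cosine_similarity(r1, r2) -> float:
    """Cosine of the angle between two band-ratio vectors (or any vectors)."""
    v1 = r1.vector if isinstance(r1, BandPowerRatios) else np.asarray(r1, dtype=np.float64)
    v2 = r2.vector if isinstance(r2, BandPowerRatios) else np.asarray(r2, dtype=np.float64)
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValidationError("cosine similarity of a zero vector is undefined")
    return float(np.dot(v1, v2) / (n1 * n2))


@dataclass
class MetricsReport:
    """Per-SNR-level aggregation of the three denoising metrics.

    Each record holds the median and interquartile range over test pairs for
    RRMSE (temporal and spectral) and CC at one SNR level.
    """

    records: list

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            for metric in ("rrmse_temporal", "rrmse_spectral", "cc"):
                rows.append({
                    "snr_db": rec["snr_db"],
                    "metric": metric,
                    "value": rec[metric],
                    "dispersion": rec[f"{metric}_iqr"],
                    "n_pairs": rec["n_pairs"],
                })
        return pd.DataFrame(rows)

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)

    def level(self, snr: float) -> dict:
        for rec in self.records:
            if rec["snr_db"] == snr:
                return rec
        raise KeyError(f"no record at {snr} dB")


def _denormalized(pair, member_values: np.ndarray) -> np.ndarray:
    return member_values * pair.norm.scale + pair.norm.offset


def evaluate_across_snr(denoise_fn: Callable[[np.ndarray], np.ndarray],
                        test: PairedDataset, fs: Optional[float] = None,
                        include_noisy_baseline: bool = False) -> MetricsReport:
    """Run a denoiser over a labelled test set and aggregate per SNR level.

    ``denoise_fn`` maps a batch of segments *in the dataset's stored frame*
    (normalized, if the dataset is) to equal-shape outputs; metrics are then
    computed in the original amplitude frame using each pair's stored
    normalization constants.  ``include_noisy_baseline`` additionally records
    the metrics of the raw noisy segments against the clean targets.
    """
    if len(test) == 0:
        raise ValidationError("empty test dataset")
    fs = fs or test.fs
    Y = test.stacked("y")
    denoised = np.asarray(denoise_fn(Y))
    if denoised.shape != Y.shape:
        raise ValidationError(
            f"denoiser returned shape {denoised.shape}, expected {Y.shape}"
        )
    by_level: Dict[float, list] = {}
    for pair, out in zip(test.pairs, denoised):
        f_y = _denormalized(pair, out)
        x = _denormalized(pair, pair.x)
        y = _denormalized(pair, pair.y)
        entry = {
            "rrmse_temporal": rrmse_temporal(f_y, x),
            "rrmse_spectral": rrmse_spectral(f_y, x, fs),
            "cc": pearson_cc(f_y, x),
        }
        if include_noisy_baseline:
            entry.update({
                "noisy_rrmse_temporal": rrmse_temporal(y, x),
                "noisy_rrmse_spectral": rrmse_spectral(y, x, fs),
                "noisy_cc": pearson_cc(y, x),
            })
        by_level.setdefault(pair.snr_db, []).append(entry)
    records = []
    for level in sorted(by_level):
        entries = by_level[level]
        if not entries:
            warnings.warn(f"no pairs at {level} dB; level omitted", stacklevel=2)
            continue
        rec = {"snr_db": level, "n_pairs": len(entries)}
        keys = entries[0].keys()
        for key in keys:
            vals = np.array([e[key] for e in entries])
            rec[key] = float(np.median(vals))
            q1, q3 = np.percentile(vals, [25, 75])
            rec[f"{key}_iqr"] = float(q3 - q1)
        records.append(rec)
    return MetricsReport(records=records)


@dataclass
class DiscriminabilityResult:
    """Outcome of the clean-vs-noisy classifier probe."""

    f1_clean_vs_noisy: float
    accuracy_clean_vs_noisy: float
    f1_denoised_vs_noisy: float
    accuracy_denoised_vs_noisy: float


def _f1_accuracy(pred: np.ndarray, truth: np.ndarray) -> tuple:
    tp = int(np.sum((pred == 1) & (truth == 1)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return f1, float(np.mean(pred == truth))


def classifier_discriminability(clean: np.ndarray, noisy: np.ndarray,
                                denoised: np.ndarray, seed: int = 0,
                                epochs: int = 15, batch_size: int = 32,
                                lr: float = 1e-3, train_fraction: float = 0.75
                                ) -> DiscriminabilityResult:
    """How separable are noisy segments from clean — and from denoised?

    Trains a binary convolutional classifier (the discriminator architecture
    with a cross-entropy objective, decision threshold 0.5) on per-segment
    z-scored clean-vs-noisy data, then reports F1/accuracy on held-out
    clean-vs-noisy and denoised-vs-noisy sets.  A drop from the first F1 to
    the second means the denoiser moved its outputs toward the clean class.
    """
    from .gan_denoiser import Discriminator, DiscriminatorSpec
    from ._nn import Adam

    clean = np.atleast_2d(np.asarray(clean, dtype=np.float64))
    noisy = np.atleast_2d(np.asarray(noisy, dtype=np.float64))
    denoised = np.atleast_2d(np.asarray(denoised, dtype=np.float64))
    if min(len(clean), len(noisy), len(denoised)) < 8:
        raise ValidationError("need at least 8 segments per class")

    def zscore(batch):
        mu = batch.mean(axis=1, keepdims=True)
        sd = batch.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            raise ValidationError("constant segment cannot be z-scored")
        return (batch - mu) / sd

    clean, noisy, denoised = zscore(clean), zscore(noisy), zscore(denoised)
    rng = np.random.default_rng(seed)

    def split(batch):
        k = int(round(len(batch) * train_fraction))
        perm = rng.permutation(len(batch))
        return batch[perm[:k]], batch[perm[k:]]

    c_tr, c_te = split(clean)
    n_tr, n_te = split(noisy)
    _, d_te = split(denoised)
    if min(len(c_te), len(n_te), len(d_te)) == 0:
        raise ValidationError("train fraction leaves an empty test set")
    X = np.concatenate([c_tr, n_tr])
    t = np.concatenate([np.ones(len(c_tr)), np.zeros(len(n_tr))])
    spec = DiscriminatorSpec(input_len=X.shape[1])
    net = Discriminator(spec, np.random.default_rng(rng.integers(2**31)))
    opt = Adam(net.params, lr=lr)
    eps = 1e-7
    for _ in range(epochs):
        perm = rng.permutation(len(X))
        for start in range(0, len(X), batch_size):
            idx = perm[start : start + batch_size]
            xb, tb = X[idx], t[idx]
            p = np.clip(net.forward(xb), eps, 1 - eps)
            net.zero_grad()
            dp = (p - tb) / (p * (1 - p)) / len(idx)  # BCE gradient
            net.backward(dp)
            opt.step(net.grads)

    def predict(batch):
        return (net.forward(batch) >= 0.5).astype(int)

    pred_cn = np.concatenate([predict(c_te), predict(n_te)])
    truth_cn = np.concatenate([np.ones(len(c_te)), np.zeros(len(n_te))])
    f1_cn, acc_cn = _f1_accuracy(pred_cn, truth_cn)
    pred_dn = np.concatenate([predict(d_te), predict(n_te)])
    truth_dn = np.concatenate([np.ones(len(d_te)), np.zeros(len(n_te))])
    f1_dn, acc_dn = _f1_accuracy(pred_dn, truth_dn)
    return DiscriminabilityResult(
        f1_clean_vs_noisy=f1_cn, accuracy_clean_vs_noisy=acc_cn,
        f1_denoised_vs_noisy=f1_dn, accuracy_denoised_vs_noisy=acc_dn,
    )
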