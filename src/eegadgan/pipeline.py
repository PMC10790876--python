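"""Resampling and the two-stage cascade denoiser.

Artefact-specific models are trained at different sampling rates (mains at
160 Hz, ocular at 256 Hz, muscular at 512 Hz), so chaining them requires an
explicit band-limited rate conversion between stages.  The cascade applies
each stage's generator in order, resampling whenever the stage's rate differs
from the current one, and keeps a band-power audit trail so the effect of
every stage on the spectrum is visible.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import List, Optional, Union

import numpy as np
from scipy import signal as sp_signal

from .errors import ValidationError
from .evaluation import band_power_ratios
from .gan_denoiser import Generator, load_checkpoint

#: Largest denominator considered when expressing a rate change as a
#: rational polyphase factor.
_MAX_DENOMINATOR = 1000


def resample(segment: np.ndarray, fs_from: float, fs_to: float) -> np.ndarray:
    """Polyphase band-limited rate conversion of one segment or a batch.

    The ratio is expressed as a rational up/down factor (e.g. 160→256 Hz is
    8/5); output length is ``round(len · fs_to / fs_from)``.
    """
    if fs_from <= 0 or fs_to <= 0:
        raise ValidationError("sampling rates must be positive")
    segment = np.asarray(segment, dtype=np.float64)
    if fs_from == fs_to:
        return segment.copy()
    frac = Fraction(fs_to / fs_from).limit_denominator(_MAX_DENOMINATOR)
    return sp_signal.resample_poly(segment, frac.numerator, frac.denominator, axis=-1)


@dataclass
class CascadeStage:
    """One denoising stage: a generator (or checkpoint path) at a given rate."""

    model: Union[str, Generator]
    fs: float
    name: str = ""

    def load(self) -> Generator:
        if isinstance(self.model, (str, bytes)) or hasattr(self.model, "__fspath__"):
            return load_checkpoint(self.model)
        return self.model


@dataclass
class CascadeSpec:
    """Ordered denoising stages joined by explicit resampling."""

    stages: List[CascadeStage]
    resampler: str = "polyphase"
    renormalize: bool = True

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValidationError("cascade needs at least one stage")
        if self.resampler != "polyphase":
            raise ValidationError(f"unknown resampler {self.resampler!r}")


def cascade_denoise(spec: CascadeSpec, segments: np.ndarray, fs_in: float):
    """Run segments through every stage; returns (output, audit).

    Each audit entry records the stage name, the sampling rate and the mean
    band-power-ratio vector of the signal *after* that point (the first entry
    describes the raw input).  When ``renormalize`` is on, each stage sees
    per-segment z-scored input and its output is mapped back to the incoming
    amplitude frame.
    """
    batch = np.atleast_2d(np.asarray(segments, dtype=np.float64))
    single = np.asarray(segments).ndim == 1
    fs = float(fs_in)

    def ratios(data: np.ndarray, rate: float) -> np.ndarray:
        vecs = []
        for row in data:
            try:
                vecs.append(band_power_ratios(row, rate).vector)
            except ValidationError:  # degenerate (e.g. constant) segment
                continue
        return np.mean(vecs, axis=0) if vecs else np.full(5, np.nan)

    audit = [{"stage": "input", "fs": fs, "band_ratios": ratios(batch, fs)}]
    for i, stage in enumerate(spec.stages):
        label = stage.name or f"stage{i}"
        gen = stage.load()
        if stage.fs != fs:
            batch = resample(batch, fs, stage.fs)
            fs = float(stage.fs)
        if batch.shape[1] != gen.spec.input_len:
            raise ValidationError(
                f"cascade stage {label!r}: segments have length {batch.shape[1]} "
                f"at {fs} Hz but the model expects {gen.spec.input_len}"
            )
        if spec.renormalize:
            mu = batch.mean(axis=1, keepdims=True)
            sd = batch.std(axis=1, keepdims=True)
            if np.any(sd == 0):
                raise ValidationError(
                    f"cascade stage {label!r}: constant segment cannot be normalized"
                )
            batch = gen.forward((batch - mu) / sd) * sd + mu
        else:
            batch = gen.forward(batch)
        audit.append({"stage": label, "fs": fs, "band_ratios": ratios(batch, fs)})
    return (batch[0] if single else batch), audit
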