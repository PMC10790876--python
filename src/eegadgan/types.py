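"""Core domain containers.

Amplitudes are physical microvolts (μV) unless a segment has been normalized,
in which case the normalization constants travel with the pair so the original
frame can always be restored.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: Artefact / signal categories a segment bank can hold.
SEGMENT_KINDS = ("clean_eeg", "eog", "emg", "mains")

#: The ten contamination levels (dB) used to build mixed datasets.
DEFAULT_SNR_LEVELS_DB = (-14.0, -12.0, -10.0, -8.0, -6.0, -4.0, -2.0, 0.0, 2.0, 4.0)


def _as_float_array(a, name: str, ndim: int) -> np.ndarray:
    arr = np.asarray(a, dtype=np.float64)
    if arr.ndim != ndim:
        raise ValidationError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite samples")
    return arr


@dataclass
class Recording:
    """A continuous multichannel recording (channels × samples, μV)."""

    samples: np.ndarray
    fs: float
    channel_labels: list[str]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = _as_float_array(self.samples, "samples", 2)
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValidationError(
                f"{len(self.channel_labels)} labels for {self.samples.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Samples of one channel; unknown labels raise ValidationError."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise ValidationError(
                f"channel {label!r} not in recording (have {self.channel_labels})"
            ) from None
        return self.samples[idx]


@dataclass
class SegmentBank:
    """Equal-length single-channel epochs of one kind at one sampling rate."""

    segments: np.ndarray  # (n_segments, length_N)
    fs: float
    kind: str

    def __post_init__(self) -> None:
        self.segments = np.atleast_2d(np.asarray(self.segments, dtype=np.float64))
        if self.segments.size and not np.all(np.isfinite(self.segments)):
            raise ValidationError("segment bank contains non-finite samples")
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.kind not in SEGMENT_KINDS:
            raise ValidationError(f"kind must be one of {SEGMENT_KINDS}, got {self.kind!r}")

    @property
    def n_segments(self) -> int:
        return 0 if self.segments.size == 0 else self.segments.shape[0]

    @property
    def length_N(self) -> int:
        return self.segments.shape[1] if self.segments.ndim == 2 else 0

    def __len__(self) -> int:
        return self.n_segments


@dataclass
class NormalizationInfo:
    """Affine constants mapping stored samples back to the original frame:
    ``original = stored * scale + offset``."""

    scheme: str = "none"
    offset: float = 0.0
    scale: float = 1.0


@dataclass
class PairedExample:
    """One (clean, artefact, noisy) triple tied by the mixing model
    ``y = x + λ·n`` at a recorded SNR level.

    ``x``, ``n`` and ``y`` always satisfy the mixing identity elementwise —
    also after normalization, because both members are rescaled by the same
    constants (the artefact term is scaled, not shifted).
    """

    x: np.ndarray
    n: np.ndarray
    lam: float
    y: np.ndarray
    snr_db: float
    kind: str
    clean_index: int = -1
    norm: NormalizationInfo = field(default_factory=NormalizationInfo)

    def __post_init__(self) -> None:
        self.x = _as_float_array(self.x, "x", 1)
        self.n = _as_float_array(self.n, "n", 1)
        self.y = _as_float_array(self.y, "y", 1)
        if not (len(self.x) == len(self.n) == len(self.y)):
            raise ValidationError(
                f"segment lengths differ: x={len(self.x)} n={len(self.n)} y={len(self.y)}"
            )
        if self.lam < 0:
            raise ValidationError(f"lambda must be >= 0, got {self.lam}")
        resid = self.y - (self.x + self.lam * self.n)
        scale = max(float(np.max(np.abs(self.y))), 1.0)
        if float(np.max(np.abs(resid))) > 1e-9 * scale:
            raise ValidationError("pair violates y = x + lambda*n beyond 1e-9 relative")

    @property
    def length(self) -> int:
        return len(self.x)


@dataclass
class PairedDataset:
    """A split-tagged collection of paired examples sharing fs and length."""

    pairs: list[PairedExample]
    split: str
    fs: float
    normalization: str = "none"

    def __post_init__(self) -> None:
        if self.split not in ("train", "test"):
            raise ValidationError(f"split must be 'train' or 'test', got {self.split!r}")
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        lengths = {p.length for p in self.pairs}
        if len(lengths) > 1:
            raise ValidationError(f"pairs have differing lengths: {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def segment_length(self) -> int:
        return self.pairs[0].length if self.pairs else 0

    def stacked(self, member: str) -> np.ndarray:
        """Stack one member ('x', 'n' or 'y') into an (n_pairs, N) array."""
        if member not in ("x", "n", "y"):
            raise ValidationError(f"member must be 'x', 'n' or 'y', got {member!r}")
        return np.stack([getattr(p, member) for p in self.pairs])

    def snr_levels(self) -> list[float]:
        """Distinct SNR labels present, ascending."""
        return sorted({p.snr_db for p in self.pairs})


@dataclass(frozen=True)
class SnrGrid:
    """Ordered decibel levels at which pairs are synthesized."""

    levels: tuple = DEFAULT_SNR_LEVELS_DB

    def __post_init__(self) -> None:
        lv = tuple(float(v) for v in self.levels)
        if not lv:
            raise ValidationError("SNR grid must be nonempty")
        if any(b <= a for a, b in zip(lv, lv[1:])):
            raise ValidationError(f"SNR levels must be strictly increasing, got {lv}")
        object.__setattr__(self, "levels", lv)

    def __len__(self) -> int:
        return len(self.levels)

    def __iter__(self):
        return iter(self.levels)
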