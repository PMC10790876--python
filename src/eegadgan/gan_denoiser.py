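"""The adversarial denoiser: recurrent generator, convolutional discriminator,
least-squares losses and the training loop.

The generator receives a *noisy* EEG segment — not a latent draw — and emits a
same-length denoised segment.  It is a two-layer stacked LSTM with 50 hidden
units per layer; the segment is consumed in short non-overlapping frames and a
fully connected head maps the flattened hidden sequence back to the segment
length (linear output, since the regression target is an unbounded normalized
amplitude).  The discriminator is a 4-layer 1-D CNN (ReLU + max pooling per
block) with a dense head and sigmoid output that scores segments as real
(clean) vs generated (denoised).

Training alternates least-squares updates: the discriminator minimizes

    ½·E[(D(x) − b)²] + ½·E[(D(G(y)) − a)²]

and the generator minimizes ``½·E[(D(G(y)) − c)²]``, with the standard label
scheme a=0 (generated), b=1 (real), c=1 (what G wants D to say).

By default a unit-weight mean-squared reconstruction term is added to the
generator objective.  The adversarial terms alone match the *distribution* of
clean segments but carry no per-pair gradient — at the training budgets this
package targets they produce clean-looking output uncorrelated with the
specific target.  The reconstruction anchor ties each output to its paired
clean segment (the usual recipe in signal-to-signal adversarial models);
``recon_weight=0`` recovers the purely adversarial objective.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import h5py
import numpy as np

from ._nn import LSTM, Adam, Conv1d, Dense, MaxPool1d, ReLU, Sigmoid
from .errors import FormatError, ValidationError
from .evaluation import pearson_cc, rrmse_temporal
from .types import PairedDataset

CHECKPOINT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class GeneratorSpec:
    """Structure of the recurrent generator."""

    input_len: int
    recurrent_layers: int = 2
    hidden_units: int = 50
    frame_size: int = 8

    def __post_init__(self) -> None:
        if self.input_len <= 0:
            raise ValidationError(f"input_len must be positive, got {self.input_len}")
        if self.recurrent_layers < 1 or self.hidden_units < 1:
            raise ValidationError("need at least one recurrent layer and one unit")
        if self.frame_size < 1 or self.input_len % self.frame_size:
            raise ValidationError(
                f"input_len {self.input_len} must be divisible by frame_size "
                f"{self.frame_size}"
            )

    @property
    def n_frames(self) -> int:
        return self.input_len // self.frame_size


@dataclass(frozen=True)
class DiscriminatorSpec:
    """Structure of the convolutional discriminator."""

    input_len: int
    channels: tuple = (16, 32, 64, 128)
    kernel: int = 5
    pool: int = 2
    in_channels: int = 1

    def __post_init__(self) -> None:
        factor = self.pool ** len(self.channels)
        if self.input_len <= 0 or self.input_len % factor:
            raise ValidationError(
                f"input_len {self.input_len} must be a positive multiple of the "
                f"cumulative pooling factor {factor}"
            )

    @property
    def pooled_len(self) -> int:
        return self.input_len // self.pool ** len(self.channels)


def generator_parameter_count(spec: GeneratorSpec) -> int:
    """Closed-form parameter count of the generator.

    Each LSTM layer holds ``4H(F + H + 1)`` weights (input, recurrent and
    bias, four gates); the dense head maps each hidden state ``(H)`` to one
    output frame ``(F)`` plus bias and is shared across time steps.
    """
    H = spec.hidden_units
    count = 4 * H * (spec.frame_size + H + 1)
    for _ in range(spec.recurrent_layers - 1):
        count += 4 * H * (H + H + 1)
    count += H * spec.frame_size + spec.frame_size
    return count


class Generator:
    """Noisy-segment → denoised-segment network (see module docstring).

    The dense head is shared across time steps: hidden state ``h_t`` is
    mapped to the ``t``-th output frame, so every output sample has a short
    gradient path to the hidden state that saw the corresponding input.
    """

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        self.spec = spec
        self.lstms = [LSTM(spec.frame_size, spec.hidden_units, rng)]
        for _ in range(spec.recurrent_layers - 1):
            self.lstms.append(LSTM(spec.hidden_units, spec.hidden_units, rng))
        self.head = Dense(spec.hidden_units, spec.frame_size, rng)
        self._layers = [*self.lstms, self.head]

    @property
    def params(self) -> list:
        return [p for l in self._layers for p in l.params]

    @property
    def grads(self) -> list:
        return [g for l in self._layers for g in l.grads]

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params)

    def zero_grad(self) -> None:
        for l in self._layers:
            l.zero_grad()

    def forward(self, batch: np.ndarray) -> np.ndarray:
        batch = np.atleast_2d(np.asarray(batch, dtype=np.float64))
        B, L = batch.shape
        if L != self.spec.input_len:
            raise ValidationError(
                f"generator expects segments of length {self.spec.input_len}, got {L}"
            )
        T, F = self.spec.n_frames, self.spec.frame_size
        h = batch.reshape(B, T, F)
        for lstm in self.lstms:
            h = lstm.forward(h)
        self._hidden_shape = h.shape
        out = self.head.forward(h.reshape(B * T, self.spec.hidden_units))
        return out.reshape(B, self.spec.input_len)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B = dy.shape[0]
        T, F = self.spec.n_frames, self.spec.frame_size
        dh = self.head.backward(dy.reshape(B * T, F)).reshape(self._hidden_shape)
        for lstm in reversed(self.lstms):
            dh = lstm.backward(dh)
        return dh.reshape(B, self.spec.input_len)

    __call__ = forward


class Discriminator:
    """Segment → probability-of-real network (see module docstring)."""

    def __init__(self, spec: DiscriminatorSpec, rng: np.random.Generator):
        self.spec = spec
        layers = []
        in_ch = spec.in_channels
        for out_ch in spec.channels:
            layers += [Conv1d(in_ch, out_ch, spec.kernel, rng), ReLU(),
                       MaxPool1d(spec.pool)]
            in_ch = out_ch
        self._blocks = layers
        self.head = Dense(spec.channels[-1] * spec.pooled_len, 1, rng)
        self.out = Sigmoid()
        self._layers = [*self._blocks, self.head, self.out]

    @property
    def params(self) -> list:
        return [p for l in self._layers for p in l.params]

    @property
    def grads(self) -> list:
        return [g for l in self._layers for g in l.grads]

    def zero_grad(self) -> None:
        for l in self._layers:
            l.zero_grad()

    def forward(self, batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch, dtype=np.float64)
        if batch.ndim == 1:
            batch = batch[None, :]
        if batch.ndim == 2:
            batch = batch[:, None, :]
        B, C, L = batch.shape
        if C != self.spec.in_channels or L != self.spec.input_len:
            raise ValidationError(
                f"discriminator expects ({self.spec.in_channels}, "
                f"{self.spec.input_len}) inputs, got ({C}, {L})"
            )
        h = batch
        for l in self._blocks:
            h = l.forward(h)
        self._conv_shape = h.shape
        h = self.head.forward(h.reshape(B, -1))
        return self.out.forward(h)[:, 0]

    def backward(self, dscore: np.ndarray) -> np.ndarray:
        dh = self.out.backward(np.asarray(dscore)[:, None])
        dh = self.head.backward(dh).reshape(self._conv_shape)
        for l in reversed(self._blocks):
            dh = l.backward(dh)
        return dh

    __call__ = forward


def build_generator(spec: GeneratorSpec, seed: int = 0) -> Generator:
    """Seeded generator construction."""
    return Generator(spec, np.random.default_rng(seed))


def build_discriminator(spec: DiscriminatorSpec, seed: int = 0) -> Discriminator:
    """Seeded discriminator construction."""
    return Discriminator(spec, np.random.default_rng(seed))


def discriminator_loss(d_real: np.ndarray, d_fake: np.ndarray,
                       a: float = 0.0, b: float = 1.0) -> float:
    """Least-squares discriminator objective:
    ``½·mean((D_real − b)²) + ½·mean((D_fake − a)²)``."""
    d_real = np.asarray(d_real, dtype=np.float64)
    d_fake = np.asarray(d_fake, dtype=np.float64)
    if d_real.size == 0 or d_fake.size == 0:
        raise ValidationError("score batches must be nonempty")
    return float(0.5 * np.mean((d_real - b) ** 2) + 0.5 * np.mean((d_fake - a) ** 2))


def generator_loss(d_fake: np.ndarray, c: float = 1.0) -> float:
    """Least-squares generator objective: ``½·mean((D_fake − c)²)``."""
    d_fake = np.asarray(d_fake, dtype=np.float64)
    if d_fake.size == 0:
        raise ValidationError("score batch must be nonempty")
    return float(0.5 * np.mean((d_fake - c) ** 2))


@dataclass
class TrainConfig:
    """Knobs of the adversarial training loop.

    ``a``/``b``/``c`` are the least-squares labels for generated/real samples
    and the generator's target.  ``recon_weight`` adds a weighted MSE
    reconstruction term to the generator objective when positive (default 0:
    purely adversarial).  ``conditional`` feeds the discriminator the noisy
    input as a second channel alongside the candidate segment.
    """

    a: float = 0.0
    b: float = 1.0
    c: float = 1.0
    epochs: int = 40
    batch_size: int = 32
    lr_g: float = 3e-3
    lr_d: float = 1e-3
    seed: int = 0
    d_steps: int = 1
    recon_weight: float = 1.0
    conditional: bool = False
    checkpoint_every: int = 0
    checkpoint_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValidationError("labels a (generated) and b (real) must differ")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("epochs and batch_size must be positive")


@dataclass
class TrainingHistory:
    """Per-epoch losses plus optional held-out metrics."""

    g_loss: list = field(default_factory=list)
    d_loss: list = field(default_factory=list)
    val_rrmse_t: list = field(default_factory=list)
    val_cc: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.g_loss)


def train_gan(train: PairedDataset, config: TrainConfig,
              gen_spec: Optional[GeneratorSpec] = None,
              disc_spec: Optional[DiscriminatorSpec] = None,
              val: Optional[PairedDataset] = None,
              generator: Optional[Generator] = None
              ) -> Tuple[Generator, TrainingHistory]:
    """Alternating least-squares adversarial training.

    Per batch the discriminator is updated on (clean-as-real,
    denoised-as-fake), then the generator on the refreshed discriminator.
    Everything that consumes randomness (initialization, data order) is
    derived from ``config.seed``; repeated runs are bitwise identical on one
    platform.  ``generator`` warm-starts training from an existing model
    (e.g. a loaded checkpoint).
    """
    if len(train) == 0:
        raise ValidationError("training dataset is empty")
    L = train.segment_length
    gen_spec = gen_spec or GeneratorSpec(input_len=L)
    disc_spec = disc_spec or DiscriminatorSpec(
        input_len=L, in_channels=2 if config.conditional else 1
    )
    if gen_spec.input_len != L:
        raise ValidationError(
            f"generator input_len {gen_spec.input_len} != segment length {L}"
        )
    if config.conditional and disc_spec.in_channels != 2:
        raise ValidationError("conditional training needs a 2-channel discriminator")

    ss = np.random.SeedSequence(config.seed)
    seed_g, seed_d, seed_order = ss.spawn(3)
    gen = generator if generator is not None else Generator(
        gen_spec, np.random.default_rng(seed_g)
    )
    disc = Discriminator(disc_spec, np.random.default_rng(seed_d))
    opt_g = Adam(gen.params, lr=config.lr_g)
    opt_d = Adam(disc.params, lr=config.lr_d)
    order_rng = np.random.default_rng(seed_order)

    X = train.stacked("x")
    Y = train.stacked("y")
    history = TrainingHistory()
    n = len(train)

    def d_input(candidate: np.ndarray, condition: np.ndarray) -> np.ndarray:
        if config.conditional:
            return np.stack([candidate, condition], axis=1)
        return candidate

    for epoch in range(config.epochs):
        perm = order_rng.permutation(n)
        g_losses, d_losses = [], []
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            xb, yb = X[idx], Y[idx]
            m = len(idx)

            fake = gen.forward(yb)
            for _ in range(config.d_steps):
                disc.zero_grad()
                p_real = disc.forward(d_input(xb, yb))
                disc.backward((p_real - config.b) / m)
                p_fake = disc.forward(d_input(fake, yb))
                disc.backward((p_fake - config.a) / m)
                opt_d.step(disc.grads)
            d_batch = discriminator_loss(p_real, p_fake, config.a, config.b)

            gen.zero_grad()
            fake = gen.forward(yb)
            disc.zero_grad()
            p = disc.forward(d_input(fake, yb))
            dfake = disc.backward((p - config.c) / m)
            if config.conditional:
                dfake = dfake[:, 0, :]
            else:
                dfake = dfake[:, 0, :] if dfake.ndim == 3 else dfake
            g_batch = generator_loss(p, config.c)
            if config.recon_weight > 0:
                resid = fake - xb
                dfake = dfake + config.recon_weight * 2.0 * resid / resid.size
                g_batch += config.recon_weight * float(np.mean(resid**2))
            gen.backward(dfake)
            opt_g.step(gen.grads)

            if not (np.isfinite(g_batch) and np.isfinite(d_batch)):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {start // config.batch_size}"
                    f" (G={g_batch}, D={d_batch})"
                )
            g_losses.append(g_batch)
            d_losses.append(d_batch)
        history.g_loss.append(float(np.mean(g_losses)))
        history.d_loss.append(float(np.mean(d_losses)))

        if val is not None and len(val):
            out = gen.forward(val.stacked("y"))
            rr, cc = [], []
            for pair, o in zip(val.pairs, out):
                f_y = o * pair.norm.scale + pair.norm.offset
                x = pair.x * pair.norm.scale + pair.norm.offset
                rr.append(rrmse_temporal(f_y, x))
                cc.append(pearson_cc(f_y, x))
            history.val_rrmse_t.append(float(np.median(rr)))
            history.val_cc.append(float(np.median(cc)))

        if (config.checkpoint_every and config.checkpoint_path
                and (epoch + 1) % config.checkpoint_every == 0):
            save_checkpoint(gen, config.checkpoint_path)

    return gen, history


def denoise(generator: Generator, segments: np.ndarray,
            constants=None) -> np.ndarray:
    """Apply a trained generator to segments (stored/normalized frame).

    ``constants`` — a NormalizationInfo or a sequence of them, one per
    segment — denormalizes the outputs back to physical amplitudes.
    """
    arr = np.asarray(segments, dtype=np.float64)
    single = arr.ndim == 1
    out = generator.forward(arr)
    if constants is not None:
        infos = [constants] if not isinstance(constants, (list, tuple)) else list(constants)
        if len(infos) == 1:
            infos = infos * out.shape[0]
        if len(infos) != out.shape[0]:
            raise ValidationError(
                f"{len(infos)} normalization constants for {out.shape[0]} segments"
            )
        out = np.stack([o * c.scale + c.offset for o, c in zip(out, infos)])
    return out[0] if single else out


def as_denoiser(generator: Generator):
    """Wrap a generator as a plain batch-callable for evaluation helpers."""
    return lambda batch: generator.forward(batch)


def save_checkpoint(generator: Generator, path: str) -> None:
    """Persist generator spec + parameters to an HDF5 checkpoint."""
    spec = generator.spec
    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = CHECKPOINT_SCHEMA_VERSION
        fh.attrs["model"] = "generator"
        fh.attrs["input_len"] = spec.input_len
        fh.attrs["recurrent_layers"] = spec.recurrent_layers
        fh.attrs["hidden_units"] = spec.hidden_units
        fh.attrs["frame_size"] = spec.frame_size
        for i, p in enumerate(generator.params):
            fh.create_dataset(f"param_{i:03d}", data=p)


def load_checkpoint(path: str, spec: Optional[GeneratorSpec] = None) -> Generator:
    """Load a generator; a provided spec must match the stored one exactly."""
    try:
        fh = h5py.File(path, "r")
    except OSError as exc:
        raise FormatError(f"{path}: not a readable checkpoint ({exc})")
    with fh:
        version = int(fh.attrs.get("schema_version", -1))
        if version != CHECKPOINT_SCHEMA_VERSION:
            raise FormatError(
                f"{path}: checkpoint schema {version} unsupported "
                f"(expected {CHECKPOINT_SCHEMA_VERSION})"
            )
        stored = GeneratorSpec(
            input_len=int(fh.attrs["input_len"]),
            recurrent_layers=int(fh.attrs["recurrent_layers"]),
            hidden_units=int(fh.attrs["hidden_units"]),
            frame_size=int(fh.attrs["frame_size"]),
        )
        if spec is not None and spec != stored:
            raise FormatError(
                f"{path}: checkpoint spec {stored} does not match requested {spec}"
            )
        gen = Generator(stored, np.random.default_rng(0))
        names = sorted(k for k in fh.keys() if k.startswith("param_"))
        if len(names) != len(gen.params):
            raise FormatError(
                f"{path}: {len(names)} parameter arrays for a model with "
                f"{len(gen.params)}"
            )
        for name, p in zip(names, gen.params):
            data = fh[name][()]
            if data.shape != p.shape:
                raise FormatError(f"{path}: parameter {name} has shape {data.shape}, "
                                  f"expected {p.shape}")
            p[...] = data
    return gen


def kfold_split(n_clean: int, k: int = 5, seed: int = 0) -> list:
    """Seeded k-fold partition of clean-source indices.

    Returns ``k`` (train_indices, val_indices) pairs; folds are disjoint and
    cover all indices.
    """
    if not 2 <= k <= n_clean:
        raise ValidationError(f"need 2 <= k <= n_clean, got k={k}, n={n_clean}")
    perm = np.random.default_rng(seed).permutation(n_clean)
    folds = np.array_split(perm, k)
    out = []
    for i in range(k):
        val = folds[i]
        tr = np.concatenate([folds[j] for j in range(k) if j != i])
        out.append((np.sort(tr), np.sort(val)))
    return out
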