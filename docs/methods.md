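# Methods

## The problem and the model

Scalp EEG recorded outside the laboratory is routinely swamped by ocular
(EOG) activity, muscle (EMG) activity and power-line interference. This
package frames artefact removal as supervised signal-to-signal translation:
a generator network G maps a noisy single-channel segment y to a denoised
segment of the same length, and a discriminator D is trained to tell clean
segments from G's outputs. Unlike the usual generative setting, G's input is
not a latent draw — it is the noisy segment itself, and the training data are
(clean, noisy) pairs manufactured by controlled contamination.

### Contamination model

Pairs are built by linear mixing,

    y = x + λ·n,

where x is a clean segment, n an artefact segment of the same length and
sampling rate, and λ ≥ 0 a scalar. The SNR convention is an amplitude ratio
under 10·log10,

    SNR = 10·log10( RMS(x) / RMS(λ·n) )  [dB],

which is implemented exactly as stated even though the more common amplitude
convention uses 20·log10; λ is obtained by inverting it,
λ = (RMS(x)/RMS(n))·10^(−SNR/10). Every dataset spans ten SNR levels
(−14 … +4 dB in 2 dB steps). Clean segments are split 80/20 into train/test
*before* mixing, so no clean source appears on both sides; each clean
segment is then paired with a randomly drawn artefact (with replacement)
once per level, expanding the data tenfold.

Each pair is normalized by the *noisy* member's mean and standard deviation,
applied identically to x and y (n is scaled but not shifted, preserving the
mixing identity). This keeps the clean target expressed in the frame the
network sees and is exactly invertible; a max-abs scheme is available behind
the same config key. Normalization is per pair, not dataset-global — the
per-pair choice makes the constants trivially invertible at inference and
lets a single model serve all contamination levels.

### Networks

* **Generator** — a two-layer stacked LSTM, 50 hidden units per layer, with
  a dense head, linear output. The segment is consumed in non-overlapping
  frames (default 8 samples), and the head is shared across time steps:
  hidden state h_t produces output frame t. The per-timestep head was chosen
  over a head on the flattened hidden sequence after the latter proved an
  order of magnitude slower to train and unable to approach the identity map
  on λ=0 data at comparable budgets; the per-frame form gives every output
  sample a short gradient path to the hidden state that saw it. Input
  lengths follow the window arithmetic: 640 samples (4 s at 160 Hz) for
  mains experiments, 512 (2 s at 256 Hz) for EOG, 1024 (2 s at 512 Hz) for
  EMG; all configurable.
* **Discriminator** — four 1-D convolution blocks (channels 16/32/64/128,
  kernel 5, ReLU, max-pool 2), dense head, sigmoid output. Input length must
  be divisible by the cumulative pooling factor (16 by default).

Both networks, backpropagation and the Adam optimizer are implemented in
numpy inside the package (`_nn.py`); runs are bitwise reproducible for a
fixed seed on a fixed platform, and all layer gradients are validated
against central finite differences in the test suite.

### Objective

Least-squares adversarial losses with labels a=0 (generated), b=1 (real),
c=1 (generator's target):

    L_D = ½·E[(D(x) − b)²] + ½·E[(D(G(y)) − a)²]
    L_G = ½·E[(D(G(y)) − c)²]  +  w·E[(G(y) − x)²]

with one discriminator step per generator step. The reconstruction weight w
defaults to 1. The purely adversarial objective (w = 0) is retained as a
configuration but is not the default, for a reason worth stating plainly:
the adversarial terms match the *distribution* of clean segments and carry
no per-pair gradient. In a controlled run (500 training pairs, 60 epochs)
the purely adversarial model produced clean-looking output essentially
uncorrelated with its paired target (CC ≈ 0 at every SNR level) while a
unit-weight MSE anchor — the standard recipe in paired signal-to-signal
adversarial models — yields strong paired denoising at the same budget.
The adversarial term still shapes the output distribution; the anchor ties
each output to its own target.

A conditional variant (discriminator sees the noisy input as a second
channel next to the candidate segment) is available behind a flag; the
default is unconditional real=clean / fake=denoised.

### Training defaults and units

| knob | default | note |
|---|---|---|
| epochs | 40 | desk-scale budget; see below |
| batch size | 32 | |
| Adam lr (G / D) | 3e-3 / 1e-3 | chosen for convergence of the numpy LSTM at small budgets; 1e-4 stalls |
| labels a, b, c | 0, 1, 1 | standard 0-1-1 scheme |
| recon weight w | 1.0 | 0 restores the purely adversarial objective |
| frame size | 8 samples | must divide the input length |

Amplitudes are microvolts throughout; segments are normalized per pair
before training and denormalized with the stored constants for evaluation.

## Synthetic data

The generators emulate the spectral signatures that drive both the
contamination procedure and the evaluation:

* **Clean EEG** — one narrowband oscillation per canonical band (delta
  20–40 μV, theta 10–20, alpha 10–25, beta 3–8, gamma 1–4, random carrier
  and phase) over 1/f-shaped background noise (5 μV RMS). Band-ratio vectors
  behave like resting EEG (delta/theta dominant); the gamma component can be
  disabled.
* **Mains** — sinusoids with per-segment amplitude drawn uniformly (default
  5–20 μV) and frequency within ±0.5 Hz of 50 Hz.
* **EOG surrogate** — sparse Gaussian blink pulses (80–150 ms, 50–150 μV) on
  a weak noise floor; delta-dominated.
* **EMG surrogate** — broadband noise high-passed above 20 Hz under a smooth
  burst envelope, 20–60 μV RMS; beta/gamma-dominated.

What these surrogates do **not** reproduce: the nonstationarity and channel
covariance of real EEG, real blink morphology (overshoot, asymmetry), EMG
spectral slopes, electrode-pop and drift artefacts. Passing tests therefore
demonstrate that the pipeline learns and removes *spectrally structured
contamination under the stated mixing model*, not performance on clinical
recordings; the published full-scale results on real benchmark data are kept
in `evaluation.FULL_SCALE_REFERENCE` as context only.

## Evaluation

PSDs are single Hann-tapered one-sided periodograms with FFT length equal to
the segment length, no averaging. Metrics: RRMSE in time and in PSD domain,
Pearson correlation, and five-band power ratios with clinical edges
delta 0.5–4, theta 4–8, alpha 8–13, beta 13–30, gamma 30–min(100, fs/2) Hz
(the published ratio tables are reproduced by these edges; the ratio
denominator is the sum over the five bands, excluding sub-0.5 Hz power).
Per-SNR-level aggregation reports the median and interquartile range — the
median is robust to the heavy-tailed errors small models produce at −14 dB.
Cosine similarity between band-ratio vectors summarizes spectral fidelity in
one number; scores are reported to 3 decimal places.

The classifier probe trains the discriminator architecture with a
cross-entropy loss (threshold 0.5) to separate per-segment z-scored clean
from noisy segments, then reports F1/accuracy on held-out clean-vs-noisy and
denoised-vs-noisy sets.

## Cascade

Signals carrying both mains noise and an ocular artefact are cleaned by
chaining artefact-specific models: mains model at 160 Hz → polyphase
resampling (160→256 Hz is the rational factor 8/5) → EOG model at 256 Hz.
Between stages each segment is re-normalized (per-segment z-score) by
default, since consecutive models were trained in normalized frames; a flag
disables this. An audit trail records the mean band-ratio vector after every
stage; degenerate (constant) segments contribute NaN rather than aborting
the audit.

## Numerical choices and degenerate inputs

* λ requires RMS(n) > 0; silent artefacts are rejected, as are zero-variance
  noisy segments at normalization and zero-RMS references in relative
  errors.
* Pairs validate y = x + λ·n to 1e-9 relative at construction and after any
  round trip; dataset containers store float64 so the identity survives
  storage.
* Segmentation drops trailing partial windows (fixed network input length);
  windows are half-open, 0-based.
* Trained-model checkpoints carry a schema version and the full generator
  spec; mismatches fail loudly rather than loading approximately.
* EDF amplitudes are converted to physical μV on read; the minimal EDF
  writer quantizes to the format's 16-bit range (step = span/65534).

## Problem sizes

Desk-scale study conditions used by the heavier tests: 63 clean segments ×
ten SNR levels → 500 training / 130 held-out pairs of 640 samples at 160 Hz,
40 training epochs. The cascade integration check trains a second, ocular
stage at 256 Hz (36 clean segments × four SNR levels → 116 training pairs of
1024 samples, 20 epochs) and feeds doubly contaminated segments through
mains stage → 160→256 Hz polyphase resampling → ocular stage. Under these conditions the trained model improves the
median RRMSE_t and CC over the noisy baseline at every SNR level and moves
the gamma-band ratio toward the clean value for over 90% of held-out pairs.
Full-scale results quoted for the original experiments (RRMSE_t 0.05 on the
mains task, Table-3-level cosine scores from trained models on the external
benchmark) require the external datasets and far larger budgets and are not
asserted by the test suite.

## Known limitations

* Single-channel, fixed-length segments only; no streaming or multi-channel
  joint modelling.
* The amplitude-ratio SNR (10·log10) follows the stated convention; datasets
  built under the 20·log10 convention will sit at twice the nominal dB
  distance from ours.
* The numpy networks are CPU-bound and intentionally small; they are not a
  route to full-scale training.
* MAT-file support covers 2-D numeric arrays (the benchmark layout), not
  arbitrary MATLAB structures.
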