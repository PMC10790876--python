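"""Readers and writers for the formats the pipeline touches.

* EDF/EDF+ recordings (read via MNE; a minimal EDF writer is provided so test
  fixtures can be created without external data).  Amplitudes are exposed in
  physical microvolts only — digital values never leave this module.
* Segment banks: 2-D arrays (segments × samples) stored in HDF5 or MAT-file
  containers, the layout the EEGdenoiseNet benchmark ships.
* The package's own paired-dataset HDF5 container with groups ``/train`` and
  ``/test`` and per-pair datasets ``x``, ``n``, ``y``.
"""
from __future__ import annotations

import os
import warnings
from typing import Optional, Sequence

import h5py
import numpy as np

from .errors import FormatError, ValidationError
from .types import (
    NormalizationInfo,
    PairedDataset,
    PairedExample,
    Recording,
    SEGMENT_KINDS,
    SegmentBank,
)

#: Schema version written into paired-dataset containers.
PAIRED_SCHEMA_VERSION = 1

#: Segment lengths the bank-orientation heuristic recognises out of the box
#: (the benchmark's ocular and muscular epochs).
KNOWN_SEGMENT_LENGTHS = (512, 1024)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def read_edf(path: str, channels: Optional[Sequence[str]] = None) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (μV).

    Parameters
    ----------
    path
        EDF file on disk.
    channels
        Optional subset of channel labels to load, in the requested order.
        Unknown labels raise :class:`ValidationError`.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = list(raw.ch_names)
    if channels is not None:
        missing = [c for c in channels if c not in labels]
        if missing:
            raise ValidationError(f"channel(s) {missing} not present in {path}")
        raw = raw.pick(list(channels))
        labels = list(channels)
    data_uv = raw.get_data() * 1e6  # MNE holds volts internally
    subject = os.path.splitext(os.path.basename(path))[0]
    return Recording(samples=data_uv, fs=float(raw.info["sfreq"]),
                     channel_labels=labels, subject_id=subject)


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path: str) -> None:
    """Write a minimal single-record EDF file (fixture support).

    Amplitudes are quantized to the 16-bit digital range per channel; the
    quantization step is ``(phys_max - phys_min) / 65534``.
    """
    ns = rec.n_channels
    duration = rec.duration_s
    dur_str = f"{duration:.6g}"
    if len(dur_str) > 8:
        raise ValidationError(f"record duration {duration} does not fit EDF header")
    header = b"".join([
        _edf_field("0", 8),
        _edf_field(rec.subject_id or "X", 80),
        _edf_field("fixture", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 + ns * 256, 8),
        _edf_field("", 44),
        _edf_field(1, 8),
        _edf_field(dur_str, 8),
        _edf_field(ns, 4),
    ])
    phys_min, phys_max, digital = [], [], []
    for ch in rec.samples:
        lo, hi = float(np.min(ch)), float(np.max(ch))
        if hi <= lo:
            hi = lo + 1.0
        scale = (hi - lo) / 65534.0
        dig = np.round((ch - lo) / scale).astype(np.int64) - 32767
        phys_min.append(lo)
        phys_max.append(hi)
        digital.append(np.clip(dig, -32768, 32767).astype("<i2"))
    per_signal = b"".join([
        b"".join(_edf_field(lbl, 16) for lbl in rec.channel_labels),
        b"".join(_edf_field("", 80) for _ in range(ns)),
        b"".join(_edf_field("uV", 8) for _ in range(ns)),
        b"".join(_edf_field(f"{v:.6g}", 8) for v in phys_min),
        b"".join(_edf_field(f"{v:.6g}", 8) for v in phys_max),
        b"".join(_edf_field(-32767, 8) for _ in range(ns)),
        b"".join(_edf_field(32767, 8) for _ in range(ns)),
        b"".join(_edf_field("", 80) for _ in range(ns)),
        b"".join(_edf_field(rec.n_samples, 8) for _ in range(ns)),
        b"".join(_edf_field("", 32) for _ in range(ns)),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        for dig in digital:
            fh.write(dig.tobytes())


# ---------------------------------------------------------------------------
# Segment banks
# ---------------------------------------------------------------------------

def _orient_segments(arr: np.ndarray, expected_length: Optional[int]) -> np.ndarray:
    """Return the array as (segments × samples), auto-detecting orientation."""
    r, c = arr.shape
    known = set(KNOWN_SEGMENT_LENGTHS)
    if expected_length is not None:
        known = {int(expected_length)}
    if c in known and r not in known:
        return arr
    if r in known and c not in known:
        return arr.T
    if r < c:
        # more samples than segments is the typical bank layout
        return arr
    if r > c:
        warnings.warn(
            "segment-bank orientation ambiguous; assuming rows are segments",
            stacklevel=3,
        )
    return arr


def _first_2d_numeric(obj) -> Optional[np.ndarray]:
    found = []

    def visit(name, node):
        if isinstance(node, h5py.Dataset) and node.ndim == 2 and \
                np.issubdtype(node.dtype, np.number):
            found.append(node[()])

    obj.visititems(visit)
    return found[0] if found else None


def read_segment_bank(path: str, kind: str, fs: float,
                      expected_length: Optional[int] = None) -> SegmentBank:
    """Load a segment bank from an HDF5 or MAT-file container.

    The first 2-D numeric array found in the container is used; MATLAB v7.3
    files are HDF5 and handled directly, older MAT versions go through
    :func:`scipy.io.loadmat`.
    """
    if kind not in SEGMENT_KINDS:
        raise ValidationError(f"kind must be one of {SEGMENT_KINDS}, got {kind!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    arr = None
    try:
        with h5py.File(path, "r") as fh:
            arr = _first_2d_numeric(fh)
    except OSError:
        from scipy.io import loadmat

        try:
            mat = loadmat(path)
        except Exception as exc:  # noqa: BLE001 - reported as format error
            raise FormatError(f"{path}: neither HDF5 nor readable MAT-file ({exc})")
        for key, val in mat.items():
            if key.startswith("__"):
                continue
            val = np.asarray(val)
            if val.ndim == 2 and np.issubdtype(val.dtype, np.number):
                arr = val
                break
    if arr is None or arr.size == 0:
        raise FormatError(f"{path}: no segments (no non-empty 2-D numeric array found)")
    arr = np.asarray(arr, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise FormatError(f"{path}: non-finite values in segment bank")
    arr = _orient_segments(arr, expected_length)
    if expected_length is not None and arr.shape[1] != expected_length:
        raise FormatError(
            f"{path}: segments have length {arr.shape[1]}, expected {expected_length}"
        )
    return SegmentBank(segments=arr, fs=fs, kind=kind)


def write_segment_bank(bank: SegmentBank, path: str) -> None:
    """Store a bank as HDF5 (dataset ``segments`` + fs/kind attributes)."""
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("segments", data=bank.segments)
        ds.attrs["fs"] = bank.fs
        ds.attrs["kind"] = bank.kind


# ---------------------------------------------------------------------------
# Paired datasets
# ---------------------------------------------------------------------------

def write_paired_dataset(dataset, path: str) -> None:
    """Write one or several :class:`PairedDataset` splits to an HDF5 container.

    Layout: ``/<split>/pair<i>/{x,n,y}`` with per-pair attributes ``lambda``,
    ``snr_db``, ``kind``, ``clean_index`` and normalization constants; the
    root carries the schema version.
    """
    datasets = [dataset] if isinstance(dataset, PairedDataset) else list(dataset)
    if not datasets or any(len(d) == 0 for d in datasets):
        raise ValidationError("refusing to write an empty paired dataset")
    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = PAIRED_SCHEMA_VERSION
        for ds in datasets:
            grp = fh.create_group(ds.split)
            grp.attrs["fs"] = ds.fs
            grp.attrs["normalization"] = ds.normalization
            for i, pair in enumerate(ds.pairs):
                pg = grp.create_group(f"pair{i:06d}")
                pg.create_dataset("x", data=pair.x)
                pg.create_dataset("n", data=pair.n)
                pg.create_dataset("y", data=pair.y)
                pg.attrs["lambda"] = pair.lam
                pg.attrs["snr_db"] = pair.snr_db
                pg.attrs["kind"] = pair.kind
                pg.attrs["clean_index"] = pair.clean_index
                pg.attrs["norm_scheme"] = pair.norm.scheme
                pg.attrs["norm_offset"] = pair.norm.offset
                pg.attrs["norm_scale"] = pair.norm.scale


def read_paired_dataset(path: str, split: Optional[str] = None) -> PairedDataset:
    """Read one split back; ``split=None`` is allowed when the file holds one."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        fh = h5py.File(path, "r")
    except OSError as exc:
        raise FormatError(f"{path}: not a readable HDF5 container ({exc})")
    with fh:
        version = int(fh.attrs.get("schema_version", -1))
        if version > PAIRED_SCHEMA_VERSION:
            raise FormatError(
                f"{path}: schema version {version} is newer than supported "
                f"({PAIRED_SCHEMA_VERSION})"
            )
        if version < 0:
            raise FormatError(f"{path}: missing schema version attribute")
        splits = sorted(fh.keys())
        if split is None:
            if len(splits) != 1:
                raise ValidationError(
                    f"{path} holds splits {splits}; pass split= to choose one"
                )
            split = splits[0]
        if split not in fh:
            raise FormatError(f"{path}: no split {split!r} (have {splits})")
        grp = fh[split]
        pairs = []
        for name in sorted(grp.keys()):
            pg = grp[name]
            pairs.append(PairedExample(
                x=pg["x"][()], n=pg["n"][()], y=pg["y"][()],
                lam=float(pg.attrs["lambda"]),
                snr_db=float(pg.attrs["snr_db"]),
                kind=str(pg.attrs["kind"]),
                clean_index=int(pg.attrs["clean_index"]),
                norm=NormalizationInfo(
                    scheme=str(pg.attrs["norm_scheme"]),
                    offset=float(pg.attrs["norm_offset"]),
                    scale=float(pg.attrs["norm_scale"]),
                ),
            ))
        return PairedDataset(pairs=pairs, split=split, fs=float(grp.attrs["fs"]),
                             normalization=str(grp.attrs["normalization"]))
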