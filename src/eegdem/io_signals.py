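"""Reading, writing and preprocessing of multichannel EEG recordings.

A :class:`Recording` holds the 19-channel scalp EEG in microvolts together
with its sampling rate. Preprocessing consists of trimming to the central
180 s window (samples ``[60*fs, 240*fs)``) and rational resampling to 256 Hz
with anti-alias filtering; both steps are deterministic and order-commuting.

Two on-disk formats are supported: plain CSV (one header row of channel
labels, one column per channel, values in microvolts — the sampling rate is
supplied by the caller) and European Data Format (EDF). EDF reading goes
through :mod:`mne`; a minimal 16-bit EDF writer is provided so recordings can
be exported and round-tripped without extra dependencies.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.signal import resample_poly

from .montage import MONTAGE_19, normalize_label

logger = logging.getLogger(__name__)

DEFAULT_FS = 256.0
TRIM_START_S = 60.0
TRIM_END_S = 240.0


class FormatError(ValueError):
    """Raised when a file parses but contains no usable montage channels."""


@dataclass
class Recording:
    """Multichannel EEG segment in microvolts.

    Parameters
    ----------
    channel_labels
        Canonical 10-20 electrode names, one per row of ``data``.
    fs
        Sampling rate in Hz, strictly positive.
    data
        Array of shape ``(n_channels, n_samples)``; potentials in microvolts.
    """

    channel_labels: list[str]
    fs: float
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaN samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_labels.index(label)]


def _select_montage(labels: list[str], data: np.ndarray) -> Recording | tuple:
    """Keep montage channels, canonical names, original row order preserved."""
    keep_idx: list[int] = []
    keep_labels: list[str] = []
    for i, raw in enumerate(labels):
        canon = normalize_label(raw)
        if canon is None:
            logger.warning("dropping non-montage channel %r", raw)
        elif canon in keep_labels:
            logger.warning("dropping duplicate montage channel %r", raw)
        else:
            keep_idx.append(i)
            keep_labels.append(canon)
    if not keep_labels:
        raise FormatError("no 10-20 montage channels found")
    return keep_labels, data[keep_idx]


def read_recording(path: str | Path, format: str | None = None,
                   fs: float | None = None) -> Recording:
    """Read an EEG recording from an EDF or CSV file.

    Channel labels are normalized to canonical 10-20 names; channels outside
    the montage are dropped with a warning. For CSV the sampling rate must be
    given via ``fs`` (the format does not carry it).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if format == "edf":
        return _read_edf(path)
    if format == "csv":
        if fs is None:
            raise ValueError("fs is required for CSV input")
        return _read_csv(path, fs)
    raise ValueError(f"unknown format {format!r}")


def _read_csv(path: Path, fs: float) -> Recording:
    with open(path) as fh:
        header = fh.readline().strip()
    if not header:
        raise IOError(f"empty file: {path}")
    labels = [c.strip() for c in header.split(",")]
    values = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if values.shape[1] != len(labels):
        raise IOError("header/column count mismatch")
    keep_labels, data = _select_montage(labels, values.T)
    return Recording(keep_labels, float(fs), data)


def _read_edf(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = list(raw.ch_names)
    data = raw.get_data(units="uV")
    keep_labels, data = _select_montage(labels, np.asarray(data))
    return Recording(keep_labels, float(raw.info["sfreq"]), data)


def write_csv(rec: Recording, path: str | Path) -> None:
    """Write a recording as headered CSV, one column per channel (microvolts)."""
    header = ",".join(rec.channel_labels)
    np.savetxt(path, rec.data.T, delimiter=",", header=header, comments="",
               fmt="%.6f")


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a plain (continuous, 16-bit) EDF file.

    Uses 1-second data records, so ``fs`` must be a positive integer. Each
    channel gets its own physical scaling covering its amplitude range;
    quantization error is bounded by range/2^16.
    """
    fs = rec.fs
    if fs != int(fs) or fs <= 0:
        raise ValueError("EDF export requires an integer sampling rate")
    spr = int(fs)  # samples per record per signal
    n_rec = rec.n_samples // spr
    if n_rec * spr != rec.n_samples:
        raise ValueError("EDF export requires a whole number of 1-s records")
    ns = rec.n_channels

    def f8(x: float) -> bytes:
        s = f"{x:.8g}"[:8]
        return s.ljust(8).encode("ascii")

    header = b"".join([
        b"0".ljust(8),
        b"X".ljust(80),            # patient id (anonymous)
        b"X".ljust(80),            # recording id
        b"01.01.00",               # start date
        b"00.00.00",               # start time
        str(256 * (1 + ns)).ljust(8).encode(),
        b" " * 44,
        str(n_rec).ljust(8).encode(),
        b"1".ljust(8),             # record duration in seconds
        str(ns).ljust(4).encode(),
    ])

    phys_min = rec.data.min(axis=1)
    phys_max = rec.data.max(axis=1)
    # widen degenerate / symmetric-free ranges so scaling is well defined
    pad = np.maximum((phys_max - phys_min) * 1e-3, 1e-6)
    phys_min = phys_min - pad
    phys_max = phys_max + pad
    dig_min, dig_max = -32768, 32767

    sig_fields = b"".join([
        b"".join(f"EEG {c}".ljust(16).encode() for c in rec.channel_labels),
        b" " * 80 * ns,                                 # transducer
        b"".join(b"uV".ljust(8) for _ in range(ns)),    # physical dimension
        b"".join(f8(v) for v in phys_min),
        b"".join(f8(v) for v in phys_max),
        b"".join(str(dig_min).ljust(8).encode() for _ in range(ns)),
        b"".join(str(dig_max).ljust(8).encode() for _ in range(ns)),
        b" " * 80 * ns,                                 # prefiltering
        b"".join(str(spr).ljust(8).encode() for _ in range(ns)),
        b" " * 32 * ns,
    ])

    # EDF stores physical values re-read as:
    #   phys = (dig - dig_min) / (dig_max - dig_min) * (pmax - pmin) + pmin
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.rint((rec.data - phys_min[:, None]) * scale[:, None]) + dig_min
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_fields)
        for r in range(n_rec):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())


def trim_central(rec: Recording, start_s: float = TRIM_START_S,
                 end_s: float = TRIM_END_S) -> Recording:
    """Extract the central window ``[start_s, end_s)`` of a recording.

    The default 60–240 s window discards the artifact-prone first and last
    minute of a 300 s session and yields exactly ``180 * fs`` samples.
    """
    if end_s <= start_s:
        raise ValueError("end_s must exceed start_s")
    i0 = int(round(start_s * rec.fs))
    i1 = int(round(end_s * rec.fs))
    if rec.n_samples < i1:
        raise ValueError(
            f"recording too short: {rec.duration_s:.1f} s < {end_s:.1f} s")
    return Recording(list(rec.channel_labels), rec.fs, rec.data[:, i0:i1].copy())


def resample_to(rec: Recording, target_fs: float = DEFAULT_FS) -> Recording:
    """Resample every channel to ``target_fs`` Hz.

    Uses polyphase rational resampling with a Kaiser-windowed anti-alias
    low-pass at the target Nyquist frequency. The 256 Hz → 256 Hz identity
    path returns the recording unchanged.
    """
    if target_fs <= 0 or rec.fs <= 0:
        raise ValueError("sampling rates must be positive")
    if target_fs == rec.fs:
        return rec
    ratio = Fraction(target_fs / rec.fs).limit_denominator(1000)
    data = resample_poly(rec.data, ratio.numerator, ratio.denominator, axis=1)
    return Recording(list(rec.channel_labels), float(target_fs), data)


def preprocess(rec: Recording, start_s: float = TRIM_START_S,
               end_s: float = TRIM_END_S,
               target_fs: float = DEFAULT_FS) -> Recording:
    """Standard preprocessing: central-window trim, then resample to 256 Hz."""
    return resample_to(trim_central(rec, start_s, end_s), target_fs)
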