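"""Fourier spectral features: DFT plus a 16-coefficient-per-electrode summary.

The discrete Fourier transform X[k] = sum_s x[s] exp(-2*pi*j*k*s/S) is
computed with an FFT but is contractually identical to the direct sum. To
reduce a 180 s spectrum to a fixed-size descriptor, each electrode's signal
is split into non-overlapping epochs; the per-epoch magnitude spectrum is
averaged inside ``m`` equal-width frequency bins spanning (0, f_max] Hz
(DC excluded) and the bins are averaged across epochs, yielding ``m``
coefficients per electrode. With the defaults (m=16, f_max=32 Hz, 2 Hz bins)
the bins tile the delta–beta range that carries the dementia-relevant
band-power changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_signals import Recording
from .matrix import FeatureMatrix, assemble_matrix  # noqa: F401  (re-export)

DEFAULT_M = 16
DEFAULT_F_MAX = 32.0
DEFAULT_N_EPOCHS = 4


@dataclass
class Spectrum:
    """Complex DFT of a real signal: values[k] for k = 0 .. S-1."""

    values: np.ndarray = field(repr=False)
    fs: float = 1.0

    @property
    def S(self) -> int:
        return self.values.size

    def frequencies(self) -> np.ndarray:
        return np.fft.fftfreq(self.S, d=1.0 / self.fs) % self.fs


def compute_dft(x: np.ndarray, fs: float = 1.0) -> Spectrum:
    """Full-length DFT of a real sequence (empty input is an error)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot transform an empty signal")
    return Spectrum(values=np.fft.fft(x), fs=fs)


def fourier_feature_names(channel_labels: list[str],
                          m: int = DEFAULT_M) -> list[str]:
    """Column names, electrode-major: ``<electrode>_c01 .. _c<m>``."""
    return [f"{ch}_c{k + 1:02d}" for ch in channel_labels for k in range(m)]


def _binned_magnitudes(x: np.ndarray, fs: float, m: int, f_max: float,
                       n_epochs: int) -> np.ndarray:
    n = x.size
    ep_len = n // n_epochs
    edges = np.linspace(0.0, f_max, m + 1)
    out = np.zeros(m)
    for e in range(n_epochs):
        seg = x[e * ep_len:(e + 1) * ep_len]
        mag = np.abs(np.fft.rfft(seg))
        freqs = np.fft.rfftfreq(seg.size, d=1.0 / fs)
        for b in range(m):
            # half-open on the left so DC (k = 0) is excluded from bin 1
            sel = (freqs > edges[b]) & (freqs <= edges[b + 1])
            out[b] += mag[sel].mean() if sel.any() else 0.0
    return out / n_epochs


def extract_fourier_features(rec: Recording, m: int = DEFAULT_M,
                             f_max: float = DEFAULT_F_MAX,
                             n_epochs: int = DEFAULT_N_EPOCHS) -> np.ndarray:
    """Per-recording Fourier feature vector of length ``E * m``.

    Electrodes are traversed in the recording's (canonical) channel order;
    within an electrode, coefficients are ordered by ascending frequency bin.
    """
    if f_max > rec.fs / 2:
        raise ValueError(f"f_max {f_max} Hz exceeds Nyquist {rec.fs / 2} Hz")
    if m < 1 or n_epochs < 1:
        raise ValueError("m and n_epochs must be positive")
    feats = [_binned_magnitudes(rec.data[ch], rec.fs, m, f_max, n_epochs)
             for ch in range(rec.n_channels)]
    return np.concatenate(feats)
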