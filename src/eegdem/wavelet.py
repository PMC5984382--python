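"""Wavelet processing: adaptive-threshold artifact attenuation and db4
sub-band features.

Artifact attenuation
--------------------
Each channel is decomposed with a sym3 discrete wavelet transform to depth 8.
For a sub-band coefficient sequence ``x`` the adaptive thresholds are

    thr_up(x)  = avg(x) + 1.5 * stdev(x)
    thr_dwn(x) = avg(x) - 1.5 * stdev(x)

and every sample outside [thr_dwn, thr_up] is *attenuated* (not zeroed) to
``s_i * (thr_up - thr_dwn) / 100``. The rule is applied to the band-limited
time-domain reconstructions of the level-5 and level-8 detail sub-bands
(4–8 Hz and 0.5–1 Hz at fs = 256 Hz): on the microvolt scale of scalp EEG
the factor (thr_up − thr_dwn)/100 = 3·sd/100 is well below one, so flagged
samples shrink. (Applied to raw orthonormal DWT coefficients, whose scale
grows as 2^(level/2), the same factor would exceed one and *amplify*
outliers — hence the time-domain form.) Because a pure oscillation of
amplitude A has a standard deviation of A/sqrt(2) (so 1.5 sd ≈ 1.06 A), a
steady rhythm stays below threshold while sparse high-amplitude transients
and beat excursions are crushed.

Feature extraction
------------------
The denoised channel is split into non-overlapping epochs; each epoch gets a
db4 decomposition to depth 5, whose dyadic sub-bands approximate the EEG
rhythms at 256 Hz: A5 → delta (0–4 Hz), D5 → theta (4–8 Hz), D4 → alpha
(8–16 Hz), D3 → beta (16–32 Hz). Per band, three statistics are computed on
the coefficients — mean, sample standard deviation, and power (mean squared
coefficient, an epoch-length-invariant PSD estimate) — giving
3 stats x 4 bands x 4 epochs = 48 features per electrode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .io_signals import Recording

DENOISE_WAVELET = "sym3"
DENOISE_LEVEL = 8
DENOISE_ATTENUATED_LEVELS = (5, 8)
FEATURE_WAVELET = "db4"
FEATURE_LEVEL = 5
DEFAULT_N_EPOCHS = 4
DWT_MODE = "symmetric"

#: db4/level-5 sub-band to rhythm-band assignment at fs = 256 Hz.
BAND_SUBBANDS = {"delta": "A5", "theta": "D5", "alpha": "D4", "beta": "D3"}
BAND_ORDER = ("delta", "theta", "alpha", "beta")
STAT_ORDER = ("mean", "std", "psd")


@dataclass
class ThresholdPair:
    """Upper/lower adaptive attenuation thresholds for one sub-band."""

    thr_up: float
    thr_dwn: float


@dataclass
class SubBandDecomposition:
    """DWT coefficient pyramid with its dyadic frequency-band mapping."""

    wavelet_name: str
    level: int
    detail_coeffs: list[np.ndarray] = field(repr=False)  # D1 .. Dlevel
    approx_coeffs: np.ndarray = field(repr=False)        # A_level
    fs: float = 256.0
    n_samples: int = 0

    @property
    def band_map(self) -> dict[str, tuple[float, float]]:
        """Frequency interval per sub-band: Di = [fs/2^(i+1), fs/2^i)."""
        out = {f"D{i}": (self.fs / 2 ** (i + 1), self.fs / 2 ** i)
               for i in range(1, self.level + 1)}
        out[f"A{self.level}"] = (0.0, self.fs / 2 ** (self.level + 1))
        return out

    def subband(self, name: str) -> np.ndarray:
        if name == f"A{self.level}":
            return self.approx_coeffs
        if name.startswith("D"):
            i = int(name[1:])
            if 1 <= i <= self.level:
                return self.detail_coeffs[i - 1]
        raise KeyError(name)

    def reconstruct(self) -> np.ndarray:
        coeffs = [self.approx_coeffs] + self.detail_coeffs[::-1]
        x = pywt.waverec(coeffs, self.wavelet_name, mode=DWT_MODE)
        return x[: self.n_samples]

    def detail_signal(self, lev: int) -> np.ndarray:
        """Time-domain band-limited reconstruction of one detail sub-band."""
        coeffs = [np.zeros_like(self.approx_coeffs)] + \
            [np.zeros_like(c) for c in self.detail_coeffs[::-1]]
        coeffs[self.level - lev + 1] = self.detail_coeffs[lev - 1]
        x = pywt.waverec(coeffs, self.wavelet_name, mode=DWT_MODE)
        return x[: self.n_samples]


def dwt_decompose(x: np.ndarray, wavelet_name: str,
                  level: int) -> SubBandDecomposition:
    """Multilevel DWT with symmetric boundary extension.

    The signal must be long enough for the requested depth with the chosen
    filter (``pywt.dwt_max_level``).
    """
    x = np.asarray(x, dtype=float)
    max_level = pywt.dwt_max_level(x.size, pywt.Wavelet(wavelet_name).dec_len)
    if level > max_level:
        raise ValueError(
            f"signal of {x.size} samples too short for level {level} "
            f"{wavelet_name} (max {max_level})")
    coeffs = pywt.wavedec(x, wavelet_name, mode=DWT_MODE, level=level)
    approx, details_desc = coeffs[0], coeffs[1:]  # D_level .. D_1
    return SubBandDecomposition(
        wavelet_name=wavelet_name, level=level,
        detail_coeffs=details_desc[::-1], approx_coeffs=approx,
        fs=256.0, n_samples=x.size)


def compute_thresholds(subband: np.ndarray) -> ThresholdPair:
    """Adaptive thresholds avg ± 1.5·stdev (sample sd, n−1 denominator)."""
    x = np.asarray(subband, dtype=float)
    if x.size == 0:
        raise ValueError("empty sub-band")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return ThresholdPair(thr_up=mean + 1.5 * sd, thr_dwn=mean - 1.5 * sd)


def attenuate_outliers(subband: np.ndarray, thr: ThresholdPair) -> np.ndarray:
    """Scale out-of-threshold coefficients by (thr_up − thr_dwn)/100."""
    x = np.asarray(subband, dtype=float)
    out = x.copy()
    mask = (x > thr.thr_up) | (x < thr.thr_dwn)
    out[mask] = x[mask] * (thr.thr_up - thr.thr_dwn) / 100.0
    return out


def denoise_channel(x: np.ndarray, fs: float = 256.0,
                    wavelet_name: str = DENOISE_WAVELET,
                    level: int = DENOISE_LEVEL,
                    attenuated_levels: tuple[int, ...] =
                    DENOISE_ATTENUATED_LEVELS) -> np.ndarray:
    """Attenuate transients in the level-5/level-8 detail sub-bands.

    Each targeted sub-band is reconstructed as a band-limited time-domain
    signal, its out-of-threshold samples are attenuated, and the channel is
    reassembled by swapping the attenuated sub-band for the original.
    """
    x = np.asarray(x, dtype=float)
    dec = dwt_decompose(x, wavelet_name, level)
    dec.fs = fs
    out = x.copy()
    for lev in attenuated_levels:
        d = dec.detail_signal(lev)
        thr = compute_thresholds(d)
        out += attenuate_outliers(d, thr) - d
    return out


def denoise_recording(rec: Recording) -> Recording:
    """Apply :func:`denoise_channel` to every channel of a recording."""
    data = np.vstack([denoise_channel(rec.data[ch], rec.fs)
                      for ch in range(rec.n_channels)])
    return Recording(list(rec.channel_labels), rec.fs, data)


def wavelet_feature_names(channel_labels: list[str],
                          n_epochs: int = DEFAULT_N_EPOCHS) -> list[str]:
    """Electrode-major names: ``<el>_e<epoch>_<band>_<stat>``."""
    return [f"{ch}_e{e + 1}_{band}_{stat}"
            for ch in channel_labels
            for e in range(n_epochs)
            for band in BAND_ORDER
            for stat in STAT_ORDER]


def _band_stats(epoch: np.ndarray) -> list[float]:
    dec = dwt_decompose(epoch, FEATURE_WAVELET, FEATURE_LEVEL)
    out: list[float] = []
    for band in BAND_ORDER:
        c = dec.subband(BAND_SUBBANDS[band])
        out.extend((float(np.mean(c)),
                    float(np.std(c, ddof=1)),
                    float(np.mean(c ** 2))))
    return out


def extract_wavelet_features(rec: Recording,
                             n_epochs: int = DEFAULT_N_EPOCHS,
                             denoise: bool = True) -> np.ndarray:
    """Per-recording wavelet feature vector of length ``E * 3 * 4 * n_epochs``.

    A trailing remainder that does not fill a whole epoch is dropped.
    """
    if n_epochs < 1:
        raise ValueError("n_epochs must be positive")
    ep_len = rec.n_samples // n_epochs
    if ep_len * n_epochs != rec.n_samples:
        import logging
        logging.getLogger(__name__).warning(
            "dropping %d trailing samples (not a whole epoch)",
            rec.n_samples - ep_len * n_epochs)
    feats: list[float] = []
    for ch in range(rec.n_channels):
        x = denoise_channel(rec.data[ch], rec.fs) if denoise else rec.data[ch]
        for e in range(n_epochs):
            feats.extend(_band_stats(x[e * ep_len:(e + 1) * ep_len]))
    return np.asarray(feats)
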