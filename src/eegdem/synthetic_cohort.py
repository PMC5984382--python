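"""Synthetic 19-channel EEG cohorts with class-dependent band-power structure.

The generator emulates the qualitative spectral signature of dementia EEG:
relative to healthy controls (HC), Alzheimer (AD) subjects show increased
delta/theta activity and decreased alpha/beta activity, with mild cognitive
impairment (MCI) intermediate. Each channel is a superposition of

* one narrow-band oscillation per canonical band (a small sum of random
  tones inside the band, amplitude scaled by the class- and band-specific
  gain),
* 1/f background noise (spectrally shaped white noise), and
* sparse high-amplitude triangular spike artifacts (Poisson-placed), which
  give the adaptive-threshold wavelet attenuation something to remove.

Everything is reproducible: a master seed plus the subject index determine
each recording bit-exactly.

The default class counts (49 AD / 37 MCI / 23 HC) mirror a typical clinical
cohort of this size; the effect sizes are free parameters of the generator,
not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io_signals import Recording
from .montage import MONTAGE_19

CLASSES = ("HC", "MCI", "AD")

#: Canonical EEG rhythm bands (Hz).
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

#: Baseline oscillation amplitude per band, microvolts (HC reference).
DEFAULT_BAND_AMPLITUDES: dict[str, float] = {
    "delta": 20.0,
    "theta": 15.0,
    "alpha": 35.0,
    "beta": 12.0,
}

#: Multiplicative per-class amplitude gain per band. HC is the reference
#: (all ones); AD gains encode the slowing of the rhythms, MCI sits between.
DEFAULT_CLASS_BAND_GAINS: dict[str, dict[str, float]] = {
    "HC": {"delta": 1.0, "theta": 1.0, "alpha": 1.0, "beta": 1.0},
    "MCI": {"delta": 1.2, "theta": 1.25, "alpha": 0.8, "beta": 0.85},
    "AD": {"delta": 1.4, "theta": 1.5, "alpha": 0.6, "beta": 0.7},
}


@dataclass
class SyntheticCohortConfig:
    """Parameters of the synthetic cohort generator.

    Attributes
    ----------
    n_ad, n_mci, n_hc
        Subject counts per class (defaults 49/37/23, total 109).
    duration_s, fs
        Recording length in seconds and sampling rate in Hz.
    band_defs
        Frequency interval per band name; intervals must not overlap and must
        lie below the Nyquist frequency.
    band_amplitudes
        HC-reference oscillation amplitude per band, microvolts.
    class_band_gains
        Per-class multiplicative gain per band; HC must be all ones.
    tones_per_band
        Number of random tones summed to build one band oscillation.
    noise_exponent, noise_scale
        1/f^exponent background noise shape and its RMS in microvolts.
    artifact_rate, artifact_amplitude
        Expected spike artifacts per minute per channel, and their peak
        amplitude in microvolts.
    subject_jitter
        Relative log-normal spread of each subject's band amplitudes,
        emulating inter-subject variability.
    seed
        Master seed; per-subject streams are derived from (seed, index).
    """

    n_ad: int = 49
    n_mci: int = 37
    n_hc: int = 23
    duration_s: float = 300.0
    fs: float = 256.0
    band_defs: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS))
    band_amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDES))
    class_band_gains: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: dict(g)
                                 for c, g in DEFAULT_CLASS_BAND_GAINS.items()})
    tones_per_band: int = 3
    noise_exponent: float = 1.0
    noise_scale: float = 12.0
    artifact_rate: float = 4.0
    artifact_amplitude: float = 120.0
    subject_jitter: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_ad, self.n_mci, self.n_hc) < 0:
            raise ValueError("subject counts must be non-negative")
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration and sampling rate must be positive")
        nyq = self.fs / 2
        intervals = sorted(self.band_defs.values())
        for (lo, hi) in intervals:
            if not (0 < lo < hi <= nyq):
                raise ValueError(f"band ({lo}, {hi}) outside (0, Nyquist]")
        for (_, hi), (lo2, _) in zip(intervals, intervals[1:]):
            if lo2 < hi:
                raise ValueError("band definitions overlap")
        hc = self.class_band_gains.get("HC", {})
        if any(hc.get(b) != 1.0 for b in self.band_defs):
            raise ValueError("HC gains must all equal 1 (reference class)")

    @property
    def n_total(self) -> int:
        return self.n_ad + self.n_mci + self.n_hc


def _one_over_f_noise(rng: np.random.Generator, n: int, fs: float,
                      exponent: float, scale: float) -> np.ndarray:
    """White noise spectrally shaped to a 1/f^exponent power spectrum."""
    if scale == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(freqs)
    nonzero = freqs > 0
    shape[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC offset
    shaped = np.fft.irfft(spec * shape, n=n)
    rms = np.sqrt(np.mean(shaped ** 2))
    return shaped * (scale / rms) if rms > 0 else shaped


def _spike_train(rng: np.random.Generator, n: int, fs: float,
                 rate_per_min: float, amplitude: float) -> np.ndarray:
    """Poisson-placed isolated triangular transients of 50–100 ms width."""
    out = np.zeros(n)
    if rate_per_min <= 0 or amplitude == 0:
        return out
    expected = rate_per_min * (n / fs) / 60.0
    count = rng.poisson(expected)
    for _ in range(count):
        width = int(rng.uniform(0.05, 0.10) * fs)
        center = rng.integers(width, max(width + 1, n - width))
        sign = rng.choice((-1.0, 1.0))
        half = width // 2
        ramp = np.linspace(0.0, 1.0, half, endpoint=False)
        pulse = np.concatenate([ramp, [1.0], ramp[::-1]])
        lo = center - half
        hi = lo + pulse.size
        if hi > n:
            pulse = pulse[: n - lo]
            hi = n
        out[lo:hi] += sign * amplitude * pulse
    return out


def generate_subject(label: str, config: SyntheticCohortConfig,
                     subject_seed: int) -> Recording:
    """Generate one 19-channel recording for a subject of the given class.

    The output is fully determined by ``(config.seed, subject_seed)``.
    """
    if label not in CLASSES:
        raise ValueError(f"unknown class label {label!r}")
    gains = config.class_band_gains[label]
    n = int(round(config.duration_s * config.fs))
    t = np.arange(n) / config.fs
    rng = np.random.default_rng([config.seed, int(subject_seed)])

    # per-subject amplitude jitter, shared across channels
    jitter = {
        band: float(np.exp(rng.normal(0.0, config.subject_jitter)))
        for band in config.band_defs
    }

    data = np.empty((len(MONTAGE_19), n))
    for ch in range(len(MONTAGE_19)):
        x = np.zeros(n)
        for band, (lo, hi) in config.band_defs.items():
            amp = config.band_amplitudes[band] * gains.get(band, 1.0)
            amp *= jitter[band]
            k = max(1, config.tones_per_band)
            freqs = rng.uniform(lo, hi, size=k)
            phases = rng.uniform(0.0, 2.0 * np.pi, size=k)
            x += (amp / k) * np.cos(
                2.0 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]
            ).sum(axis=0)
        x += _one_over_f_noise(rng, n, config.fs, config.noise_exponent,
                               config.noise_scale)
        x += _spike_train(rng, n, config.fs, config.artifact_rate,
                          config.artifact_amplitude)
        data[ch] = x
    return Recording(list(MONTAGE_19), config.fs, data)


def generate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[list[Recording], list[str]]:
    """Generate the full cohort: AD, then MCI, then HC subjects.

    Subject seeds are consecutive indices, so the cohort is reproducible and
    individual subjects can be regenerated in isolation.
    """
    labels = (["AD"] * config.n_ad + ["MCI"] * config.n_mci
              + ["HC"] * config.n_hc)
    recordings = [generate_subject(lab, config, idx)
                  for idx, lab in enumerate(labels)]
    return recordings, labels


def null_config(config: SyntheticCohortConfig) -> SyntheticCohortConfig:
    """Copy of ``config`` with every class gain set to 1 (no class signal)."""
    flat = {c: {b: 1.0 for b in config.band_defs} for c in CLASSES}
    return replace(config, class_band_gains=flat)
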