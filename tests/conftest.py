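import numpy as np
import pytest

from eegdem.montage import MONTAGE_19
from eegdem.io_signals import Recording
from eegdem.synthetic_cohort import SyntheticCohortConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Small, fast cohort config for unit tests (not the study defaults)."""
    return SyntheticCohortConfig(n_ad=3, n_mci=2, n_hc=2, duration_s=8.0,
                                 artifact_rate=2.0, seed=7)


def make_recording(n_channels=19, fs=256.0, duration_s=8.0, seed=0,
                   labels=None):
    """Random multichannel recording with canonical labels."""
    r = np.random.default_rng(seed)
    n = int(duration_s * fs)
    if labels is None:
        labels = list(MONTAGE_19[:n_channels])
    return Recording(labels, fs, r.standard_normal((len(labels), n)) * 10.0)


@pytest.fixture
def recording():
    return make_recording()
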