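"""Canonical 19-channel International 10-20 montage.

All feature vectors in this package are ordered by :data:`MONTAGE_19`, so the
column layout of a serialized feature matrix is stable across recordings
regardless of the channel order found in the source file.
"""

from __future__ import annotations

import re

#: Electrode names of the 19-channel 10-20 montage, in canonical order.
MONTAGE_19: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz",
    "C3", "C4", "Cz", "P3", "P4", "Pz",
    "T3", "T4", "T5", "T6", "O1", "O2",
)

_CANONICAL = {name.lower(): name for name in MONTAGE_19}

# "EEG Fp1-A1", "Fp1-REF", "eeg fp1" etc. -> "fp1"
_PREFIX = re.compile(r"^\s*eeg[\s_]*", re.IGNORECASE)
_SUFFIX = re.compile(r"[\s_-](a1|a2|ref|le|avg)\s*$", re.IGNORECASE)


def normalize_label(label: str) -> str | None:
    """Map a raw channel label to its canonical 10-20 name.

    Matching is case-insensitive; an ``EEG`` prefix and reference suffixes
    such as ``-A1`` or ``-REF`` are stripped. Returns ``None`` when the label
    does not belong to the 19-channel montage (e.g. ``ECG``, ``Photic``).
    """
    stripped = _SUFFIX.sub("", _PREFIX.sub("", label.strip()))
    return _CANONICAL.get(stripped.lower())
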