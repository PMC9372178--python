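"""Electrode montage: labels, roles, canonicalization, and neighbor graph.

The cap is a standard 10-20 layout completed by FC1/2/5/6, CP1/2/5/6 and Oz,
with ear electrodes A1/A2 used for referencing, bipolar vertical/horizontal
EOG channels and one EMG channel.
"""

from __future__ import annotations

EEG_1020 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
]
EEG_EXTRA = ["FC1", "FC2", "FC5", "FC6", "CP1", "CP2", "CP5", "CP6", "Oz"]
REFERENCE = ["A1", "A2"]
EOG = ["VEOG", "HEOG"]
EMG = ["EMG"]

ALL_LABELS = EEG_1020 + EEG_EXTRA + REFERENCE + EOG + EMG

#: Default reduced montage used by the session simulators; the analyses are
#: Fz-referenced-to-ears so a frontal-midline subset keeps simulation cheap.
DEFAULT_SIM_MONTAGE = ["Fz", "Cz", "Pz", "F3", "F4", "Oz", "A1", "A2",
                       "VEOG", "HEOG", "EMG"]

_CANONICAL = {lab.lower(): lab for lab in ALL_LABELS}


def canonical_label(label: str) -> str:
    """Case-insensitive canonical form of a channel label (``OZ`` -> ``Oz``).

    Raises ``KeyError`` for labels outside the montage.
    """
    key = label.strip().lower()
    if key not in _CANONICAL:
        raise KeyError(f"unknown channel label: {label!r}")
    return _CANONICAL[key]


def role_of(label: str) -> str:
    """Channel role: one of ``eeg``, ``reference``, ``eog``, ``emg``."""
    lab = canonical_label(label)
    if lab in REFERENCE:
        return "reference"
    if lab in EOG:
        return "eog"
    if lab in EMG:
        return "emg"
    return "eeg"


# Scalp adjacency used for bad-channel interpolation (mean of nearest
# neighbors). Hand-built from 10-20 geometry; only EEG channels appear.
NEIGHBORS = {
    "Fp1": ["Fp2", "F3", "F7"],
    "Fp2": ["Fp1", "F4", "F8"],
    "F7": ["Fp1", "F3", "T3", "FC5"],
    "F3": ["Fp1", "Fz", "F7", "C3", "FC1", "FC5"],
    "Fz": ["F3", "F4", "Cz", "FC1", "FC2"],
    "F4": ["Fp2", "Fz", "F8", "C4", "FC2", "FC6"],
    "F8": ["Fp2", "F4", "T4", "FC6"],
    "FC1": ["Fz", "F3", "Cz", "C3"],
    "FC2": ["Fz", "F4", "Cz", "C4"],
    "FC5": ["F7", "F3", "T3", "C3"],
    "FC6": ["F8", "F4", "T4", "C4"],
    "T3": ["F7", "C3", "T5", "FC5", "CP5"],
    "C3": ["F3", "Cz", "T3", "P3", "FC1", "FC5", "CP1", "CP5"],
    "Cz": ["Fz", "C3", "C4", "Pz", "FC1", "FC2", "CP1", "CP2"],
    "C4": ["F4", "Cz", "T4", "P4", "FC2", "FC6", "CP2", "CP6"],
    "T4": ["F8", "C4", "T6", "FC6", "CP6"],
    "CP1": ["Cz", "C3", "Pz", "P3"],
    "CP2": ["Cz", "C4", "Pz", "P4"],
    "CP5": ["T3", "C3", "T5", "P3"],
    "CP6": ["T4", "C4", "T6", "P4"],
    "T5": ["T3", "P3", "O1", "CP5"],
    "P3": ["C3", "Pz", "T5", "O1", "CP1", "CP5"],
    "Pz": ["Cz", "P3", "P4", "Oz", "CP1", "CP2"],
    "P4": ["C4", "Pz", "T6", "O2", "CP2", "CP6"],
    "T6": ["T4", "P4", "O2", "CP6"],
    "O1": ["T5", "P3", "Oz"],
    "Oz": ["O1", "O2", "Pz"],
    "O2": ["T6", "P4", "Oz"],
}
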