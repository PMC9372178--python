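"""Readers/writers and referencing for recordings, events, and biomarker
tables.

Formats: EDF (recordings), TSV sidecars (events, columns onset_sample /
onset_s / type / train_rate_hz), long-format CSV (biomarker records with
header subject_id,visit,parameter,electrode,value,qc_pass,qc_reason) and
JSON manifests carrying a content hash that is checked on load.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import edf
from .recording import Recording, StimulusEvent, StimulusSchedule

BIOMARKER_COLUMNS = ["subject_id", "visit", "parameter", "electrode",
                     "value", "qc_pass", "qc_reason"]


@dataclass(frozen=True)
class BiomarkerRecord:
    """One (subject, visit, parameter) biomarker value at one electrode."""

    subject_id: str
    visit: str
    parameter: str
    electrode: str
    value: float
    qc_pass: bool
    qc_reason: str = ""

    def __post_init__(self):
        if not self.qc_pass and not self.qc_reason:
            raise ValueError("qc_pass=False records must carry a reason")


def records_to_frame(records: list[BiomarkerRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records],
                        columns=BIOMARKER_COLUMNS)


def write_biomarkers(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, columns=BIOMARKER_COLUMNS)


def read_biomarkers(path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"subject_id": str, "visit": str})
    missing = [c for c in BIOMARKER_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"biomarker table lacks columns: {missing}")
    frame["qc_reason"] = frame["qc_reason"].fillna("")
    return frame


# ---------------------------------------------------------------- recordings

def write_recording(rec: Recording, path,
                    physical_range: float = edf.DEFAULT_PHYSICAL_RANGE):
    edf.write_edf(rec, path, physical_range=physical_range)


def read_recording(path, require: list[str] | None = None) -> Recording:
    """Load an EDF recording; optionally insist on required channels.

    ``require`` lists channel labels a downstream pipeline needs; the error
    names every missing label.
    """
    rec = edf.read_edf(path)
    if require:
        rec.require_channels(require)
    return rec


def rereference_to_ears(rec: Recording) -> Recording:
    """Re-reference every EEG channel to the mean of the ear electrodes.

    A1/A2 are retained unchanged for audit; EOG/EMG channels are untouched.
    """
    rec.require_channels(["A1", "A2"])
    out = rec.copy()
    ref = 0.5 * (rec.channel("A1") + rec.channel("A2"))
    for i, lab in enumerate(out.labels):
        if out.roles.get(lab) == "eeg":
            out.data[i] = out.data[i] - ref
    return out


def select_channel(rec: Recording, label: str) -> np.ndarray:
    """Case-folded single-channel view (``FZ`` matches ``Fz``)."""
    return rec.channel(label)


# -------------------------------------------------------------------- events

def write_events_tsv(schedule: StimulusSchedule, path) -> None:
    rows = []
    for e in schedule.events:
        rows.append({
            "onset_sample": e.onset_sample,
            "onset_s": e.onset_sample / schedule.fs,
            "type": e.type,
            "train_rate_hz": e.attrs.get("train_rate_hz", ""),
        })
    pd.DataFrame(rows, columns=["onset_sample", "onset_s", "type",
                                "train_rate_hz"]).to_csv(
        path, sep="\t", index=False)


def read_events_tsv(path, fs: float) -> StimulusSchedule:
    frame = pd.read_csv(path, sep="\t")
    events = []
    for _, row in frame.iterrows():
        attrs = {}
        rate = row.get("train_rate_hz", "")
        if pd.notna(rate) and rate != "":
            attrs["train_rate_hz"] = float(rate)
        events.append(StimulusEvent(int(row["onset_sample"]),
                                    str(row["type"]), attrs))
    return StimulusSchedule(events, fs)


# ----------------------------------------------------------------- manifests

def _payload_hash(payload: dict) -> str:
    canon = json.dumps(payload, sort_keys=True, default=float)
    return hashlib.sha256(canon.encode()).hexdigest()


def write_manifest(payload: dict, path) -> None:
    doc = {"payload": payload, "sha256": _payload_hash(payload)}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, default=float)


def read_manifest(path) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    if _payload_hash(doc["payload"]) != doc.get("sha256"):
        raise ValueError(f"manifest content hash mismatch: {os.fspath(path)}")
    return doc["payload"]
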