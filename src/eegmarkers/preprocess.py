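"""Filtering, eyeblink regression, epoching, baseline correction, epoch QC.

Filters are Butterworth second-order sections; zero-phase variants run
forward-backward (``sosfiltfilt``), which squares the magnitude response
and cancels phase. The notch is a narrow zero-phase band-stop (2 Hz wide)
with a true magnitude zero at its center frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from . import montage
from .recording import Recording, StimulusSchedule


@dataclass
class FilterSpec:
    kind: str                      # highpass | lowpass | notch
    cutoff_hz: float | None = None
    center_hz: float | None = None
    width_hz: float = 2.0          # notch only
    order: int = 4
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        if self.kind in ("highpass", "lowpass"):
            if self.cutoff_hz is None or not 0 < self.cutoff_hz < nyq:
                raise ValueError(
                    f"cutoff must lie in (0, {nyq}), got {self.cutoff_hz}")
        elif self.kind == "notch":
            if self.center_hz is None or not 0 < self.center_hz < nyq:
                raise ValueError("notch center must lie below Nyquist")
            if self.center_hz + self.width_hz / 2 >= nyq:
                raise ValueError("notch band exceeds Nyquist")
        else:
            raise ValueError(f"unknown filter kind {self.kind!r}")

    def sos(self, fs: float) -> np.ndarray:
        self.validate(fs)
        if self.kind == "notch":
            half = self.width_hz / 2.0
            return signal.butter(self.order,
                                 [self.center_hz - half,
                                  self.center_hz + half],
                                 btype="bandstop", fs=fs, output="sos")
        btype = "highpass" if self.kind == "highpass" else "lowpass"
        return signal.butter(self.order, self.cutoff_hz, btype=btype,
                             fs=fs, output="sos")


def filter_array(x: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    sos = spec.sos(fs)
    if spec.zero_phase:
        return signal.sosfiltfilt(sos, x, axis=-1)
    return signal.sosfilt(sos, x, axis=-1)


def apply_filter(rec: Recording, spec: FilterSpec) -> Recording:
    """Filter every channel of a recording (sample count preserved)."""
    out = rec.copy()
    out.data = filter_array(out.data, spec, rec.fs)
    return out


def remove_eyeblinks(rec: Recording,
                     eog_labels: tuple[str, ...] = ("VEOG", "HEOG"),
                     blink_threshold_uv: float = 75.0,
                     pad_s: float = 0.1,
                     ) -> tuple[Recording, dict]:
    """Regression-based blink removal.

    Blink intervals are flagged where the low-passed VEOG exceeds the
    threshold (conventional 75 uV), dilated by ``pad_s``. Each EEG channel
    is regressed (OLS) on the EOG channels over flagged samples only, and
    the fitted propagation is subtracted over the whole record. Flat EOG
    (zero variance) or no detected blinks degrade to a no-op with a status
    in the returned report.
    """
    rec.require_channels(list(eog_labels))
    fs = rec.fs
    eog = np.vstack([rec.channel(l) for l in eog_labels])
    report: dict = {"status": "ok", "coefficients": {}}

    if np.ptp(eog, axis=1).max() == 0.0:
        report["status"] = "flat_eog"
        return rec.copy(), report

    veog_lp = filter_array(rec.channel(eog_labels[0]),
                           FilterSpec("lowpass", cutoff_hz=10.0, order=4),
                           fs)
    mask = np.abs(veog_lp) > blink_threshold_uv
    if mask.any():
        pad = int(round(pad_s * fs))
        idx = np.flatnonzero(mask)
        grow = np.zeros_like(mask)
        for i in idx:
            grow[max(0, i - pad): i + pad + 1] = True
        mask = grow
    if mask.sum() < int(0.05 * fs):
        report["status"] = "no_blinks"
        return rec.copy(), report

    out = rec.copy()
    design = eog[:, mask].T                      # samples x n_eog
    design = design - design.mean(axis=0)
    for i, lab in enumerate(out.labels):
        if out.roles.get(lab) != "eeg":
            continue
        y = rec.data[rec.index_of(lab)][mask]
        beta, *_ = np.linalg.lstsq(design, y - y.mean(), rcond=None)
        out.data[i] = out.data[i] - beta @ eog
        report["coefficients"][lab] = {
            eog_labels[j]: float(beta[j]) for j in range(len(eog_labels))}
    report["n_blink_samples"] = int(mask.sum())
    return out, report


@dataclass
class EpochSet:
    """Time-locked segments (n_epochs x channels x time) with QC status."""

    data: np.ndarray
    fs: float
    window: tuple[float, float]            # (t_min, t_max), half-open
    channel_labels: list[str]
    conditions: np.ndarray                 # per-epoch label
    roles: dict[str, str] = field(default_factory=dict)
    qc: list[str] = field(default_factory=list)   # per kept epoch
    dropped: list[tuple[int, str]] = field(default_factory=list)
    n_events_total: int = 0

    def __post_init__(self):
        if not self.qc:
            self.qc = ["kept"] * self.data.shape[0]
        if not self.roles:
            self.roles = {l: montage.role_of(l) for l in self.channel_labels}

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.n_samples) / self.fs

    def channel_index(self, label: str) -> int:
        want = label.strip().lower()
        for i, lab in enumerate(self.channel_labels):
            if lab.lower() == want:
                return i
        raise KeyError(f"channel {label!r} not in epochs")

    def kept_mask(self) -> np.ndarray:
        return np.array([not q.startswith("rejected") for q in self.qc])

    def copy(self) -> "EpochSet":
        return replace(self, data=self.data.copy(),
                       conditions=self.conditions.copy(),
                       qc=list(self.qc), dropped=list(self.dropped))


def epoch(rec: Recording, schedule: StimulusSchedule,
          window: tuple[float, float] = (-0.1, 0.4)) -> EpochSet:
    """Cut half-open ``[t_min, t_max)`` epochs around each scheduled event.

    Events whose window would cross a record edge are dropped with reason
    ``edge``. Epoch length is ``round((t_max - t_min) * fs)`` samples.
    """
    t_min, t_max = window
    if t_max <= t_min:
        raise ValueError("window must be increasing")
    fs = rec.fs
    length = int(round((t_max - t_min) * fs))
    offset = int(round(t_min * fs))

    kept, conditions, dropped = [], [], []
    for i, ev in enumerate(schedule.events):
        start = ev.onset_sample + offset
        if start < 0 or start + length > rec.n_samples:
            dropped.append((i, "edge"))
            continue
        kept.append(rec.data[:, start: start + length])
        conditions.append(ev.type)
    data = (np.stack(kept) if kept
            else np.empty((0, rec.n_channels, length)))
    return EpochSet(data=data, fs=fs, window=window,
                    channel_labels=list(rec.labels),
                    conditions=np.array(conditions, dtype=object),
                    roles=dict(rec.roles), dropped=dropped,
                    n_events_total=len(schedule.events))


def baseline_correct(epochs: EpochSet,
                     interval: tuple[float, float] = (-0.1, 0.0)
                     ) -> EpochSet:
    """Subtract the per-epoch, per-channel mean over ``[a, b)``.

    The interval must lie inside the pre-stimulus part of the epoch window.
    """
    a, b = interval
    t_min, t_max = epochs.window
    if a < t_min - 1e-9 or b > t_max + 1e-9 or b <= a:
        raise ValueError("baseline interval outside epoch window")
    if a > 0:
        raise ValueError("baseline interval must be pre-stimulus")
    t = epochs.times()
    sel = (t >= a - 1e-12) & (t < b - 1e-12)
    if not sel.any():
        raise ValueError("baseline interval contains no samples")
    out = epochs.copy()
    out.data = out.data - out.data[:, :, sel].mean(axis=2, keepdims=True)
    return out


@dataclass
class RejectionCriteria:
    abs_threshold_uv: float = 100.0
    flat_threshold_uv: float = 0.5
    max_bad_channel_fraction: float = 0.2


def reject_and_interpolate(epochs: EpochSet,
                           criteria: RejectionCriteria | None = None,
                           neighbors: dict | None = None
                           ) -> tuple[EpochSet, dict]:
    """Mark bad channels per epoch; interpolate few, reject many.

    A channel within an epoch is bad if any sample exceeds the absolute
    threshold or its peak-to-peak lies below the flat threshold. If the
    bad fraction (over EEG channels) is within the allowance, bad channels
    are replaced by the mean of their clean montage neighbors; otherwise
    the whole epoch is rejected. Idempotent on its own output.
    """
    criteria = criteria or RejectionCriteria()
    neighbors = neighbors if neighbors is not None else montage.NEIGHBORS
    out = epochs.copy()
    eeg_idx = [i for i, l in enumerate(epochs.channel_labels)
               if epochs.roles.get(l) == "eeg"]
    report = {"n_events": epochs.n_events_total,
              "n_edge_dropped": sum(1 for _, r in epochs.dropped
                                    if r == "edge"),
              "n_kept": 0, "n_interpolated": 0,
              "n_rejected_by_reason": {}}

    def _reject(e: int, reason: str) -> None:
        out.qc[e] = f"rejected:{reason}"
        report["n_rejected_by_reason"][reason] = \
            report["n_rejected_by_reason"].get(reason, 0) + 1

    for e in range(epochs.n_epochs):
        if out.qc[e].startswith("rejected"):
            continue
        seg = out.data[e]
        bad = []
        for i in eeg_idx:
            if (np.abs(seg[i]).max() > criteria.abs_threshold_uv
                    or np.ptp(seg[i]) < criteria.flat_threshold_uv):
                bad.append(i)
        if not bad:
            report["n_kept"] += 1
            continue
        if len(bad) / len(eeg_idx) > criteria.max_bad_channel_fraction:
            _reject(e, "too_many_bad_channels")
            continue
        good = set(eeg_idx) - set(bad)
        fixed = []
        ok = True
        for i in bad:
            lab = epochs.channel_labels[i]
            neigh = [epochs.channel_index(nl) for nl in neighbors.get(lab, [])
                     if any(cl.lower() == nl.lower()
                            for cl in epochs.channel_labels)]
            neigh = [j for j in neigh if j in good]
            if not neigh:
                ok = False
                break
            out.data[e, i] = out.data[e][neigh].mean(axis=0)
            fixed.append(lab)
        if not ok:
            _reject(e, "uninterpolatable")
            continue
        out.qc[e] = "interpolated:" + ",".join(fixed)
        report["n_kept"] += 1
        report["n_interpolated"] += 1
    return out, report
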