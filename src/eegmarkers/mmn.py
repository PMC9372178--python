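"""Mismatch negativity extraction at Fz.

The deviant-minus-standard difference wave is searched for its most
negative sample in the 100-205 ms post-stimulus window. Quality gates: the
pre-stimulus baseline of the Fz difference wave must stay within +/-2 uV,
and the SNR -- RMS of the 400 ms post-stimulus segment over RMS of the
100 ms pre-stimulus segment -- must exceed 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import BiomarkerRecord
from .preprocess import (EpochSet, FilterSpec, RejectionCriteria,
                         baseline_correct, epoch, filter_array,
                         remove_eyeblinks, reject_and_interpolate)
from .recording import Recording, StimulusSchedule

DEVIANT_PARAMETERS = {"frequency": "mmn_amp_freq",
                      "duration": "mmn_amp_dur",
                      "frequency_duration": "mmn_amp_freqdur"}


@dataclass
class ERPWaveform:
    values: np.ndarray
    fs: float
    window: tuple[float, float]
    condition: str
    n_epochs_averaged: int

    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.values.size) / self.fs


@dataclass
class MMNQualityCriteria:
    baseline_band_uv: tuple[float, float] = (-2.0, 2.0)
    snr_min: float = 2.0
    post_window_s: tuple[float, float] = (0.0, 0.4)
    pre_window_s: tuple[float, float] = (-0.1, 0.0)


@dataclass
class MMNResult:
    deviant: str
    amplitude_uv: float
    latency_ms: float
    snr: float
    baseline_ok: bool
    qc_pass: bool
    reason: str = ""
    n_deviant_epochs: int = 0
    n_standard_epochs: int = 0


@dataclass
class MMNConfig:
    highpass_hz: float = 1.0
    lowpass_hz: float = 30.0
    filter_order: int = 4
    window_s: tuple[float, float] = (-0.1, 0.4)
    baseline_s: tuple[float, float] = (-0.1, 0.0)
    peak_window_ms: tuple[float, float] = (100.0, 205.0)
    electrode: str = "Fz"
    rejection: RejectionCriteria = field(default_factory=RejectionCriteria)
    criteria: MMNQualityCriteria = field(default_factory=MMNQualityCriteria)


def average_erp(epochs: EpochSet, condition: str,
                channel: str = "Fz") -> ERPWaveform | None:
    """Pointwise mean over kept epochs of one condition at one channel.

    Returns ``None`` when no kept epochs match (callers degrade to a
    QC-fail result rather than crashing).
    """
    ch = epochs.channel_index(channel)
    sel = epochs.kept_mask() & (epochs.conditions == condition)
    if not sel.any():
        return None
    return ERPWaveform(values=epochs.data[sel, ch].mean(axis=0),
                       fs=epochs.fs, window=epochs.window,
                       condition=condition,
                       n_epochs_averaged=int(sel.sum()))


def difference_wave(deviant: ERPWaveform,
                    standard: ERPWaveform) -> ERPWaveform:
    """Pointwise deviant minus standard; windows and rates must match."""
    if deviant.window != standard.window or deviant.fs != standard.fs:
        raise ValueError("waveform windows/sampling rates do not match")
    return ERPWaveform(values=deviant.values - standard.values,
                       fs=deviant.fs, window=deviant.window,
                       condition=f"{deviant.condition}-standard",
                       n_epochs_averaged=deviant.n_epochs_averaged)


def detect_mmn_peak(diff: ERPWaveform,
                    window_ms: tuple[float, float] = (100.0, 205.0)
                    ) -> tuple[float, float]:
    """Most negative sample in the closed window; earliest latency on ties.

    Returns (amplitude uV, latency ms). The windowed minimum may be
    positive; the definition does not force a negative value.
    """
    t_ms = diff.times() * 1000.0
    sel = (t_ms >= window_ms[0] - 1e-9) & (t_ms <= window_ms[1] + 1e-9)
    if sel.sum() < 2:
        raise ValueError("peak window contains fewer than 2 samples")
    vals = diff.values[sel]
    i = int(np.argmin(vals))           # argmin takes the earliest tie
    return float(vals[i]), float(t_ms[sel][i])


def erp_snr(diff: ERPWaveform,
            criteria: MMNQualityCriteria | None = None) -> float:
    """RMS(post-stimulus 400 ms) / RMS(pre-stimulus 100 ms).

    Zero pre-window RMS with nonzero post maps to +inf; the all-zero wave
    maps to 0 (a QC failure downstream).
    """
    criteria = criteria or MMNQualityCriteria()
    t = diff.times()

    def rms(lo: float, hi: float) -> float:
        sel = (t >= lo - 1e-12) & (t < hi - 1e-12)
        if not sel.any():
            raise ValueError("SNR window outside epoch")
        return float(np.sqrt(np.mean(diff.values[sel] ** 2)))

    post = rms(*criteria.post_window_s)
    pre = rms(*criteria.pre_window_s)
    if pre == 0.0:
        return float("inf") if post > 0 else 0.0
    return post / pre


def _baseline_ok(diff: ERPWaveform, criteria: MMNQualityCriteria) -> bool:
    t = diff.times()
    lo, hi = criteria.pre_window_s
    sel = (t >= lo - 1e-12) & (t < hi - 1e-12)
    seg = diff.values[sel]
    lo_uv, hi_uv = criteria.baseline_band_uv
    if seg.size == 0:
        return False
    return bool(((seg >= lo_uv) & (seg <= hi_uv)).all())


def evaluate_quality(diff: ERPWaveform,
                     criteria: MMNQualityCriteria | None = None
                     ) -> tuple[float, bool, bool, str]:
    """Apply both quality gates to a difference wave.

    Returns (snr, baseline_ok, qc_pass, reason). The SNR must strictly
    exceed ``snr_min`` (a ratio of exactly 2 fails); the pre-stimulus
    baseline must remain inside the band, boundary included.
    """
    criteria = criteria or MMNQualityCriteria()
    snr = erp_snr(diff, criteria)
    base_ok = _baseline_ok(diff, criteria)
    passed = base_ok and snr > criteria.snr_min
    reason = "" if passed else ("baseline" if not base_ok else "snr")
    return snr, base_ok, passed, reason


def run_mmn(rec: Recording, schedule: StimulusSchedule,
            config: MMNConfig | None = None
            ) -> tuple[list[MMNResult], dict]:
    """Full oddball pipeline at one electrode.

    Stage order: 1 Hz high-pass -> eyeblink regression -> epoching ->
    baseline correction -> epoch rejection/interpolation -> second
    baseline correction -> 30 Hz zero-phase low-pass -> per-deviant
    difference waves -> windowed peak + quality gates. Stage failures
    degrade to qc_pass=False results with a reason, never partial output.
    """
    config = config or MMNConfig()
    rec.require_channels([config.electrode])
    deviant_names = [t for t in dict.fromkeys(schedule.types())
                     if t != "standard"]
    if not deviant_names:
        raise ValueError("schedule contains no deviant events")

    filtered = rec.copy()
    filtered.data = filter_array(
        filtered.data, FilterSpec("highpass", cutoff_hz=config.highpass_hz,
                                  order=config.filter_order), rec.fs)
    if filtered.has_channel("VEOG"):
        filtered, blink_report = remove_eyeblinks(filtered)
    else:
        blink_report = {"status": "no_eog"}

    epochs = epoch(filtered, schedule, config.window_s)
    epochs = baseline_correct(epochs, config.baseline_s)
    epochs, qc_report = reject_and_interpolate(epochs, config.rejection)
    epochs = baseline_correct(epochs, config.baseline_s)  # second pass
    qc_report["blink_removal"] = blink_report

    lp = FilterSpec("lowpass", cutoff_hz=config.lowpass_hz,
                    order=config.filter_order)

    def _fail(name: str, reason: str, n_dev=0, n_std=0) -> MMNResult:
        return MMNResult(deviant=name, amplitude_uv=float("nan"),
                         latency_ms=float("nan"), snr=0.0,
                         baseline_ok=False, qc_pass=False, reason=reason,
                         n_deviant_epochs=n_dev, n_standard_epochs=n_std)

    standard = average_erp(epochs, "standard", config.electrode)
    results = []
    for name in deviant_names:
        dev = average_erp(epochs, name, config.electrode)
        if standard is None or dev is None:
            results.append(_fail(name, "no_epochs"))
            continue
        # low-pass the averages (filtering commutes with averaging)
        dev_f = ERPWaveform(filter_array(dev.values, lp, dev.fs), dev.fs,
                            dev.window, dev.condition, dev.n_epochs_averaged)
        std_f = ERPWaveform(filter_array(standard.values, lp, standard.fs),
                            standard.fs, standard.window, "standard",
                            standard.n_epochs_averaged)
        diff = difference_wave(dev_f, std_f)
        amp, lat = detect_mmn_peak(diff, config.peak_window_ms)
        snr, base_ok, passed, reason = evaluate_quality(diff,
                                                        config.criteria)
        results.append(MMNResult(
            deviant=name, amplitude_uv=amp, latency_ms=lat, snr=snr,
            baseline_ok=base_ok, qc_pass=passed, reason=reason,
            n_deviant_epochs=dev.n_epochs_averaged,
            n_standard_epochs=standard.n_epochs_averaged))
    return results, qc_report


def mmn_records(results: list[MMNResult], subject_id: str, visit: str,
                electrode: str = "Fz") -> list[BiomarkerRecord]:
    records = []
    for r in results:
        records.append(BiomarkerRecord(
            subject_id=subject_id, visit=visit,
            parameter=DEVIANT_PARAMETERS.get(r.deviant, f"mmn_{r.deviant}"),
            electrode=electrode, value=r.amplitude_uv,
            qc_pass=r.qc_pass, qc_reason=r.reason))
    return records
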