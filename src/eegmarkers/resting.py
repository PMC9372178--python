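"""Resting-state band power from 5-minute eyes-closed recordings.

Overlapping Hanning-windowed segments are averaged into a Parseval-
consistent power spectral density (Welch estimator: 4 s segments, 50%
overlap, 0.25 Hz resolution). Band powers integrate the density over
half-open [lo, hi) bands -- delta 1.5-6, theta 6-8.5, alpha 8.5-12.5,
beta 12.5-30, gamma 30-40 Hz -- so shared edges count once and the
delta..beta absolutes add up exactly to the 1.5-30 Hz total. Relative
power divides by that 1.5-30 Hz total (the study's printed definition),
so the relative gamma sits outside the 100% budget of delta..beta; a
full-spectrum denominator is available as a switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .io import BiomarkerRecord
from .recording import Recording

DEFAULT_BANDS = {"delta": (1.5, 6.0), "theta": (6.0, 8.5),
                 "alpha": (8.5, 12.5), "beta": (12.5, 30.0),
                 "gamma": (30.0, 40.0)}


@dataclass
class BandScheme:
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    relative_denominator_hz: tuple[float, float] = (1.5, 30.0)

    def validate(self) -> None:
        edges = sorted(self.bands.values())
        for (a0, a1), (b0, b1) in zip(edges, edges[1:]):
            if a1 > b0:
                raise ValueError("bands must not overlap")


@dataclass
class BandPowerResult:
    absolute_uv2: dict
    relative_pct: dict
    n_segments_used: int
    qc_pass: bool
    reason: str = ""


@dataclass
class SegmentCriteria:
    abs_threshold_uv: float = 100.0
    flat_threshold_uv: float = 0.5


def segment_resting(trace: np.ndarray, fs: float, seg_len_s: float = 4.0,
                    overlap_frac: float = 0.5,
                    criteria: SegmentCriteria | None = None
                    ) -> tuple[np.ndarray, dict]:
    """Overlapping segments of one channel with amplitude/flat rejection.

    Returns (n_segments x n_samples array of surviving segments, report).
    A 300 s record at 4 s / 50% yields floor((300-4)/2)+1 = 149 segments
    before rejection. A record shorter than one segment is an error.
    """
    criteria = criteria or SegmentCriteria()
    trace = np.asarray(trace, dtype=float)
    nper = int(round(seg_len_s * fs))
    if trace.size < nper:
        raise ValueError("recording shorter than one segment")
    step = int(round(nper * (1.0 - overlap_frac)))
    if step < 1:
        raise ValueError("overlap too large")
    starts = np.arange(0, trace.size - nper + 1, step)
    segs, dropped = [], 0
    for s in starts:
        seg = trace[s: s + nper]
        if (np.abs(seg).max() > criteria.abs_threshold_uv
                or np.ptp(seg) < criteria.flat_threshold_uv):
            dropped += 1
            continue
        segs.append(seg)
    report = {"n_segments": len(starts), "n_dropped": dropped,
              "n_used": len(segs)}
    data = np.stack(segs) if segs else np.empty((0, nper))
    return data, report


def power_spectrum(segments: np.ndarray, fs: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Averaged Hanning-windowed periodogram, uV^2/Hz.

    Window-power compensated so the integral of the density approximates
    the mean squared signal (Parseval consistency).
    """
    segments = np.atleast_2d(np.asarray(segments, dtype=float))
    if segments.shape[0] < 1:
        raise ValueError("need at least one segment")
    freqs, psd = _signal.periodogram(segments, fs=fs, window="hann",
                                     scaling="density", detrend=False,
                                     axis=-1)
    return freqs, psd.mean(axis=0)


def band_powers(freqs: np.ndarray, psd: np.ndarray,
                scheme: BandScheme | None = None,
                n_segments_used: int = 1,
                full_spectrum_denominator: bool = False
                ) -> BandPowerResult:
    """Integrate the density over half-open bands; relative in percent.

    ``full_spectrum_denominator=True`` switches the relative-power
    denominator from the 1.5-30 Hz total to the whole banded range.
    """
    scheme = scheme or BandScheme()
    scheme.validate()
    if freqs[-1] < max(hi for _, hi in scheme.bands.values()) - 1e-9:
        raise ValueError("spectrum does not cover the banded range")
    df = float(freqs[1] - freqs[0])

    def integral(lo: float, hi: float) -> float:
        sel = (freqs >= lo - 1e-9) & (freqs < hi - 1e-9)
        return float(psd[sel].sum() * df)

    absolute = {b: integral(lo, hi) for b, (lo, hi) in scheme.bands.items()}
    if full_spectrum_denominator:
        denom = sum(absolute.values())
    else:
        denom = integral(*scheme.relative_denominator_hz)
    if denom <= 0:
        return BandPowerResult(absolute_uv2=absolute,
                               relative_pct={b: float("nan")
                                             for b in absolute},
                               n_segments_used=n_segments_used,
                               qc_pass=False, reason="zero_denominator")
    relative = {b: 100.0 * v / denom for b, v in absolute.items()}
    return BandPowerResult(absolute_uv2=absolute, relative_pct=relative,
                           n_segments_used=n_segments_used, qc_pass=True)


def run_resting(rec: Recording, electrode: str = "Fz",
                seg_len_s: float = 4.0, overlap_frac: float = 0.5,
                scheme: BandScheme | None = None,
                criteria: SegmentCriteria | None = None) -> BandPowerResult:
    """Segment -> averaged spectrum -> band powers for one electrode."""
    rec.require_channels([electrode])
    segs, report = segment_resting(rec.channel(electrode), rec.fs,
                                   seg_len_s, overlap_frac, criteria)
    if segs.shape[0] == 0:
        empty = {b: float("nan") for b in (scheme or BandScheme()).bands}
        return BandPowerResult(absolute_uv2=empty, relative_pct=dict(empty),
                               n_segments_used=0, qc_pass=False,
                               reason="no_clean_segments")
    freqs, psd = power_spectrum(segs, rec.fs)
    return band_powers(freqs, psd, scheme,
                       n_segments_used=int(segs.shape[0]))


def resting_records(result: BandPowerResult, subject_id: str, visit: str,
                    electrode: str = "Fz",
                    bands: tuple[str, ...] = ("gamma",)
                    ) -> list[BiomarkerRecord]:
    out = []
    suffix = {"gamma": ("gamma_abs", "gamma_rel")}
    for band in bands:
        abs_name, rel_name = suffix.get(band,
                                        (f"{band}_abs", f"{band}_rel"))
        for name, value in ((abs_name, result.absolute_uv2.get(band)),
                            (rel_name, result.relative_pct.get(band))):
            out.append(BiomarkerRecord(
                subject_id=subject_id, visit=visit, parameter=name,
                electrode=electrode, value=float(value),
                qc_pass=result.qc_pass, qc_reason=result.reason))
    return out
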