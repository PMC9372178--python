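"""Stimulus schedule generation with exact proportions and seeded order.

Oddball sequences use exact-proportion allocation (round(p*n) of each type)
rather than i.i.d. draws, so the printed probabilities hold as exact counts
in every generated sequence, and no two deviants are ever adjacent. Click
trains are laid out on a fixed train-onset grid with the rate order drawn
pseudo-randomly per subject (the same order serves both visits).
"""

from __future__ import annotations

import numpy as np

from .designs import AssrDesign, OddballDesign
from .recording import StimulusEvent, StimulusSchedule


def generate_oddball_schedule(design: OddballDesign, n_stimuli: int,
                              seed: int, fs: float = 512.0
                              ) -> StimulusSchedule:
    """Seeded oddball sequence: exact counts, no two deviants adjacent.

    ``n_stimuli`` must be a multiple of 20 so that the 85/5/5/5 split is
    integral. Deviant positions are a uniform draw over all non-adjacent
    position sets (via the standard combinatorial bijection), deviant types
    a seeded shuffle of the exact type multiset. Onsets sit at k*SOA.
    """
    design.validate()
    if n_stimuli <= 0 or n_stimuli % 20 != 0:
        raise ValueError(
            f"n_stimuli must be a positive multiple of 20, got {n_stimuli}")
    n_std = round(design.p_standard * n_stimuli)
    n_each = round(design.p_deviant_each * n_stimuli)
    k = n_stimuli - n_std
    if k != n_each * len(design.deviants):
        raise ValueError("proportions do not produce integral counts")
    if k > (n_stimuli + 1) // 2:
        raise ValueError("no-adjacent-deviants constraint unsatisfiable")

    rng = np.random.default_rng(seed)
    # uniform non-adjacent k-subset of range(n): choose from n-k+1, spread
    base = np.sort(rng.choice(n_stimuli - k + 1, size=k, replace=False))
    positions = base + np.arange(k)

    types = np.array(["standard"] * n_stimuli, dtype=object)
    deviant_names = np.repeat([d.name for d in design.deviants], n_each)
    rng.shuffle(deviant_names)
    types[positions] = deviant_names

    soa_samples = int(round(design.soa_ms / 1000.0 * fs))
    by_name = {d.name: d for d in design.deviants}
    events = []
    for i, t in enumerate(types):
        if t == "standard":
            attrs = {"freq_hz": design.standard_freq,
                     "dur_ms": design.standard_dur_ms}
        else:
            dev = by_name[t]
            attrs = {"freq_hz": dev.freq_hz, "dur_ms": dev.dur_ms}
        events.append(StimulusEvent(i * soa_samples, str(t), attrs))
    return StimulusSchedule(events, fs)


def _allocate_evenly(total: int, bins: int) -> list[int]:
    base = total // bins
    counts = [base] * bins
    for i in range(total - base * bins):
        counts[i] += 1
    return counts


def generate_click_schedule(design: AssrDesign, seed: int,
                            fs: float = 512.0) -> StimulusSchedule:
    """Seeded click-train schedule over all tested rates.

    Emits one ``click`` event per click at k*separation within each train;
    the click with ``click_index`` 0 anchors the train onset. Rate order is
    a seeded permutation; seeding by subject (not visit) reproduces the
    within-patient order across baseline and end-of-treatment sessions.
    """
    design.validate()
    rng = np.random.default_rng(seed)
    rates = list(design.rates_tested)
    counts = _allocate_evenly(design.n_trains, len(rates))
    rate_seq = np.repeat(rates, counts).astype(float)
    rng.shuffle(rate_seq)

    tos_samples = int(round(design.train_onset_asynchrony_s * fs))
    events = []
    for j, rate in enumerate(rate_seq):
        onset = j * tos_samples
        sep_ms = 1000.0 / rate
        n_clicks = int(round(design.train_dur_ms / sep_ms))
        for c in range(n_clicks):
            click = onset + int(round(c * sep_ms / 1000.0 * fs))
            events.append(StimulusEvent(click, "click",
                                        {"train_rate_hz": float(rate),
                                         "train_index": j,
                                         "click_index": c}))
    return StimulusSchedule(events, fs)
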