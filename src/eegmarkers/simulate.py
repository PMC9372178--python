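"""Synthetic EEG session generators with stored ground truth.

Sessions are built from: a 1/f^alpha Gaussian background (spectral
shaping), a posterior-dominant 10 Hz alpha process, stimulus-locked
components (an N100-like deflection on every tone, a negative Gaussian
deviance response on deviants, a phase-jittered 40 Hz sinusoid per click
train), stereotyped biphasic eyeblink transients on VEOG propagated into
the scalp channels by known coefficients, and band-limited noise processes
for resting state. Every session stores its ground truth in
``Recording.meta['ground_truth']`` so downstream recovery is testable.

No acoustic waveform is synthesized; tone level and rise/fall times are
metadata only. Ear reference channels are simulated as quiet (zero signal)
so ear re-referencing is the identity on clean data.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize, special

from .designs import AssrDesign, SubjectProfile
from .montage import DEFAULT_SIM_MONTAGE
from .recording import Recording, StimulusSchedule

#: Relative scalp gain of the frontocentral generators per channel; Fz
#: carries the full component amplitude (the study's reporting electrode).
SCALP_GAIN = {"Fz": 1.0, "Cz": 0.8, "F3": 0.6, "F4": 0.6, "Pz": 0.4,
              "Oz": 0.2}
#: Known EOG->EEG blink propagation coefficients (frontal > posterior).
BLINK_COEFF = {"Fz": 0.30, "F3": 0.25, "F4": 0.25, "Cz": 0.15, "Pz": 0.08,
               "Oz": 0.03}

DEFAULT_RESTING_POWERS = {"delta": 8.0, "theta": 4.0, "alpha": 15.0,
                          "beta": 4.0}


def one_over_f_noise(n: int, fs: float, rms: float, alpha: float = 1.0,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Gaussian noise with a 1/f^alpha amplitude spectrum and target RMS."""
    if rms <= 0 or n == 0:
        return np.zeros(n)
    rng = rng or np.random.default_rng()
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = np.ones_like(f)
    nz = f > 0
    shaping[nz] = f[nz] ** (-alpha / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n)
    return x * (rms / np.std(x))


def band_limited_noise(n: int, fs: float, band: tuple[float, float],
                       power_uv2: float,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Gaussian noise confined to ``band`` with variance ``power_uv2``."""
    if power_uv2 <= 0 or n == 0:
        return np.zeros(n)
    rng = rng or np.random.default_rng()
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, 1.0 / fs)
    mask = (f >= band[0]) & (f < band[1])
    spec[~mask] = 0.0
    x = np.fft.irfft(spec, n)
    sd = np.std(x)
    if sd == 0:
        return np.zeros(n)
    return x * (math.sqrt(power_uv2) / sd)


def gaussian_pulse(t: np.ndarray, center_s: float, sigma_s: float,
                   amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t - center_s) / sigma_s) ** 2)


def deviance_pulse(t: np.ndarray, center_s: float, sigma_s: float,
                   amp: float, ratio: float = 2.5) -> np.ndarray:
    """Zero-integral deviance component with peak value ``amp`` at center.

    A Gaussian trough minus a broader, shallower Gaussian of equal area
    (width ratio 2.5), mimicking an AC-coupled difference wave: the main
    deflection is flanked by small opposite-sign lobes and the component
    carries no DC, so acquisition-style high-pass filtering leaves the
    peak essentially untouched.
    """
    u = (t - center_s) / sigma_s
    raw = np.exp(-0.5 * u * u) - (1.0 / ratio) * np.exp(
        -0.5 * (u / ratio) ** 2)
    return (amp / (1.0 - 1.0 / ratio)) * raw


def blink_waveform(fs: float, dur_s: float = 0.4,
                   amp_uv: float = 200.0) -> np.ndarray:
    """Stereotyped biphasic 400 ms blink transient (VEOG polarity)."""
    n = int(round(dur_s * fs))
    t = np.arange(n) / fs
    env = np.sin(np.pi * t / dur_s) ** 2
    return amp_uv * env * np.cos(2 * np.pi * t / dur_s - np.pi / 4)


def plf_to_kappa(plf: float) -> float:
    """Von Mises concentration giving mean resultant length ``plf``.

    Inverts R(kappa) = I1(kappa)/I0(kappa). plf=0 maps to kappa=0 (uniform
    phases); plf=1 is the degenerate zero-jitter limit handled by callers.
    """
    if not 0.0 <= plf < 1.0:
        raise ValueError("plf must lie in [0, 1)")
    if plf == 0.0:
        return 0.0

    def resultant(kappa: float) -> float:
        return special.i1e(kappa) / special.i0e(kappa)

    return optimize.brentq(lambda k: resultant(k) - plf, 1e-9, 1e4)


def _session_canvas(n: int, fs: float, channels: list[str],
                    profile: SubjectProfile, rng: np.random.Generator,
                    background_rms: float, alpha_rms: float,
                    one_over_f_alpha: float = 1.0):
    """Background + alpha + blinks shared by the ERP/ASSR simulators.

    Returns (data, blink mask info). Backgrounds are independent per EEG
    channel; the alpha process is posterior-weighted; blinks are drawn at
    Poisson times from the profile's blink rate and mixed into EEG
    channels by :data:`BLINK_COEFF`.
    """
    data = np.zeros((len(channels), n))
    veog = np.zeros(n)
    if profile.blink_rate_per_min > 0:
        wave = blink_waveform(fs)
        rate_hz = profile.blink_rate_per_min / 60.0
        t = 0.0
        while True:
            t += rng.exponential(1.0 / rate_hz)
            start = int(round(t * fs))
            if start + wave.size >= n:
                break
            veog[start: start + wave.size] += wave
    for i, lab in enumerate(channels):
        role_gain = SCALP_GAIN.get(lab, 0.5)
        low = lab.lower()
        if low in ("a1", "a2"):
            continue  # quiet reference electrodes
        if low == "veog":
            data[i] = veog + one_over_f_noise(n, fs, 0.1 * background_rms,
                                              one_over_f_alpha, rng)
        elif low == "heog":
            data[i] = one_over_f_noise(n, fs, 0.3 * background_rms,
                                       one_over_f_alpha, rng)
        elif low == "emg":
            if background_rms > 0:
                data[i] = rng.standard_normal(n) * background_rms
        else:
            if background_rms > 0:
                data[i] += one_over_f_noise(n, fs, background_rms,
                                            one_over_f_alpha, rng)
            if alpha_rms > 0:
                post = 1.5 if lab in ("Pz", "Oz", "O1", "O2") else 0.7
                data[i] += band_limited_noise(n, fs, (8.5, 12.5),
                                              (alpha_rms * post) ** 2, rng)
            data[i] += BLINK_COEFF.get(lab, 0.05) * veog
    return data, veog


def simulate_erp_session(schedule: StimulusSchedule, profile: SubjectProfile,
                         fs: float = 512.0,
                         channels: list[str] | None = None,
                         seed: int = 0,
                         background_rms: float = 10.0,
                         alpha_rms: float = 2.0,
                         n100_amp: float = -3.0,
                         mmn_latency_s: float = 0.150,
                         mmn_sigma_s: float = 0.025,
                         duration_s: float | None = None) -> Recording:
    """Oddball session: N100 on every tone, deviance response on deviants.

    The deviance response is a negative Gaussian at ``mmn_latency_s``
    post-onset with per-deviant amplitude from ``profile.true_mmn_amp``.
    With ``background_rms=0`` and ``blink_rate_per_min=0`` the deviant and
    standard averages differ exactly by that Gaussian.
    """
    if fs < 256:
        raise ValueError("fs must be at least 256 Hz")
    channels = list(channels or DEFAULT_SIM_MONTAGE)
    if not {"fz", "a1", "a2", "veog"} <= {c.lower() for c in channels}:
        raise ValueError("montage must include Fz, A1/A2 and VEOG")
    rng = np.random.default_rng(seed)

    tail_s = 1.0
    need = (schedule.end_sample + int(round(tail_s * fs))) / fs
    dur = duration_s if duration_s is not None else math.ceil(need)
    n = int(round(dur * fs))
    if schedule.end_sample + int(0.5 * fs) > n:
        raise ValueError("schedule extends past the configured length")

    data, _ = _session_canvas(n, fs, channels, profile, rng,
                              background_rms, alpha_rms)

    # stimulus-locked components on a pulse train, added per channel gain
    locked = np.zeros(n)
    span = int(round(0.45 * fs))
    t_local = np.arange(span) / fs
    n100 = gaussian_pulse(t_local, 0.100, 0.015, n100_amp)
    amp_by_type = dict(profile.true_mmn_amp)
    for ev in schedule.events:
        seg = slice(ev.onset_sample, ev.onset_sample + span)
        locked[seg] += n100[: locked[seg].size]
        if ev.type != "standard":
            amp = amp_by_type.get(ev.type, 0.0)
            if amp != 0.0:
                pulse = deviance_pulse(t_local, mmn_latency_s, mmn_sigma_s,
                                       amp)
                locked[seg] += pulse[: locked[seg].size]
    for i, lab in enumerate(channels):
        if lab.lower() in ("a1", "a2", "veog", "heog", "emg"):
            continue
        data[i] += SCALP_GAIN.get(lab, 0.5) * locked

    meta = {"subject_id": profile.subject_id, "paradigm": "oddball",
            "ground_truth": {"true_mmn_amp": dict(amp_by_type),
                             "mmn_latency_s": mmn_latency_s,
                             "blink_coeffs": dict(BLINK_COEFF),
                             "n100_amp": n100_amp}}
    return Recording(data=data, fs=fs, labels=channels, meta=meta)


def simulate_assr_session(schedule: StimulusSchedule,
                          profile: SubjectProfile,
                          fs: float = 512.0,
                          channels: list[str] | None = None,
                          seed: int = 0,
                          background_rms: float = 10.0,
                          alpha_rms: float = 2.0,
                          train_dur_s: float = 0.5,
                          onset_amp: float = -2.0) -> Recording:
    """Click-train session with von-Mises phase-jittered entrainment.

    Each train adds a sinusoid at its stimulation rate whose per-train
    phase offset is drawn von Mises with concentration chosen so the
    population phase-locking factor equals ``profile.true_plf`` (the mean
    resultant length mapping). ``true_plf == 1`` means zero jitter.
    """
    if fs < 256:
        raise ValueError("fs must be at least 256 Hz")
    channels = list(channels or DEFAULT_SIM_MONTAGE)
    rng = np.random.default_rng(seed)

    trains = schedule.trains_at_rate()
    if not len(trains):
        raise ValueError("schedule contains no trains")
    n = trains.end_sample + int(round(2.5 * fs))

    data, _ = _session_canvas(n, fs, channels, profile, rng,
                              background_rms, alpha_rms)

    if profile.true_plf >= 1.0:
        kappa = math.inf
    else:
        kappa = plf_to_kappa(profile.true_plf)

    span = int(round(train_dur_s * fs))
    t_local = np.arange(span) / fs
    ramp = np.minimum(1.0, np.minimum(t_local, train_dur_s - t_local) / 0.01)
    locked = np.zeros(n)
    for ev in trains.events:
        rate = ev.train_rate_hz
        phase = 0.0 if math.isinf(kappa) else rng.vonmises(0.0, kappa)
        tone = profile.true_entrained_amp * ramp * np.cos(
            2 * np.pi * rate * t_local + phase)
        tone += gaussian_pulse(t_local, 0.100, 0.015, onset_amp)
        seg = slice(ev.onset_sample, ev.onset_sample + span)
        locked[seg] += tone[: locked[seg].size]
    for i, lab in enumerate(channels):
        if lab.lower() in ("a1", "a2", "veog", "heog", "emg"):
            continue
        data[i] += SCALP_GAIN.get(lab, 0.5) * locked

    meta = {"subject_id": profile.subject_id, "paradigm": "assr",
            "ground_truth": {"true_plf": profile.true_plf,
                             "kappa": kappa,
                             "true_entrained_amp":
                                 profile.true_entrained_amp,
                             "blink_coeffs": dict(BLINK_COEFF)}}
    return Recording(data=data, fs=fs, labels=channels, meta=meta)


def simulate_resting_session(profile: SubjectProfile, fs: float = 512.0,
                             channels: list[str] | None = None,
                             duration_s: float = 300.0,
                             seed: int = 0,
                             band_powers: dict[str, float] | None = None
                             ) -> Recording:
    """Eyes-closed resting session as a sum of band-limited noise processes.

    Per-band variances (uV^2) default to an alpha-dominant eyes-closed
    profile plus the profile's gamma power; the exact configured powers are
    stored as ground truth.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    channels = list(channels or DEFAULT_SIM_MONTAGE)
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))

    powers = dict(DEFAULT_RESTING_POWERS)
    powers.update(profile.band_powers)
    if band_powers:
        powers.update(band_powers)
    powers.setdefault("gamma", profile.true_gamma_power)
    edges = {"delta": (1.5, 6.0), "theta": (6.0, 8.5), "alpha": (8.5, 12.5),
             "beta": (12.5, 30.0), "gamma": (30.0, 40.0)}

    data = np.zeros((len(channels), n))
    for i, lab in enumerate(channels):
        low = lab.lower()
        if low in ("a1", "a2"):
            continue
        if low in ("veog", "heog"):
            data[i] = one_over_f_noise(n, fs, 2.0, 1.0, rng)
            continue
        if low == "emg":
            data[i] = rng.standard_normal(n) * 2.0
            continue
        for band, (lo, hi) in edges.items():
            # keep one 0.25 Hz analysis bin clear of each edge so the
            # configured variance sits unambiguously inside the band
            guard = min(0.25, (hi - lo) / 8.0)
            data[i] += band_limited_noise(n, fs, (lo + guard, hi - guard),
                                          powers.get(band, 0.0), rng)

    meta = {"subject_id": profile.subject_id, "paradigm": "resting",
            "ground_truth": {"band_powers": {b: float(powers.get(b, 0.0))
                                             for b in edges}}}
    return Recording(data=data, fs=fs, labels=channels, meta=meta)
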