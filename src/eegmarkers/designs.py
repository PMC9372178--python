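"""Paradigm designs, subject ground-truth profiles, and clinical scores."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Deviant:
    name: str
    freq_hz: float
    dur_ms: float


@dataclass
class OddballDesign:
    """Auditory oddball: frequent standard tones with three rare deviants.

    The standard is a 1000 Hz, 50 ms tone at 85% probability; deviants
    (frequency 1500/50, duration 1000/100, frequency+duration 1500/100)
    occur at 5% each. Stimulus-onset asynchrony is 500 ms. Sound level and
    rise/fall times are metadata only (no acoustic synthesis).
    """

    standard_freq: float = 1000.0
    standard_dur_ms: float = 50.0
    deviants: tuple[Deviant, ...] = (
        Deviant("frequency", 1500.0, 50.0),
        Deviant("duration", 1000.0, 100.0),
        Deviant("frequency_duration", 1500.0, 100.0),
    )
    p_standard: float = 0.85
    p_deviant_each: float = 0.05
    soa_ms: float = 500.0
    rise_fall_ms: float = 5.0
    level_db: float = 80.0

    def validate(self) -> None:
        if abs(self.p_standard + len(self.deviants) * self.p_deviant_each
               - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")
        durations = [self.standard_dur_ms] + [d.dur_ms for d in self.deviants]
        if any(d <= 0 for d in durations):
            raise ValueError("stimulus durations must be positive")
        if self.soa_ms <= max(durations):
            raise ValueError("SOA must exceed the longest stimulus")


@dataclass
class AssrDesign:
    """Click-train steady-state paradigm.

    Each train lasts 500 ms and contains 20 clicks separated by 25 ms
    (40 Hz); 20 and 30 Hz rates are also presented. ``n_trains`` is the
    total across the tested rates, split as evenly as possible; train-rate
    order is pseudo-random per subject and reused across visits.
    """

    n_trains: int = 150
    train_dur_ms: float = 500.0
    clicks_per_train: int = 20
    click_separation_ms: float = 25.0
    rates_tested: tuple[float, ...] = (20.0, 30.0, 40.0)
    level_db: float = 80.0
    train_onset_asynchrony_s: float = 3.2

    def validate(self) -> None:
        if not self.rates_tested:
            raise ValueError("rates_tested must be non-empty")
        if abs(self.clicks_per_train * self.click_separation_ms
               - self.train_dur_ms) > 1e-9:
            raise ValueError(
                "clicks_per_train x click_separation must equal train_dur")
        if self.n_trains < 1:
            raise ValueError("need at least one train")

    def rate_for(self, rate: float) -> "AssrDesign":
        """Design restricted to a single stimulation rate."""
        d = AssrDesign(**{**self.__dict__})
        d.rates_tested = (rate,)
        d.click_separation_ms = 1000.0 / rate
        d.clicks_per_train = int(round(self.train_dur_ms
                                       / d.click_separation_ms))
        d.train_dur_ms = d.clicks_per_train * d.click_separation_ms
        return d


ARMS = ("placebo", "2mg", "5mg", "10mg", "25mg")


@dataclass
class SubjectProfile:
    """Ground-truth carrier for one simulated subject.

    ``true_mmn_amp`` maps deviant name -> microvolts (negative = intact
    response); ``true_plf`` is the population phase-locking factor in
    [0, 1]; ``treatment_effect`` is the additive shift applied to each
    parameter at end of treatment.
    """

    subject_id: str
    latent_severity: float = 0.0
    true_mmn_amp: dict[str, float] = field(default_factory=lambda: {
        "frequency": -2.0, "duration": -1.5, "frequency_duration": -3.0})
    true_plf: float = 0.4
    true_entrained_amp: float = 5.0
    true_gamma_power: float = 1.5
    band_powers: dict[str, float] = field(default_factory=dict)
    blink_rate_per_min: float = 10.0
    treatment_arm: str = "placebo"
    treatment_effect: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.true_plf <= 1.0):
            raise ValueError("true_plf must lie in [0, 1]")
        if self.blink_rate_per_min < 0:
            raise ValueError("blink rate must be non-negative")
        if self.treatment_arm not in ARMS:
            raise ValueError(f"unknown treatment arm {self.treatment_arm!r}")


MCCB_SCORES = ("mccb_overall", "mccb_neurocog", "lns", "wms_ss",
               "nab_mazes", "tmt_a")
PANSS_SCORES = ("panss_total", "panss_pos", "panss_neg", "panss_general")
CLINICAL_SCORES = MCCB_SCORES + PANSS_SCORES
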