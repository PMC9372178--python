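"""Cohort simulation: latent severity -> clinical scores and EEG ground
truth with planted rank correlations.

A single latent severity z ~ N(0,1) drives everything. Each clinical
score is a Gaussian-copula draw against z with a planted Spearman target
(the Pearson latent correlation is 2*sin(pi*rho_s/6), the exact
bivariate-normal inversion), then mapped to the instrument's marginal
(cognitive composites as T-scores around 30 with SD ~12, symptom totals
around 60 with SD 18, as observed in comparable patient cohorts).
Biomarker ground truth is monotone in z -- phase locking and entrained
amplitude fall, mismatch amplitude becomes less negative (shallower) as
severity rises -- so biomarker x score Spearman correlations approach the
planted severity x score targets as n grows. End-of-treatment values add
a per-arm effect (zero by default: the reference study found no treatment
response) plus test-retest noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .designs import (ARMS, CLINICAL_SCORES, MCCB_SCORES, PANSS_SCORES,
                      SubjectProfile)
from .io import BiomarkerRecord, records_to_frame

DEFAULT_ARM_RATIOS = {"2mg": 1, "5mg": 1, "10mg": 1, "25mg": 1, "placebo": 2}

#: Planted Spearman targets between latent severity and each score.
#: Severity worsens cognition (negative) and inflates symptoms (positive),
#: echoing the sign pattern of baseline biomarker-clinical correlations.
DEFAULT_CORR_TARGETS = {
    "mccb_overall": -0.45, "mccb_neurocog": -0.45, "lns": -0.30,
    "wms_ss": -0.30, "nab_mazes": -0.30, "tmt_a": -0.30,
    "panss_total": 0.40, "panss_pos": 0.30, "panss_neg": 0.30,
    "panss_general": 0.40,
}

#: Marginal (mean, SD) per score on its instrument scale.
SCORE_MARGINALS = {
    "mccb_overall": (30.3, 11.8), "mccb_neurocog": (31.5, 11.5),
    "lns": (35.0, 10.0), "wms_ss": (35.0, 10.0),
    "nab_mazes": (35.0, 10.0), "tmt_a": (35.0, 10.0),
    "panss_pos": (13.9, 5.9), "panss_neg": (16.4, 5.4),
    "panss_general": (29.8, 9.0),
}

#: Test-retest noise SD per biomarker parameter (units of the parameter);
#: chosen so paired-visit change scores have SDs on the scale reported
#: for repeat EEG sessions (~1.4 uV for MMN, ~0.07 for PLF, ~1.9 uV^2
#: for gamma power).
RETEST_SD = {"mmn_amp_freq": 0.95, "mmn_amp_dur": 1.0,
             "mmn_amp_freqdur": 1.2, "assr_plf": 0.05,
             "assr_entrained_amp": 0.15, "gamma_abs": 1.3}

TRUTH_PARAMETERS = ("mmn_amp_freq", "mmn_amp_dur", "mmn_amp_freqdur",
                    "assr_plf", "gamma_abs")


def allocate_arms(n_subjects: int, arm_ratios: dict | None = None
                  ) -> list[str]:
    """Exact largest-remainder allocation of subjects to arms (unshuffled).

    1:1:1:1:2 with n=120 gives 20/20/20/20/40.
    """
    ratios = arm_ratios or DEFAULT_ARM_RATIOS
    if any(v <= 0 for v in ratios.values()):
        raise ValueError("arm ratios must be positive")
    arms = [a for a in ARMS if a in ratios] + \
           [a for a in ratios if a not in ARMS]
    total = sum(ratios.values())
    quotas = {a: n_subjects * ratios[a] / total for a in arms}
    counts = {a: int(math.floor(quotas[a])) for a in arms}
    remainder = n_subjects - sum(counts.values())
    order = sorted(arms, key=lambda a: quotas[a] - counts[a], reverse=True)
    for a in order[:remainder]:
        counts[a] += 1
    out = []
    for a in arms:
        out.extend([a] * counts[a])
    return out


def spearman_to_pearson(rho_s: float) -> float:
    """Bivariate-normal latent correlation with Spearman ``rho_s``."""
    if not -1.0 < rho_s < 1.0:
        raise ValueError("rank-correlation targets must lie in (-1, 1)")
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def _biomarker_truth(z: np.ndarray, rng: np.random.Generator,
                     noise_scale: float) -> dict[str, np.ndarray]:
    """Ground-truth biomarkers, monotone in severity plus optional noise.

    ``noise_scale`` multiplies each parameter's cross-sectional noise SD;
    0 gives strictly monotone (noiseless-extraction) truth.
    """
    n = z.size

    def jitter(sd):
        return rng.standard_normal(n) * sd * noise_scale

    return {
        "mmn_amp_freq": -2.0 + 0.5 * z + jitter(0.4),
        "mmn_amp_dur": -1.5 + 0.35 * z + jitter(0.4),
        "mmn_amp_freqdur": -3.0 + 0.6 * z + jitter(0.5),
        "assr_plf": np.clip(0.40 - 0.10 * z + jitter(0.04), 0.02, 0.98),
        "assr_entrained_amp": np.clip(5.0 - 0.5 * z + jitter(0.3),
                                      1.0, None),
        "gamma_abs": np.exp(0.4 + 0.25 * z + jitter(0.2)),
    }


@dataclass
class Cohort:
    profiles: list[SubjectProfile]
    arms: dict                      # subject_id -> arm
    assessments: pd.DataFrame       # long over (subject, visit) x scores
    truth_baseline: pd.DataFrame    # biomarker long table (ground truth)
    truth_eot: pd.DataFrame
    latent: pd.DataFrame = field(default_factory=pd.DataFrame)


def simulate_cohort(n_subjects: int,
                    arm_ratios: dict | None = None,
                    effect_sizes: dict | None = None,
                    corr_targets: dict | None = None,
                    seed: int = 0,
                    biomarker_noise_scale: float = 1.0,
                    clinical_drift: dict | None = None) -> Cohort:
    """Simulate profiles, clinical tables, and ground-truth biomarkers.

    ``effect_sizes`` maps arm -> {parameter -> additive EoT shift}
    (default all zero). ``corr_targets`` maps score -> planted Spearman
    against latent severity. EEG recordings are rendered on demand with
    :func:`render_session`, not here, so large cohorts stay cheap.
    """
    rng = np.random.default_rng(seed)
    corr = dict(DEFAULT_CORR_TARGETS)
    if corr_targets:
        corr.update(corr_targets)
    effects = effect_sizes or {}

    arm_list = allocate_arms(n_subjects, arm_ratios)
    rng.shuffle(arm_list)
    subject_ids = [f"S{i+1:04d}" for i in range(n_subjects)]
    z = rng.standard_normal(n_subjects)

    # --- clinical scores via Gaussian copula against z ------------------
    def draw_score(name: str):
        r = spearman_to_pearson(corr.get(name, 0.0))
        latent = r * z + math.sqrt(1 - r * r) * rng.standard_normal(
            n_subjects)
        mean, sd = SCORE_MARGINALS[name]
        vals = mean + sd * latent
        return vals

    panss_range = {"panss_pos": (7, 49), "panss_neg": (7, 49),
                   "panss_general": (16, 112)}
    base_scores = {}
    for name in MCCB_SCORES:
        base_scores[name] = np.clip(draw_score(name), 0.0, 80.0)
    for name in ("panss_pos", "panss_neg", "panss_general"):
        lo, hi = panss_range[name]
        base_scores[name] = np.clip(np.rint(draw_score(name)), lo, hi)
    base_scores["panss_total"] = (base_scores["panss_pos"]
                                  + base_scores["panss_neg"]
                                  + base_scores["panss_general"])

    drift = {"mccb": 1.5, "panss": -2.0}
    if clinical_drift:
        drift.update(clinical_drift)
    eot_scores = {}
    for name in MCCB_SCORES:
        eot_scores[name] = np.clip(
            base_scores[name] + drift["mccb"]
            + rng.standard_normal(n_subjects) * 5.0, 0.0, 80.0)
    for name in ("panss_pos", "panss_neg", "panss_general"):
        lo, hi = panss_range[name]
        eot_scores[name] = np.clip(
            np.rint(base_scores[name] + drift["panss"] / 3.0
                    + rng.standard_normal(n_subjects) * 3.0),
            lo, hi)
    eot_scores["panss_total"] = (eot_scores["panss_pos"]
                                 + eot_scores["panss_neg"]
                                 + eot_scores["panss_general"])

    rows = []
    for visit, scores in (("baseline", base_scores), ("EoT", eot_scores)):
        for i, sid in enumerate(subject_ids):
            row = {"subject_id": sid, "visit": visit}
            row.update({k: float(scores[k][i]) for k in CLINICAL_SCORES})
            rows.append(row)
    assessments = pd.DataFrame(rows)

    # --- biomarker ground truth -----------------------------------------
    truth = _biomarker_truth(z, rng, biomarker_noise_scale)
    arms = dict(zip(subject_ids, arm_list))

    def truth_frame(visit: str) -> pd.DataFrame:
        recs = []
        for i, sid in enumerate(subject_ids):
            for param in TRUTH_PARAMETERS:
                val = float(truth[param][i])
                if visit == "EoT":
                    val += float(effects.get(arms[sid], {})
                                 .get(param, 0.0))
                    val += rng.standard_normal() * RETEST_SD[param]
                    if param == "assr_plf":
                        val = float(np.clip(val, 0.0, 1.0))
                recs.append(BiomarkerRecord(sid, visit, param, "Fz", val,
                                            True))
        return records_to_frame(recs)

    profiles = []
    for i, sid in enumerate(subject_ids):
        profiles.append(SubjectProfile(
            subject_id=sid, latent_severity=float(z[i]),
            true_mmn_amp={
                "frequency": float(truth["mmn_amp_freq"][i]),
                "duration": float(truth["mmn_amp_dur"][i]),
                "frequency_duration": float(truth["mmn_amp_freqdur"][i])},
            true_plf=float(truth["assr_plf"][i]),
            true_entrained_amp=float(truth["assr_entrained_amp"][i]),
            true_gamma_power=float(truth["gamma_abs"][i]),
            blink_rate_per_min=float(rng.uniform(4.0, 18.0)),
            treatment_arm=arms[sid],
            treatment_effect=dict(effects.get(arms[sid], {}))))

    latent = pd.DataFrame({"subject_id": subject_ids, "severity": z,
                           "arm": arm_list})
    return Cohort(profiles=profiles, arms=arms, assessments=assessments,
                  truth_baseline=truth_frame("baseline"),
                  truth_eot=truth_frame("EoT"), latent=latent)


def render_session(profile: SubjectProfile, paradigm: str, visit: str,
                   base_seed: int, fs: float = 512.0,
                   oddball_n_stimuli: int = 400,
                   assr_design=None, resting_duration_s: float = 300.0,
                   **sim_kwargs):
    """Render one subject-visit EEG session for a given paradigm.

    Returns (Recording, StimulusSchedule-or-None). Stimulus order for the
    click trains is keyed by the subject seed only, so baseline and EoT
    reuse the same pseudo-random rate order; the noise seed differs per
    visit. EoT ground truth adds the profile's treatment effect.
    """
    from . import schedules as _sched
    from . import simulate as _sim
    from .designs import AssrDesign, OddballDesign

    sseed = subject_seed(base_seed, profile.subject_id)
    vseed = subject_seed(base_seed, profile.subject_id,
                         salt=1 if visit == "EoT" else 0) + 1
    prof = profile
    if visit == "EoT" and profile.treatment_effect:
        import copy as _copy
        prof = _copy.deepcopy(profile)
        eff = profile.treatment_effect
        for key, dev in (("mmn_amp_freq", "frequency"),
                         ("mmn_amp_dur", "duration"),
                         ("mmn_amp_freqdur", "frequency_duration")):
            prof.true_mmn_amp[dev] += eff.get(key, 0.0)
        prof.true_plf = float(np.clip(prof.true_plf
                                      + eff.get("assr_plf", 0.0), 0.0, 1.0))
        prof.true_gamma_power = max(
            0.0, prof.true_gamma_power + eff.get("gamma_abs", 0.0))

    if paradigm == "oddball":
        sched = _sched.generate_oddball_schedule(
            OddballDesign(), oddball_n_stimuli, seed=vseed, fs=fs)
        rec = _sim.simulate_erp_session(sched, prof, fs=fs, seed=vseed,
                                        **sim_kwargs)
        return rec, sched
    if paradigm == "assr":
        sched = _sched.generate_click_schedule(
            assr_design or AssrDesign(), seed=sseed, fs=fs)
        rec = _sim.simulate_assr_session(sched, prof, fs=fs, seed=vseed,
                                         **sim_kwargs)
        return rec, sched
    if paradigm == "resting":
        rec = _sim.simulate_resting_session(
            prof, fs=fs, duration_s=resting_duration_s, seed=vseed,
            **sim_kwargs)
        return rec, None
    raise ValueError(f"unknown paradigm {paradigm!r}")


def subject_seed(base_seed: int, subject_id: str, salt: int = 0) -> int:
    """Stable per-subject seed below 2**31 derived from a cohort seed."""
    h = 0
    for ch in subject_id:
        h = (h * 131 + ord(ch)) % 2_147_483_647
    return (base_seed * 1_000_003 + h + salt * 7919) % 2_147_483_647
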