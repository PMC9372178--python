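#!/usr/bin/env python
"""Flagged Spearman correlation analyses of biomarkers vs clinical scores.

Three cross-sections mirror the biomarker questions:
  baseline    -- baseline EEG x baseline clinical (neurophysiological
                 marker of disease-related deficits),
  cfb         -- change-from-baseline EEG x change-from-baseline clinical
                 (treatment-response marker), in the combined 10+25 mg
                 group and in placebo separately,
  predictive  -- baseline EEG x change-from-baseline clinical.

Each pair gets tie-aware Spearman rho and a two-sided p; entries with
|rho| >= 0.3 and p < 0.05 are flagged. No multiplicity adjustment is
applied (hypothesis-generating analyses). Writes one CSV per mode under
results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from eegmarkers.cohort import simulate_cohort
from eegmarkers.designs import CLINICAL_SCORES
from eegmarkers.stats import (change_from_baseline, combine_groups,
                              correlation_matrix)

ROOT = Path(__file__).resolve().parents[1]


def clinical_cfb(assessments: pd.DataFrame) -> pd.DataFrame:
    base = assessments[assessments["visit"] == "baseline"].set_index(
        "subject_id")
    eot = assessments[assessments["visit"] == "EoT"].set_index(
        "subject_id")
    both = base.index.intersection(eot.index)
    out = (eot.loc[both, list(CLINICAL_SCORES)]
           - base.loc[both, list(CLINICAL_SCORES)])
    return out.reset_index()


def report(matrix: pd.DataFrame, label: str) -> None:
    flagged = matrix[matrix["flag"] != "none"]
    print(f"{label}: {len(matrix)} pairs, "
          f"{(matrix['flag'] == 'plus').sum()} '+' / "
          f"{(matrix['flag'] == 'minus').sum()} '-' flags")
    if len(flagged):
        print(flagged.to_string(index=False))


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-subjects", type=int, default=79)
    args = ap.parse_args()

    cohort = simulate_cohort(args.n_subjects, seed=args.seed)
    out = ROOT / "results"
    out.mkdir(exist_ok=True)

    clin_base = cohort.assessments[
        cohort.assessments["visit"] == "baseline"][
        ["subject_id", *CLINICAL_SCORES]]
    baseline_matrix = correlation_matrix(cohort.truth_baseline, clin_base)
    baseline_matrix.to_csv(out / "correlations_baseline.csv", index=False)
    report(baseline_matrix, "baseline x baseline (all subjects)")

    eeg_cfb, _ = change_from_baseline(cohort.truth_baseline,
                                      cohort.truth_eot)
    clin_cfb = clinical_cfb(cohort.assessments)
    merged_groups = combine_groups(cohort.arms, ("10mg", "25mg"))
    frames = []
    for group in ("10+25mg", "placebo"):
        members = [s for s, g in merged_groups.items() if g == group]
        m = correlation_matrix(
            eeg_cfb[eeg_cfb["subject_id"].isin(members)],
            clin_cfb[clin_cfb["subject_id"].isin(members)])
        m.insert(0, "group", group)
        frames.append(m)
        report(m, f"CfB x CfB ({group})")
    pd.concat(frames).to_csv(out / "correlations_cfb.csv", index=False)

    frames = []
    for group in ("10+25mg", "placebo"):
        members = [s for s, g in merged_groups.items() if g == group]
        m = correlation_matrix(
            cohort.truth_baseline[
                cohort.truth_baseline["subject_id"].isin(members)],
            clin_cfb[clin_cfb["subject_id"].isin(members)])
        m.insert(0, "group", group)
        frames.append(m)
        report(m, f"baseline EEG x CfB clinical ({group})")
    pd.concat(frames).to_csv(out / "correlations_predictive.csv",
                             index=False)


if __name__ == "__main__":
    main()
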