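#!/usr/bin/env python
"""Simulate the EEG substudy cohort.

Generates a 79-subject cohort randomized 1:1:1:1:2 across four active dose
arms and placebo, with a latent-severity structure linking clinical scores
(MCCB composites and subdomains, PANSS totals and subscales) to the EEG
ground truth (mismatch-response amplitudes, 40 Hz phase locking, resting
gamma power). Treatment effects are zero by default, matching the null
treatment-response picture the change-from-baseline tables summarize.

Writes under results/: the clinical table, ground-truth biomarker tables
for both visits, and the latent/arm assignment. Example raw EEG sessions
(EDF + events) for the first two subjects go to scratch/sessions/.
"""

import argparse
from pathlib import Path

from eegmarkers import io as eio
from eegmarkers.cohort import render_session, simulate_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-subjects", type=int, default=79)
    ap.add_argument("--render-examples", type=int, default=2,
                    help="how many subjects get raw EDF sessions rendered")
    args = ap.parse_args()

    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    cohort = simulate_cohort(args.n_subjects, seed=args.seed)

    cohort.assessments.to_csv(out / "clinical_scores.csv", index=False)
    eio.write_biomarkers(cohort.truth_baseline,
                         out / "biomarkers_truth_baseline.csv")
    eio.write_biomarkers(cohort.truth_eot, out / "biomarkers_truth_eot.csv")
    cohort.latent.to_csv(out / "cohort_assignment.csv", index=False)

    arms = cohort.latent["arm"].value_counts().to_dict()
    print(f"simulated {args.n_subjects} subjects, arms: {arms}")

    scratch = ROOT / "scratch" / "sessions"
    scratch.mkdir(parents=True, exist_ok=True)
    for prof in cohort.profiles[: args.render_examples]:
        for paradigm in ("oddball", "assr", "resting"):
            rec, sched = render_session(prof, paradigm, "baseline",
                                        base_seed=args.seed)
            rec.meta["visit"] = "baseline"
            stem = f"{prof.subject_id}_baseline_{paradigm}"
            eio.write_recording(rec, scratch / f"{stem}.edf")
            if sched is not None:
                eio.write_events_tsv(sched, scratch / f"{stem}_events.tsv")
            eio.write_manifest(rec.meta.get("ground_truth", {}),
                               scratch / f"{stem}_truth.json")
        print(f"rendered example sessions for {prof.subject_id} "
              f"(arm {prof.treatment_arm})")


if __name__ == "__main__":
    main()
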