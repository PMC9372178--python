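"""Change-from-baseline tables, group summaries, and flagged Spearman
correlation matrices.

Spearman's rho is the product-moment correlation of mid-ranks (tie-aware).
Two-sided p-values use the exact permutation distribution for n <= 10 and
the t approximation with n-2 degrees of freedom above that. Correlations
are flagged '+' when rho >= 0.3 with p < 0.05 and '-' when rho <= -0.3
with p < 0.05; no multiple-comparison adjustment is applied (the analyses
are hypothesis-generating). Report rounding is half-away-from-zero to two
decimals.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as _st

FLAG_RHO = 0.3
FLAG_P = 0.05


def round_half_away(x, decimals: int = 2):
    """Round half away from zero (the convention of printed summary
    tables), elementwise."""
    x = np.asarray(x, dtype=float)
    factor = 10.0 ** decimals
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return float(out) if out.ndim == 0 else out


def sem_from_sd(sd: float, n: int) -> float:
    return sd / math.sqrt(n)


@lru_cache(maxsize=None)
def _permutation_matrix(n: int) -> np.ndarray:
    """All permutations of range(n), built recursively (n! x n, int8)."""
    if n == 1:
        return np.zeros((1, 1), dtype=np.int8)
    prev = _permutation_matrix(n - 1)
    blocks = []
    col = np.full((prev.shape[0], 1), n - 1, dtype=np.int8)
    for pos in range(n):
        blocks.append(np.concatenate(
            [prev[:, :pos], col, prev[:, pos:]], axis=1))
    return np.concatenate(blocks, axis=0)


def spearman(x, y) -> tuple[float, float]:
    """Tie-aware Spearman rho with exact-permutation or t-based p.

    Pairs with a missing value in either input are deleted; at least 4
    complete pairs are required. Zero variance in either ranked variable
    is undefined and returns (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 complete pairs, got {n}")
    rx = _st.rankdata(x)
    ry = _st.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return float("nan"), float("nan")
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n <= 10:
        perms = _permutation_matrix(n)
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
        obs = abs(float(rxc @ ryc))
        count = 0
        chunk = 200_000
        for i in range(0, perms.shape[0], chunk):
            s = np.abs(ryc[perms[i: i + chunk]] @ rxc)
            count += int((s >= obs - 1e-9 * denom).sum())
        p = count / perms.shape[0]
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * _st.t.sf(abs(t), n - 2)
    return rho, float(min(p, 1.0))


def flag_for(rho: float, p: float) -> str:
    if np.isnan(rho) or np.isnan(p):
        return "none"
    if p < FLAG_P and rho >= FLAG_RHO:
        return "plus"
    if p < FLAG_P and rho <= -FLAG_RHO:
        return "minus"
    return "none"


def change_from_baseline(baseline: pd.DataFrame, eot: pd.DataFrame
                         ) -> tuple[pd.DataFrame, dict]:
    """Per-subject EoT minus baseline, restricted to QC-passing pairs.

    Inputs are long-format biomarker tables. Subjects missing either visit
    for a parameter, or failing QC at either visit, are excluded and
    counted in the report.
    """
    keys = ["subject_id", "parameter", "electrode"]
    b = baseline[baseline["qc_pass"].astype(bool)]
    e = eot[eot["qc_pass"].astype(bool)]
    merged = b.merge(e, on=keys, suffixes=("_baseline", "_eot"))
    merged["cfb"] = merged["value_eot"] - merged["value_baseline"]
    out = merged[keys + ["cfb"]].rename(columns={"cfb": "value"})

    all_pairs = baseline.merge(eot, on=keys, how="outer",
                               suffixes=("_baseline", "_eot"),
                               indicator=True)
    n_both = int((all_pairs["_merge"] == "both").sum())
    report = {"n_pairs": len(out),
              "n_missing_visit": len(all_pairs) - n_both,
              "n_qc_excluded": n_both - len(out),
              "n_excluded": len(all_pairs) - len(out)}
    return out, report


def summarize_group(values: pd.DataFrame, groups: pd.Series | dict,
                    rounded: bool = False) -> pd.DataFrame:
    """N / mean / SEM / SD / min / max per (group, parameter).

    ``groups`` maps subject_id -> group label. SD uses the n-1 denominator
    and SEM = SD/sqrt(n); both are missing for n = 1. ``rounded`` applies
    the 2-decimal half-away-from-zero report convention.
    """
    frame = values.copy()
    gmap = groups if isinstance(groups, dict) else groups.to_dict()
    frame["group"] = frame["subject_id"].map(gmap)
    frame = frame.dropna(subset=["group"])
    rows = []
    for (group, param), sub in frame.groupby(["group", "parameter"],
                                             sort=True):
        v = sub["value"].to_numpy(dtype=float)
        n = v.size
        sd = float(np.std(v, ddof=1)) if n > 1 else float("nan")
        rows.append({"group": group, "parameter": param, "n": n,
                     "mean": float(v.mean()),
                     "sem": sd / math.sqrt(n) if n > 1 else float("nan"),
                     "sd": sd, "min": float(v.min()),
                     "max": float(v.max())})
    out = pd.DataFrame(rows)
    if rounded and len(out):
        for col in ("mean", "sem", "sd", "min", "max"):
            out[col] = round_half_away(out[col].to_numpy())
    return out


def combine_groups(groups: pd.Series | dict, merge: tuple[str, ...],
                   label: str = "10+25mg") -> dict:
    """Relabel the listed groups with a pooled label.

    Rejects subjects appearing under more than one of the merged labels.
    """
    gmap = dict(groups if isinstance(groups, dict) else groups.to_dict())
    seen = [s for s, g in gmap.items() if g in merge]
    if len(seen) != len(set(seen)):
        raise ValueError("overlapping membership in merged groups")
    return {s: (label if g in merge else g) for s, g in gmap.items()}


def correlation_matrix(eeg: pd.DataFrame, clinical: pd.DataFrame,
                       min_pairs: int = 4) -> pd.DataFrame:
    """Flagged Spearman matrix over EEG-parameter x clinical-score pairs.

    ``eeg`` is long format (subject_id, parameter, value; qc_pass
    optional), ``clinical`` wide with a subject_id column and one column
    per score. Pairwise-complete deletion per pair; pairs with fewer than
    ``min_pairs`` cases are reported as missing, never dropped silently.
    """
    if "qc_pass" in eeg.columns:
        eeg = eeg[eeg["qc_pass"].astype(bool)]
    wide = eeg.pivot_table(index="subject_id", columns="parameter",
                           values="value", aggfunc="first")
    clin = clinical.set_index("subject_id")
    scores = [c for c in clin.columns if c != "visit"]
    joined = wide.join(clin[scores], how="inner")

    rows = []
    for param in wide.columns:
        for score in scores:
            x = joined[param].to_numpy(dtype=float)
            y = joined[score].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            n = int(ok.sum())
            if n < min_pairs:
                rows.append({"parameter": param, "score": score,
                             "rho": float("nan"), "p": float("nan"),
                             "n": n, "flag": "missing"})
                continue
            rho, p = spearman(x[ok], y[ok])
            rows.append({"parameter": param, "score": score, "rho": rho,
                         "p": p, "n": n, "flag": flag_for(rho, p)})
    return pd.DataFrame(rows, columns=["parameter", "score", "rho", "p",
                                       "n", "flag"])
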