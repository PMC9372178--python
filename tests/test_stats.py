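"""Spearman statistics, change-from-baseline, and group summaries."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegmarkers.io import BiomarkerRecord, records_to_frame
from eegmarkers.stats import (change_from_baseline, combine_groups,
                              correlation_matrix, flag_for,
                              round_half_away, sem_from_sd, spearman,
                              summarize_group)


def _brute_force_spearman(x, y):
    """Independent oracle: rank formula + full permutation enumeration."""
    n = len(x)
    rx = np.argsort(np.argsort(x)) + 1.0
    ry = np.argsort(np.argsort(y)) + 1.0

    def rho_of(r1, r2):
        d2 = np.sum((r1 - r2) ** 2)
        return 1.0 - 6.0 * d2 / (n * (n * n - 1))

    obs = rho_of(rx, ry)
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(rho_of(rx, np.array(perm))) >= abs(obs) - 1e-12:
            count += 1
    return obs, count / total


class TestSpearman:
    def test_perfect_and_reversed(self):
        rho, _ = spearman([1, 2, 3, 10], [1, 2, 3, 10])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_hand_formula_case(self):
        """Sum d^2 = 4, n = 4 -> rho = 1 - 24/60 = 0.6."""
        rho, _ = spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    @pytest.mark.parametrize("n", [5, 6, 7])
    def test_exact_permutation_p_matches_brute_force(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.permutation(n) * 1.0
        y = rng.permutation(n) * 1.0
        rho, p = spearman(x, y)
        orho, op = _brute_force_spearman(x, y)
        assert rho == pytest.approx(orho)
        assert p == pytest.approx(op)

    def test_t_approximation_large_n(self):
        from scipy import stats as st_
        rng = np.random.default_rng(4)
        x = rng.standard_normal(60)
        y = 0.5 * x + rng.standard_normal(60)
        rho, p = spearman(x, y)
        ref = st_.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_missing_values_pairwise_deleted(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 4.0, 6.0, 8.0, 10.0]
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="4"):
            spearman([1, 2, 3], [3, 2, 1])

    def test_zero_variance_undefined(self):
        rho, p = spearman([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])
        assert math.isnan(rho) and math.isnan(p)

    @settings(deadline=None, max_examples=20)
    @given(seed=st.integers(0, 9999))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(25)
        y = rng.standard_normal(25)
        rho1, p1 = spearman(x, y)
        rho2, p2 = spearman(np.exp(x), 3.0 * y + 7.0)
        assert rho1 == pytest.approx(rho2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestFlags:
    @pytest.mark.parametrize("rho,p,expected", [
        (0.35, 0.02, "plus"),
        (0.35, 0.20, "none"),
        (-0.31, 0.01, "minus"),
        (0.29, 0.001, "none"),
        (0.30, 0.049, "plus"),
        (-0.90, 0.06, "none"),
    ])
    def test_flag_rule(self, rho, p, expected):
        assert flag_for(rho, p) == expected


class TestChangeFromBaseline:
    def _table(self, visit, values, qc=None):
        recs = []
        qc = qc or {}
        for sid, v in values.items():
            ok = qc.get(sid, True)
            recs.append(BiomarkerRecord(sid, visit, "assr_plf", "Fz", v,
                                        ok, "" if ok else "snr"))
        return records_to_frame(recs)

    def test_simple_difference(self):
        cfb, report = change_from_baseline(
            self._table("baseline", {"S1": 5.0}),
            self._table("EoT", {"S1": 3.0}))
        assert cfb["value"].tolist() == [-2.0]
        assert report["n_excluded"] == 0

    def test_qc_fail_excluded_and_counted(self):
        cfb, report = change_from_baseline(
            self._table("baseline", {"S1": 5.0, "S2": 4.0},
                        qc={"S1": False}),
            self._table("EoT", {"S1": 3.0, "S2": 2.0}))
        assert cfb["subject_id"].tolist() == ["S2"]
        assert report["n_qc_excluded"] == 1

    def test_missing_visit_counted(self):
        cfb, report = change_from_baseline(
            self._table("baseline", {"S1": 5.0, "S2": 4.0}),
            self._table("EoT", {"S1": 3.0}))
        assert report["n_missing_visit"] == 1

    def test_identical_tables_zero(self):
        base = self._table("baseline", {"S1": 5.0, "S2": 1.5})
        eot = base.assign(visit="EoT")
        cfb, _ = change_from_baseline(base, eot)
        assert (cfb["value"] == 0.0).all()


class TestGroupSummary:
    def test_printed_sem_cells_reproduced(self):
        """SEM = SD/sqrt(N) at 2-decimal report rounding."""
        cases = [(1.38, 12, 0.40), (1.41, 47, 0.21),
                 (1.62, 12, 0.47), (1.33, 46, 0.20)]
        for sd, n, sem in cases:
            assert round_half_away(sem_from_sd(sd, n)) == pytest.approx(sem)

    def test_degenerate_identical_values(self):
        frame = pd.DataFrame({
            "subject_id": ["S1", "S2", "S3"],
            "parameter": ["assr_plf"] * 3,
            "electrode": ["Fz"] * 3,
            "value": [1.0, 1.0, 1.0]})
        out = summarize_group(frame, {f"S{i}": "placebo"
                                      for i in (1, 2, 3)})
        row = out.iloc[0]
        assert row["mean"] == 1.0 and row["sd"] == 0.0 and row["sem"] == 0.0
        assert row["min"] == row["max"] == 1.0

    def test_n1_missing_sd(self):
        frame = pd.DataFrame({"subject_id": ["S1"],
                              "parameter": ["assr_plf"],
                              "electrode": ["Fz"], "value": [0.4]})
        out = summarize_group(frame, {"S1": "placebo"})
        assert math.isnan(out.iloc[0]["sd"])
        assert math.isnan(out.iloc[0]["sem"])

    def test_sem_consistent_with_sd(self, rng):
        values = rng.normal(0, 1.5, 30)
        frame = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(30)],
            "parameter": ["gamma_abs"] * 30,
            "electrode": ["Fz"] * 30,
            "value": values})
        out = summarize_group(frame, {f"S{i}": "g" for i in range(30)})
        row = out.iloc[0]
        assert row["sem"] == pytest.approx(row["sd"] / math.sqrt(30))


class TestCombineGroups:
    def test_merge_counts(self):
        groups = {f"A{i}": "10mg" for i in range(20)}
        groups.update({f"B{i}": "25mg" for i in range(15)})
        merged = combine_groups(groups, ("10mg", "25mg"))
        assert sum(1 for g in merged.values() if g == "10+25mg") == 35

    def test_merge_empty_group_identity(self):
        groups = {"S1": "10mg"}
        merged = combine_groups(groups, ("10mg", "25mg"))
        assert merged == {"S1": "10+25mg"}

    def test_merged_summary_equals_pooled_raw(self, rng):
        values = rng.normal(0, 1, 12)
        frame = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(12)],
            "parameter": ["assr_plf"] * 12,
            "electrode": ["Fz"] * 12,
            "value": values})
        groups = {f"S{i}": ("10mg" if i < 7 else "25mg")
                  for i in range(12)}
        merged = combine_groups(groups, ("10mg", "25mg"))
        out = summarize_group(frame, merged)
        row = out[out["group"] == "10+25mg"].iloc[0]
        assert row["n"] == 12
        assert row["mean"] == pytest.approx(values.mean())
        assert row["sd"] == pytest.approx(np.std(values, ddof=1))


class TestCorrelationMatrix:
    def test_flags_and_missing(self, rng):
        n = 40
        sev = rng.standard_normal(n)
        eeg = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(n)],
            "parameter": ["assr_plf"] * n,
            "value": sev + rng.standard_normal(n) * 0.5,
            "qc_pass": [True] * n})
        clinical = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(n)],
            "mccb_overall": sev + rng.standard_normal(n) * 0.5,
            "sparse_score": [np.nan] * (n - 2) + [1.0, 2.0]})
        out = correlation_matrix(eeg, clinical)
        strong = out[out["score"] == "mccb_overall"].iloc[0]
        assert strong["flag"] == "plus"
        assert strong["n"] == n
        sparse = out[out["score"] == "sparse_score"].iloc[0]
        assert sparse["flag"] == "missing"
        assert math.isnan(sparse["rho"])

    def test_qc_failed_records_excluded(self, rng):
        n = 12
        eeg = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(n)],
            "parameter": ["gamma_abs"] * n,
            "value": rng.standard_normal(n),
            "qc_pass": [True] * 8 + [False] * 4})
        clinical = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(n)],
            "panss_total": rng.standard_normal(n)})
        out = correlation_matrix(eeg, clinical)
        assert out.iloc[0]["n"] == 8
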