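import itertools

import numpy as np
import pandas as pd
import pytest

from hsisas.errors import DegenerateInputError, HsisasError
from hsisas.stats import (
    improvement_deltas,
    median_iqr,
    paper_tables,
    spearman_rho,
    wilcoxon_signed_rank,
)


def wilcoxon_enumeration_oracle(pre, post, alternative="two-sided"):
    """Independent oracle: explicit 2^n enumeration of sign assignments."""
    diffs = np.asarray(post, float) - np.asarray(pre, float)
    d = diffs[diffs != 0]
    n = len(d)
    # average ranks of |d|, scalar implementation
    order = sorted(range(n), key=lambda i: abs(d[i]))
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while (j + 1 < n
               and abs(d[order[j + 1]]) == abs(d[order[i]])):
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    w_obs = sum(ranks[i] for i in range(n) if d[i] > 0)
    ge = le = 0
    total = 2 ** n
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        ge += w >= w_obs - 1e-9
        le += w <= w_obs + 1e-9
    p_ge, p_le = ge / total, le / total
    if alternative == "greater":
        return w_obs, p_ge
    if alternative == "less":
        return w_obs, p_le
    return w_obs, min(1.0, 2 * min(p_ge, p_le))


class TestMedianIQR:
    def test_singleton(self):
        assert median_iqr([3]) == (3, 3, 3)

    def test_odd_length_midpoint(self):
        med, q1, q3 = median_iqr([1, 2, 3, 4, 5])
        assert med == 3
        assert q1 == 2 and q3 == 4

    def test_matches_sort_interpolate_oracle(self, rng):
        values = rng.normal(size=100)
        med, q1, q3 = median_iqr(values)

        def oracle(p):
            v = sorted(values)
            pos = p * (len(v) - 1)
            lo = int(np.floor(pos))
            hi = int(np.ceil(pos))
            return v[lo] + (pos - lo) * (v[hi] - v[lo])

        assert med == pytest.approx(oracle(0.5), abs=1e-12)
        assert q1 == pytest.approx(oracle(0.25), abs=1e-12)
        assert q3 == pytest.approx(oracle(0.75), abs=1e-12)

    def test_empty_raises(self):
        with pytest.raises(DegenerateInputError):
            median_iqr([])


class TestWilcoxon:
    def test_worked_case_n5_all_positive(self):
        pre = [1.0, 2.0, 3.0, 4.0, 5.0]
        post = [2.0, 4.0, 6.0, 8.0, 10.0]
        res = wilcoxon_signed_rank(pre, post)
        assert res.statistic == 15.0
        assert res.p_value == pytest.approx(0.0625, abs=1e-12)
        assert res.method == "exact"

    def test_all_zero_differences_raise(self):
        with pytest.raises(DegenerateInputError):
            wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_matches_enumeration_oracle(self, rng, alternative):
        for _ in range(60):
            n = int(rng.integers(3, 13))
            pre = rng.normal(size=n)
            post = pre + rng.normal(0.2, 1.0, size=n)
            res = wilcoxon_signed_rank(pre, post, alternative=alternative)
            w_o, p_o = wilcoxon_enumeration_oracle(pre, post, alternative)
            assert res.statistic == pytest.approx(w_o)
            assert res.p_value == pytest.approx(p_o, abs=1e-12)

    def test_tied_differences_match_oracle(self, rng):
        for _ in range(40):
            n = int(rng.integers(4, 12))
            pre = rng.integers(0, 4, size=n).astype(float)
            post = rng.integers(0, 4, size=n).astype(float)
            if np.all(pre == post):
                continue
            res = wilcoxon_signed_rank(pre, post)
            w_o, p_o = wilcoxon_enumeration_oracle(pre, post)
            assert res.statistic == pytest.approx(w_o)
            assert res.p_value == pytest.approx(p_o, abs=1e-12)

    def test_zeros_dropped(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4], [1, 3, 5, 7])
        assert res.n_effective == 3

    def test_pratt_keeps_zero_ranks(self):
        res_w = wilcoxon_signed_rank([1, 2, 3, 4], [1, 3, 5, 7],
                                     zero_method="wilcox")
        res_p = wilcoxon_signed_rank([1, 2, 3, 4], [1, 3, 5, 7],
                                     zero_method="pratt")
        assert res_p.statistic > res_w.statistic

    def test_large_n_normal_approximation(self, rng):
        from scipy import stats as sps

        pre = rng.normal(size=60)
        post = pre + rng.normal(0.4, 1.0, size=60)
        res = wilcoxon_signed_rank(pre, post)
        assert res.method == "normal"
        ref = sps.wilcoxon(post, pre, correction=True, method="approx")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_greater_alternative_direction(self):
        pre = np.arange(10.0)
        post = pre + 1.0
        res = wilcoxon_signed_rank(pre, post, alternative="greater")
        assert res.p_value < wilcoxon_signed_rank(
            pre, post, alternative="less"
        ).p_value


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 12.0])
        y = np.exp(x)
        res = spearman_rho(x, y)
        assert res.rho == 1.0

    def test_perfect_antitone(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 12.0])
        res = spearman_rho(x, -np.sqrt(x))
        assert res.rho == -1.0

    def test_tied_data_matches_rank_oracle(self, rng):
        from scipy.stats import rankdata

        for _ in range(30):
            n = int(rng.integers(4, 20))
            x = rng.integers(0, 5, size=n).astype(float)
            y = rng.integers(0, 5, size=n).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            rx, ry = rankdata(x), rankdata(y)
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert spearman_rho(x, y).rho == pytest.approx(oracle, abs=1e-12)

    def test_symmetry(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        assert spearman_rho(x, y).rho == pytest.approx(
            spearman_rho(y, x).rho, abs=1e-15
        )

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        base = spearman_rho(x, y).rho
        assert spearman_rho(np.exp(x), y).rho == pytest.approx(base, abs=1e-12)
        assert spearman_rho(x, y ** 3).rho == pytest.approx(base, abs=1e-12)

    def test_p_value_against_scipy(self, rng):
        from scipy.stats import spearmanr

        x = rng.normal(size=22)
        y = 0.5 * x + rng.normal(size=22)
        res = spearman_rho(x, y)
        ref = spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_input_raises(self):
        with pytest.raises(DegenerateInputError):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_short_raises(self):
        with pytest.raises(HsisasError):
            spearman_rho([1, 2], [3, 4])


def _cohort_table(rng, m=6, effect=0.0, missing_das28=()):
    rows = []
    for i in range(m):
        sid = f"s{i:02d}"
        das_pre = rng.normal(4.8, 0.5)
        das_post = das_pre - effect - rng.normal(0, 0.2)
        for hand in ("L", "R"):
            base = {
                "roi_syn_area_px": rng.normal(14000, 3000),
                "pd_area_px": rng.normal(300, 100),
                "intra_hsisas": rng.normal(0.5, 0.1),
                "inter_hsisas": rng.normal(0.5, 0.1),
                "esr_mm_per_h": rng.normal(30, 8),
                "crp_mg_per_dl": rng.normal(1.5, 0.4),
            }
            for visit in ("pre", "post"):
                row = {"subject_id": sid, "hand": hand, "visit": visit}
                for var, v in base.items():
                    shift = effect if visit == "post" else 0.0
                    sign = 1 if var.endswith("hsisas") else -1
                    row[var] = v + sign * shift + rng.normal(0, 0.05)
                row["das28"] = das_pre if visit == "pre" else das_post
                if sid in missing_das28 and visit == "post":
                    row["das28"] = np.nan
                rows.append(row)
    return pd.DataFrame(rows)


class TestImprovementDeltas:
    def test_sign_conventions(self):
        table = pd.DataFrame([
            dict(subject_id="a", hand="L", visit="pre", das28=4.8,
                 intra_hsisas=0.2, inter_hsisas=0.5),
            dict(subject_id="a", hand="L", visit="post", das28=4.3,
                 intra_hsisas=0.9, inter_hsisas=0.5),
        ])
        deltas = improvement_deltas(table)
        assert deltas.loc[0, "d_das28"] == pytest.approx(0.5)
        assert deltas.loc[0, "d_intra_hsisas"] == pytest.approx(0.7)
        assert deltas.loc[0, "d_inter_hsisas"] == pytest.approx(0.0)

    def test_uniform_improvement_gives_positive_deltas(self, rng):
        table = _cohort_table(rng, effect=1.0)
        deltas = improvement_deltas(table)
        for col in deltas.columns:
            if col.startswith("d_"):
                assert (deltas[col].dropna() > 0).all(), col

    def test_das28_patient_level_assignment(self, rng):
        table = _cohort_table(rng, m=4)
        deltas = improvement_deltas(table)
        for sid, group in deltas.groupby("subject_id"):
            assert group["d_das28"].nunique() <= 1

    def test_missing_das28_excluded_only_from_das28(self, rng):
        table = _cohort_table(rng, m=4, missing_das28=("s01",))
        deltas = improvement_deltas(table)
        s01 = deltas[deltas.subject_id == "s01"]
        assert s01["d_das28"].isna().all()
        assert s01["d_intra_hsisas"].notna().all()

    def test_missing_visit_gives_nan(self, rng):
        table = _cohort_table(rng, m=3)
        table = table[~((table.subject_id == "s00") & (table.hand == "L")
                        & (table.visit == "post"))]
        deltas = improvement_deltas(table)
        row = deltas[(deltas.subject_id == "s00") & (deltas.hand == "L")]
        assert row["d_intra_hsisas"].isna().all()


class TestPaperTables:
    def test_report_structure(self, rng):
        report = paper_tables(_cohort_table(rng, m=6))
        summary = report["summary"]
        assert set(summary["variable"]) == {
            "roi_syn_area_px", "pd_area_px", "intra_hsisas", "inter_hsisas",
            "das28", "esr_mm_per_h", "crp_mg_per_dl",
        }
        das_n = summary.loc[summary.variable == "das28", "n"].iloc[0]
        wrist_n = summary.loc[summary.variable == "intra_hsisas", "n"].iloc[0]
        assert das_n == 6 and wrist_n == 12
        assert report["spearman"].shape[0] == report["spearman"].shape[1]

    def test_strong_effect_flags_only_affected_variable(self, rng):
        table = _cohort_table(rng, m=8, effect=0.0)
        wide = table.pivot_table(index=["subject_id", "hand"],
                                 columns="visit", values="intra_hsisas")
        # inject a strong, consistent effect on intra only
        table.loc[table.visit == "post", "intra_hsisas"] += 5.0
        report = paper_tables(table)
        summary = report["summary"].set_index("variable")
        assert summary.loc["intra_hsisas", "p_value"] < 0.05
        assert summary.loc["pd_area_px", "p_value"] > 0.05

    def test_type_one_error_near_nominal(self, rng):
        """Null Wilcoxon report: per-variable flag rate within [0.01, 0.10]."""
        flags = 0
        n_rep = 500
        for _ in range(n_rep):
            pre = rng.normal(size=22)
            post = pre + rng.normal(0, 1, size=22)
            res = wilcoxon_signed_rank(pre, post)
            flags += res.p_value < 0.05
        assert 0.01 <= flags / n_rep <= 0.10

    def test_duplicated_wrist_semantics(self, rng):
        table = _cohort_table(rng, m=6, effect=0.3)
        single = table[table.hand == "L"].copy()
        duplicated = pd.concat([
            single, single.assign(hand="R")
        ], ignore_index=True)
        rep_s = paper_tables(single)["summary"].set_index("variable")
        rep_d = paper_tables(duplicated)["summary"].set_index("variable")
        for var in ("intra_hsisas", "esr_mm_per_h"):
            assert rep_d.loc[var, "pre_median"] == pytest.approx(
                rep_s.loc[var, "pre_median"])
            assert rep_d.loc[var, "n"] == 2 * rep_s.loc[var, "n"]

    def test_starred_formatting(self, rng):
        table = _cohort_table(rng, m=8, effect=0.5)
        report = paper_tables(table)
        starred = report["spearman_starred"]
        p = report["spearman_p"]
        for i in starred.index:
            for j in starred.columns:
                cell = starred.loc[i, j]
                if cell == "":
                    continue
                if p.loc[i, j] < 0.01:
                    assert cell.endswith("**")
                elif p.loc[i, j] < 0.05:
                    assert cell.endswith("*") and not cell.endswith("**")

    def test_few_pairs_variable_skipped(self, rng):
        table = _cohort_table(rng, m=3)
        table.loc[(table.subject_id != "s00") & (table.visit == "post"),
                  "das28"] = np.nan
        report = paper_tables(table)
        # das28 has only 1 complete patient pair -> skipped with a note
        assert "das28" not in set(report["summary"].get("variable", []))
        assert any("das28" in n for n in report["notes"])
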