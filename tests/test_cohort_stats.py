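"""Cohort summaries and the group-comparison test battery."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mitofiber import (
    cohort_fixture,
    compare_independent,
    compare_paired,
    label_significance,
    sidak_adjust,
    summarize,
    two_way_anova_sidak,
)


class TestSummarize:
    def test_missing_values_excluded(self):
        t = cohort_fixture()
        mean, sd, n = summarize(t, "ncam_pos_pct", group="unaffected")
        assert n == 7
        assert mean == pytest.approx(0.804, abs=1e-3)

    def test_single_value_has_undefined_sd(self):
        t = pd.DataFrame({"x": [3.0, np.nan]})
        mean, sd, n = summarize(t, "x")
        assert (mean, n) == (3.0, 1)
        assert np.isnan(sd)

    def test_all_missing_rejected(self):
        t = cohort_fixture()
        with pytest.raises(ValueError, match="non-missing"):
            summarize(t, "ctg_repeats", group="unaffected")


def rank_sum_exact_p(a, b):
    """Enumeration oracle: exact two-sided Mann-Whitney p over all splits."""
    pooled = sorted(a + b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1 = len(a)

    def u_stat(group):
        r = sum(ranks[v] for v in group)
        return r - n1 * (n1 + 1) / 2

    u_obs = u_stat(a)
    n = len(pooled)
    us = [u_stat(list(c)) for c in itertools.combinations(pooled, n1)]
    mean_u = n1 * (n - n1) / 2
    extreme = sum(abs(u - mean_u) >= abs(u_obs - mean_u) for u in us)
    return extreme / len(us)


class TestCompareIndependent:
    def test_identical_groups_not_significant(self):
        res = compare_independent([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p_value > 0.5

    def test_fully_separated_small_groups_match_enumeration(self):
        a, b = [1, 2, 3], [10, 11, 12]
        res = compare_independent(a, b)
        assert res.statistic == 0.0
        assert res.method == "mann-whitney-exact"
        assert res.p_value == pytest.approx(rank_sum_exact_p(a, b))

    def test_random_small_samples_match_enumeration(self, rng):
        for _ in range(5):
            a = list(rng.permutation(np.arange(1.0, 13.0))[:5])
            b = list(rng.permutation(np.arange(13.0, 25.0))[:4] + rng.random(4))
            res = compare_independent(a, b)
            assert res.p_value == pytest.approx(rank_sum_exact_p(a, b))

    def test_p_decreases_with_shift(self, rng):
        base = rng.normal(0, 1, 50)
        ps = [
            compare_independent(base, base + shift).p_value
            for shift in (0.0, 0.5, 1.0, 2.0)
        ]
        assert all(p2 < p1 + 1e-12 for p1, p2 in zip(ps, ps[1:]))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_independent([], [1.0])


def signed_rank_exact_p(diffs):
    """Enumeration oracle over all sign assignments of |differences|."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_obs = ranks[d > 0].sum()
    n = len(d)
    mean_w = n * (n + 1) / 4
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        count += abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12
    return count / 2**n


class TestComparePaired:
    def test_no_change_gives_p_one(self):
        res = compare_paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0
        assert res.method == "wilcoxon-degenerate"

    def test_all_positive_differences_n6(self):
        pre = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        post = [2.0, 4.0, 6.0, 8.0, 10.0, 12.0]
        res = compare_paired(pre, post)
        assert res.p_value == pytest.approx(2 / 2**6)

    def test_random_pairs_match_enumeration(self, rng):
        for _ in range(5):
            d = rng.normal(0.3, 1.0, 8)
            d = np.where(np.abs(d) < 1e-6, 0.5, d)  # avoid zeros/ties
            res = compare_paired(np.zeros(8), d)
            assert res.p_value == pytest.approx(signed_rank_exact_p(d))

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            compare_paired([1.0], [1.0, 2.0])


class TestSidak:
    def test_k_one_is_identity(self):
        assert sidak_adjust(0.03, 1) == pytest.approx(0.03)

    def test_closed_form_k2(self):
        assert sidak_adjust(0.05, 2) == pytest.approx(0.0975)

    def test_bounded_by_bonferroni(self, rng):
        for p in rng.uniform(0.001, 0.5, 20):
            for k in (2, 5, 10):
                adj = sidak_adjust(p, k)
                assert p <= adj <= min(1.0, k * p) + 1e-12


def anova_frame(rng, group_effect=0.0, n_subjects=8):
    rows = []
    for g in ("A", "B"):
        for s in ("GM", "ADP", "SUCC"):
            base = {"GM": 5, "ADP": 15, "SUCC": 25}[s]
            for i in range(n_subjects):
                val = base + (group_effect if g == "B" else 0) + rng.normal(0, 2)
                rows.append(dict(value=val, group=g, state=s, subject=f"{g}{i}"))
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_detects_group_effect_and_sidak_adjusts(self, rng):
        df = anova_frame(rng, group_effect=6.0)
        res = two_way_anova_sidak(df)
        assert res["k_comparisons"] == 3
        for _, row in res["pairwise"].iterrows():
            assert row["p_sidak"] == pytest.approx(
                sidak_adjust(row["p_value"], 3)
            )
            assert row["p_sidak"] >= row["p_value"]

    def test_repeated_measures_complete_design(self, rng):
        rows = []
        for i in range(8):
            subj_offset = rng.normal(0, 1)
            for g in ("pre", "post"):
                for s in ("GM", "ADP"):
                    base = {"GM": 5, "ADP": 15}[s] + (3.0 if g == "post" else 0)
                    rows.append(dict(value=base + subj_offset + rng.normal(0, 0.5),
                                     group=g, state=s, subject=f"S{i}"))
        df = pd.DataFrame(rows)
        res = two_way_anova_sidak(df, subject="subject", repeated=True)
        anova = res["anova"]
        assert anova.loc["group", "Pr > F"] < 0.01

    def test_missing_cell_in_repeated_design_rejected(self, rng):
        rows = []
        for i in range(4):
            for g in ("pre", "post"):
                for s in ("GM", "ADP"):
                    rows.append(dict(value=rng.normal(), group=g, state=s,
                                     subject=f"S{i}"))
        df = pd.DataFrame(rows).drop(index=0)
        with pytest.raises(ValueError, match="incomplete"):
            two_way_anova_sidak(df, subject="subject", repeated=True)

    def test_null_type_one_error_near_alpha(self, rng):
        """Main-effect rejection rate ~5% when there is no group effect."""
        rejections = 0
        n_sims = 200
        for _ in range(n_sims):
            df = anova_frame(rng, group_effect=0.0, n_subjects=5)
            res = two_way_anova_sidak(df)
            p = res["anova"].loc["C(group)", "PR(>F)"]
            rejections += p < 0.05
        assert 0.02 <= rejections / n_sims <= 0.08


def test_trend_band_labels():
    assert label_significance(0.01) == "significant"
    assert label_significance(0.07) == "trend"
    assert label_significance(0.2) == "ns"
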