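"""Bootstrap / permutation / FDR machinery for Δfiber proportions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mitofiber import (
    FiberPopulationSpec,
    analyze_cohort_deltas,
    bonferroni_mean_tests,
    bootstrap_delta,
    call_significance,
    classify_fibers,
    fdr_adjust,
    generate_fiber_population,
    permutation_test_delta,
)


def labels(n_low, n_normal, n_high, rng=None):
    arr = np.array(["low"] * n_low + ["normal"] * n_normal + ["high"] * n_high,
                   dtype=object)
    if rng is not None:
        rng.shuffle(arr)
    return pd.Series(arr)


class TestBootstrapDelta:
    def test_same_fibers_ci_centered_on_zero(self, rng):
        pre = labels(30, 140, 30, rng)
        res = bootstrap_delta(pre, pre, B=500, seed=1)
        assert res["delta_high"] == 0.0
        lo, hi = res["ci_high"]
        assert lo < 0 < hi
        assert lo == pytest.approx(-hi, abs=0.03)  # symmetric by construction

    def test_degenerate_single_class_ci_is_zero(self):
        pre = labels(0, 50, 0)
        res = bootstrap_delta(pre, pre, B=200, seed=2)
        assert res["ci_high"] == (0.0, 0.0)
        assert res["ci_low"] == (0.0, 0.0)

    def test_ci_contains_point_estimate(self, rng):
        pre = labels(20, 150, 30, rng)
        post = labels(10, 130, 60, rng)
        res = bootstrap_delta(pre, post, B=1000, seed=3)
        assert res["ci_high"][0] <= res["delta_high"] <= res["ci_high"][1]
        assert res["ci_low"][0] <= res["delta_low"] <= res["ci_low"][1]

    def test_bit_exact_reproducibility(self, rng):
        pre = labels(20, 60, 20, rng)
        post = labels(10, 60, 30, rng)
        a = bootstrap_delta(pre, post, B=300, seed=7)
        b = bootstrap_delta(pre, post, B=300, seed=7)
        assert a == b

    def test_small_b_rejected(self):
        with pytest.raises(ValueError, match="B"):
            bootstrap_delta(labels(1, 1, 1), labels(1, 1, 1), B=50)


class TestPermutationTest:
    def test_zero_delta_gives_p_one(self, rng):
        pre = labels(20, 60, 20, rng)
        res = permutation_test_delta(pre, pre, n_perm=199, seed=1)
        assert res["p_high"] == 1.0
        assert res["p_low"] == 1.0

    def test_degenerate_pool_gives_p_one(self):
        res = permutation_test_delta(labels(0, 40, 0), labels(0, 40, 0),
                                     n_perm=199, seed=1)
        assert res["p_high"] == 1.0

    def test_p_in_unit_interval_never_zero(self, rng):
        pre = labels(0, 100, 0)
        post = labels(0, 40, 60)  # extreme shift
        res = permutation_test_delta(pre, post, n_perm=199, seed=2)
        assert 0 < res["p_high"] <= 1
        assert res["p_high"] == pytest.approx(1 / 200)  # add-one floor

    def test_bit_exact_reproducibility(self, rng):
        pre = labels(20, 60, 20, rng)
        post = labels(10, 50, 40, rng)
        a = permutation_test_delta(pre, post, n_perm=299, seed=5)
        b = permutation_test_delta(pre, post, n_perm=299, seed=5)
        assert a == b

    def test_power_above_09_for_quarter_shift(self, control_model):
        """Injected Δfibers_high = 0.25 at 300 fibers/side is detected nearly
        always at alpha = 0.05."""
        rejections = 0
        n_sims = 40
        for s in range(n_sims):
            pre = classify_fibers(control_model, generate_fiber_population(
                FiberPopulationSpec(n_fibers=300, frac_high=0.05, seed=1000 + s)))
            post = classify_fibers(control_model, generate_fiber_population(
                FiberPopulationSpec(n_fibers=300, frac_high=0.30, seed=2000 + s)))
            res = permutation_test_delta(pre, post, n_perm=299, seed=s)
            rejections += res["p_high"] < 0.05
        assert rejections / n_sims > 0.9


class TestFDR:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.037])[0] == pytest.approx(0.037)

    def test_hand_computed_step_up(self):
        # step-up: q_(i) = min over j>=i of p_(j) * m / j
        # {0.01,0.02,0.03,0.04}, m=4 -> 0.04 for every rank
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04] * 4)

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1,
                    max_size=30))
    @settings(derandomize=True, max_examples=50)
    def test_never_decreases_and_preserves_order(self, ps):
        q = fdr_adjust(ps)
        p = np.asarray(ps)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1.0 + 1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestCallRule:
    @pytest.mark.parametrize(
        "delta,p,direction,expected",
        [
            (0.3, 0.01, "high", "significant_increase_high"),
            (0.3, 0.20, "high", "ns"),
            (-0.3, 0.01, "high", "significant_negative_change"),
            (-0.2, 0.01, "low", "significant_decrease_low"),
            (0.2, 0.01, "low", "significant_negative_change"),
            (0.2, 0.30, "low", "ns"),
            (0.0, 0.01, "high", "ns"),
        ],
    )
    def test_direction_plus_significance(self, delta, p, direction, expected):
        assert call_significance(delta, p, direction=direction) == expected


class TestBonferroni:
    def test_adjustment_is_min_one_k_p(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
        for k in (1, 3, 50):
            res = bonferroni_mean_tests(a, b, k=k)
            assert res["p_adjusted"] == pytest.approx(min(1.0, k * res["p_value"]))
        res1 = bonferroni_mean_tests(a, b, k=1)
        assert res1["p_adjusted"] == pytest.approx(res1["p_value"])

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_mean_tests([1, 2], [3, 4], k=0)


class TestCohortAnalysis:
    def _cohort(self, control_model, seed0):
        """3 responders (Δfibers_high = +0.25) and 3 nulls."""
        classified = {}
        for i in range(6):
            responder = i < 3
            pre = classify_fibers(control_model, generate_fiber_population(
                FiberPopulationSpec(n_fibers=300, frac_high=0.05,
                                    seed=seed0 + 2 * i)))
            post_frac = 0.30 if responder else 0.05
            post = classify_fibers(control_model, generate_fiber_population(
                FiberPopulationSpec(n_fibers=300, frac_high=post_frac,
                                    seed=seed0 + 2 * i + 1)))
            classified[(f"P{i + 1}", "ndufb8")] = (pre, post)
        return classified

    def test_joint_recovery_of_responders(self, control_model):
        """At q < 0.05 the call rule finds the true responders and stays
        quiet on the nulls in nearly all simulated cohorts."""
        sens, clean = [], []
        n_reps = 25
        for rep in range(n_reps):
            table, _ = analyze_cohort_deltas(
                self._cohort(control_model, seed0=10_000 + 100 * rep),
                B=300, n_perm=299, seed=rep,
            )
            calls = [
                call_significance(d, q, alpha=0.05, direction="high")
                for d, q in zip(table["delta_high"], table["q_fdr_high"])
            ]
            responders = [c == "significant_increase_high" for c in calls[:3]]
            false_calls = [c != "ns" for c in calls[3:]]
            sens.append(np.mean(responders))
            clean.append(not any(false_calls))
        assert np.mean(sens) >= 0.9
        assert np.mean(clean) >= 0.9

    def test_manifest_labels_null_model_as_stand_in(self, control_model):
        table, manifest = analyze_cohort_deltas(
            self._cohort(control_model, seed0=555), B=100, n_perm=99, seed=0
        )
        assert "stand-in" in manifest["null_model"]
        assert set(table.columns) >= {
            "delta_high", "delta_low", "boot_ci_high", "boot_ci_low",
            "p_perm_high", "p_perm_low", "q_fdr_high", "q_fdr_low",
            "call_high", "call_low",
        }
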