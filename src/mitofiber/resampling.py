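"""Uncertainty and significance for Δfiber proportions.

A participant's change in fiber-class proportions between paired pre- and
post-training sections (Δfibers_high, Δfibers_low) is a difference of two
empirical proportions at fiber resolution. Uncertainty is attached by a
nonparametric bootstrap (fibers resampled with replacement independently
within each timepoint, classes fixed by the shared control model) and
significance by a permutation test whose null pools the participant's pre +
post fibers and randomly re-splits them into groups of the original sizes —
a documented stand-in for an exchangeable no-change null. Two-sided p-values
use the add-one rule, ``p = (1 + #{|Δ*| ≥ |Δ̂|}) / (n_perm + 1)``, so p is
never 0. Across the whole family (participants × channels × directions),
p-values are adjusted by the Benjamini–Hochberg false-discovery-rate
step-up, and the final direction-plus-significance call declares a
significant increase of high fibers only when Δfibers_high > 0 with p below
alpha (symmetrically a significant decrease of low fibers); significant
changes in the opposite direction are reported as "significant negative
change" rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic_data import split_seed

__all__ = [
    "DeltaResult",
    "bootstrap_delta",
    "permutation_test_delta",
    "fdr_adjust",
    "call_significance",
    "bonferroni_mean_tests",
    "analyze_cohort_deltas",
]


def _as_labels(classes) -> np.ndarray:
    """Coerce a classification result to a clean label array (NaN dropped)."""
    s = pd.Series(classes).dropna()
    if s.empty:
        raise ValueError("no classified fibers")
    return s.to_numpy(dtype=object)


def _deltas(pre: np.ndarray, post: np.ndarray) -> tuple[float, float]:
    dh = float(np.mean(post == "high") - np.mean(pre == "high"))
    dl = float(np.mean(post == "low") - np.mean(pre == "low"))
    return dh, dl


def bootstrap_delta(
    pre_classes,
    post_classes,
    B: int = 1000,
    seed: int | None = None,
) -> dict:
    """Percentile bootstrap CI for Δfibers_high and Δfibers_low.

    Fibers are resampled with replacement independently within the pre and
    post sets; their classes are fixed (the control model is shared, so
    resampling fibers resamples labels). Returns the point estimates and the
    2.5/97.5 percentile intervals. Deterministic under a fixed seed.
    """
    if B < 100:
        raise ValueError("B must be >= 100 for a stable percentile interval")
    pre = _as_labels(pre_classes)
    post = _as_labels(post_classes)
    rng = np.random.default_rng(seed)
    dh, dl = _deltas(pre, post)

    n1, n2 = pre.size, post.size
    pre_hi, pre_lo = (pre == "high").astype(np.int8), (pre == "low").astype(np.int8)
    post_hi, post_lo = (post == "high").astype(np.int8), (post == "low").astype(np.int8)
    i1 = rng.integers(0, n1, size=(B, n1))
    i2 = rng.integers(0, n2, size=(B, n2))
    dh_star = post_hi[i2].mean(axis=1) - pre_hi[i1].mean(axis=1)
    dl_star = post_lo[i2].mean(axis=1) - pre_lo[i1].mean(axis=1)

    return {
        "delta_high": dh,
        "delta_low": dl,
        "ci_high": tuple(np.percentile(dh_star, [2.5, 97.5])),
        "ci_low": tuple(np.percentile(dl_star, [2.5, 97.5])),
        "B": B,
    }


def permutation_test_delta(
    pre_classes,
    post_classes,
    n_perm: int = 999,
    seed: int | None = None,
) -> dict:
    """Two-sided permutation p-values for Δfibers_high and Δfibers_low.

    Null: pool the participant's pre + post fibers and re-split at random
    into groups of the original sizes. ``p = (1 + #{|Δ*| ≥ |Δ̂|}) /
    (n_perm + 1)``. When the pooled classes are all identical the test is
    degenerate and p = 1 by convention.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    pre = _as_labels(pre_classes)
    post = _as_labels(post_classes)
    dh, dl = _deltas(pre, post)
    pooled = np.concatenate([pre, post])
    if len(set(pooled.tolist())) == 1:
        return {"p_high": 1.0, "p_low": 1.0, "n_perm": n_perm,
                "delta_high": dh, "delta_low": dl}

    rng = np.random.default_rng(seed)
    n1 = pre.size
    hi = (pooled == "high").astype(np.int8)
    lo = (pooled == "low").astype(np.int8)
    both = np.stack([hi, lo])  # permute the two indicators with one shuffle
    perms = np.tile(np.arange(pooled.size), (n_perm, 1))
    perms = rng.permuted(perms, axis=1)
    hi_p = both[0][perms]
    lo_p = both[1][perms]
    dh_star = hi_p[:, n1:].mean(axis=1) - hi_p[:, :n1].mean(axis=1)
    dl_star = lo_p[:, n1:].mean(axis=1) - lo_p[:, :n1].mean(axis=1)

    eps = 1e-12  # proportions are rationals; guard float comparison
    p_high = (1 + np.sum(np.abs(dh_star) >= abs(dh) - eps)) / (n_perm + 1)
    p_low = (1 + np.sum(np.abs(dl_star) >= abs(dl) - eps)) / (n_perm + 1)
    return {"p_high": float(p_high), "p_low": float(p_low), "n_perm": n_perm,
            "delta_high": dh, "delta_low": dl}


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values.

    Monotone and order-preserving; never smaller than the raw p.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to adjust")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_significance(
    delta: float, p: float, alpha: float = 0.05, direction: str = "high"
) -> str:
    """Direction-plus-significance call for one class.

    For the high class, a significant *increase* requires Δ > 0 and p <
    alpha; for the low class, a significant *decrease* requires Δ < 0 and
    p < alpha. A significant change in the opposite direction (e.g. more
    deficient fibers after training) is reported as
    ``significant_negative_change``; everything else is ``ns``.
    """
    if direction not in ("high", "low"):
        raise ValueError("direction must be 'high' or 'low'")
    if p >= alpha or delta == 0:
        return "ns"
    if direction == "high":
        return "significant_increase_high" if delta > 0 else "significant_negative_change"
    return "significant_decrease_low" if delta < 0 else "significant_negative_change"


def bonferroni_mean_tests(
    values_a, values_b, k: int, paired: bool = False
) -> dict:
    """Two-sided t-test on mean values with Bonferroni adjustment for k comparisons.

    ``p_adjusted = min(1, k * p)``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if paired:
        res = stats.ttest_rel(a, b)
    else:
        res = stats.ttest_ind(a, b)
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "p_adjusted": float(min(1.0, k * res.pvalue)),
        "k": k,
    }


@dataclass(frozen=True)
class DeltaResult:
    """Per participant × channel change result with uncertainty and calls."""

    participant: str
    channel: str
    delta_high: float
    delta_low: float
    boot_ci_high: tuple[float, float]
    boot_ci_low: tuple[float, float]
    p_perm_high: float
    p_perm_low: float
    q_fdr_high: float
    q_fdr_low: float
    call_high: str
    call_low: str


def analyze_cohort_deltas(
    classified: Mapping[tuple[str, str], tuple],
    B: int = 1000,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Full Δfiber analysis for a cohort of classified pre/post fiber sets.

    ``classified`` maps ``(participant, channel)`` to ``(pre_classes,
    post_classes)`` label arrays produced with one shared control model per
    channel. Runs bootstrap + permutation per pair, adjusts the whole family
    of p-values (participants × channels × both directions) by
    Benjamini–Hochberg, applies the call rule, and returns a result table
    plus a run manifest recording seeds and settings.
    """
    keys = list(classified)
    seeds = split_seed(seed, 2 * len(keys))
    rows = []
    for i, (participant, channel) in enumerate(keys):
        pre, post = classified[(participant, channel)]
        boot = bootstrap_delta(pre, post, B=B, seed=seeds[2 * i])
        perm = permutation_test_delta(pre, post, n_perm=n_perm, seed=seeds[2 * i + 1])
        rows.append(
            dict(
                participant=participant, channel=channel,
                delta_high=boot["delta_high"], delta_low=boot["delta_low"],
                boot_ci_high=boot["ci_high"], boot_ci_low=boot["ci_low"],
                p_perm_high=perm["p_high"], p_perm_low=perm["p_low"],
            )
        )
    table = pd.DataFrame(rows)
    q = fdr_adjust(np.concatenate([table["p_perm_high"], table["p_perm_low"]]))
    table["q_fdr_high"] = q[: len(table)]
    table["q_fdr_low"] = q[len(table):]
    table["call_high"] = [
        call_significance(d, p, alpha, "high")
        for d, p in zip(table["delta_high"], table["p_perm_high"])
    ]
    table["call_low"] = [
        call_significance(d, p, alpha, "low")
        for d, p in zip(table["delta_low"], table["p_perm_low"])
    ]
    manifest = {
        "seed": seed, "B": B, "n_perm": n_perm, "alpha": alpha,
        "fdr_method": "benjamini-hochberg",
        "null_model": (
            "pool-and-resplit permutation within participant; documented "
            "stand-in for the combined bootstrap/permutation/FDR procedure"
        ),
    }
    return table, manifest
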