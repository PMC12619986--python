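"""Muscle-integrity marker proportions and the NCAM+/− CSA contrast.

Works on per-fiber flag tables: each fiber carries boolean calls for
sarcolemmal NCAM re-expression (denervation), at least one centrally located
nucleus, a nuclear clump (aggregation of two or more nuclei) and damaged
(inward-folded or ruptured) laminin, plus an optional cross-sectional area.
Upstream image analysis is out of scope — flags are inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_stats import compare_paired

__all__ = ["MarkerProportion", "marker_proportion", "csa_contrast", "ncam_csa_analysis"]


@dataclass(frozen=True)
class MarkerProportion:
    """Percentage of marker-positive fibers in one sample."""

    percent: float
    n_fibers: int
    n_positive: int
    low_n: bool  # fewer fibers than the counting rule asks for


def marker_proportion(
    table: pd.DataFrame, marker: str, min_fibers: int = 100
) -> MarkerProportion:
    """Percentage of fibers positive for a marker.

    Samples with fewer than ``min_fibers`` analyzable fibers (default 100,
    the per-sample counting rule) are flagged ``low_n`` but still reported —
    scarce biopsy tissue is the norm in this population, and dropping such
    samples would bias the cohort.
    """
    if table.empty:
        raise ValueError("empty fiber table")
    flags = table[marker].dropna().astype(bool)
    n = len(flags)
    if n == 0:
        raise ValueError(f"no non-missing values for marker {marker!r}")
    pos = int(flags.sum())
    return MarkerProportion(
        percent=100.0 * pos / n, n_fibers=n, n_positive=pos, low_n=n < min_fibers
    )


def csa_contrast(ncam_pos_csa, ncam_neg_csa) -> float:
    """Percent difference in mean CSA of NCAM+ vs NCAM− fibers.

    ``100 * (mean(pos) - mean(neg)) / mean(neg)``; negative values mean the
    denervated (NCAM+) fibers are atrophied relative to innervated fibers.
    """
    pos = np.asarray(ncam_pos_csa, dtype=float)
    neg = np.asarray(ncam_neg_csa, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both NCAM+ and NCAM- groups must be non-empty")
    return float(100.0 * (pos.mean() - neg.mean()) / neg.mean())


def ncam_csa_analysis(table: pd.DataFrame) -> dict:
    """Participant-level NCAM+/− CSA comparison.

    Pools fibers within participant to get per-participant NCAM+ and NCAM−
    mean CSAs, averages the per-participant contrasts, and pairs the two
    means across participants with a Wilcoxon signed-rank test. Participants
    lacking fibers in either group are skipped (no within-subject contrast).
    """
    per_participant = []
    for pid, sub in table.groupby("participant"):
        pos = sub.loc[sub["ncam_pos"].astype(bool), "csa"].dropna()
        neg = sub.loc[~sub["ncam_pos"].astype(bool), "csa"].dropna()
        if len(pos) == 0 or len(neg) == 0:
            continue
        per_participant.append(
            {"participant": pid, "mean_pos": pos.mean(), "mean_neg": neg.mean(),
             "contrast_pct": csa_contrast(pos, neg)}
        )
    if not per_participant:
        raise ValueError("no participant has fibers in both NCAM groups")
    df = pd.DataFrame(per_participant)
    result = {
        "per_participant": df,
        "mean_contrast_pct": float(df["contrast_pct"].mean()),
    }
    if len(df) >= 2 and (df["mean_pos"] != df["mean_neg"]).any():
        result["wilcoxon"] = compare_paired(df["mean_pos"], df["mean_neg"])
    return result
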