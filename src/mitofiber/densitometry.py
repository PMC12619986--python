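"""Immunoblot densitometry: loading-control normalization and OXPHOS index.

Band optical densities (OD) for the five representative OXPHOS subunits —
NDUFB8 (Complex I), SDHB (Complex II), UQCRC2 (Complex III), MT-CO1
(Complex IV) and ATP5A (ATP synthase) — are normalized to the stain-free
total-protein signal of their own lane (the loading control), expressed as
fold change relative to the mean of the unaffected group, and summed into a
single OXPHOS protein content index per sample.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["SUBUNITS", "lane_normalize", "fold_change_vs_unaffected", "oxphos_index"]

#: Blot subunit columns, one representative subunit per OXPHOS complex.
SUBUNITS = ("ndufb8", "sdhb", "uqcrc2", "mtco1", "atp5a")


def lane_normalize(lanes: pd.DataFrame) -> pd.DataFrame:
    """Divide each subunit OD by the lane's total-protein (stain-free) signal.

    Expects columns ``total_protein`` plus any subset of :data:`SUBUNITS`;
    other columns (participant, timepoint, group, ...) pass through.
    """
    total = np.asarray(lanes["total_protein"], dtype=float)
    if np.any(~np.isfinite(total)) or np.any(total <= 0):
        raise ValueError("total_protein must be positive in every lane")
    present = [s for s in SUBUNITS if s in lanes.columns]
    if not present:
        raise ValueError("no subunit OD columns found")
    if (lanes[present] < 0).any().any():
        raise ValueError("optical densities must be non-negative")
    out = lanes.copy()
    out[present] = lanes[present].div(lanes["total_protein"], axis=0)
    out = out.drop(columns=["total_protein"])
    return out


def fold_change_vs_unaffected(
    normalized: pd.DataFrame, reference_group: str = "unaffected"
) -> pd.DataFrame:
    """Express each lane's normalized subunit values relative to the
    unaffected-group mean of that subunit.

    By construction the reference group's mean fold change is exactly 1 per
    subunit.
    """
    ref = normalized[normalized["group"] == reference_group]
    if ref.empty:
        raise ValueError(f"no lanes in reference group {reference_group!r}")
    present = [s for s in SUBUNITS if s in normalized.columns]
    ref_means = ref[present].mean()
    if (ref_means <= 0).any():
        bad = list(ref_means.index[ref_means <= 0])
        raise ValueError(f"non-positive reference mean for subunit(s) {bad}")
    out = normalized.copy()
    out[present] = normalized[present].div(ref_means, axis=1)
    return out


def oxphos_index(fold_changes: pd.DataFrame, on_missing: str = "drop") -> pd.Series:
    """OXPHOS protein content index: per-sample sum of the five subunits.

    Requires all five subunit columns. Samples with any missing band are not
    imputed: with ``on_missing="drop"`` (default) they are excluded with a
    warning naming the sample; with ``on_missing="error"`` they raise.
    """
    missing_cols = [s for s in SUBUNITS if s not in fold_changes.columns]
    if missing_cols:
        raise ValueError(f"missing subunit column(s): {missing_cols}")
    vals = fold_changes[list(SUBUNITS)]
    incomplete = vals.isna().any(axis=1)
    if incomplete.any():
        if on_missing == "error":
            raise ValueError(
                f"missing band(s) in rows {list(fold_changes.index[incomplete])}"
            )
        warnings.warn(
            "excluded from OXPHOS index (missing band, not imputed): "
            f"rows {list(fold_changes.index[incomplete])}",
            stacklevel=2,
        )
    return vals[~incomplete].sum(axis=1)
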