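"""Per-fiber OXPHOS deficiency classification by prediction-interval regression.

In quadruple immunofluorescence each fiber yields intensities for a Complex I
subunit (NDUFB8), a Complex IV subunit (MT-CO1) and a mitochondrial mass
marker (VDAC1). Because subunit abundance scales with mitochondrial mass, a
fiber is judged deficient or overabundant *relative to its mass signal*:
a linear regression of (log2) subunit intensity on (log2) VDAC1 intensity is
fitted on the pooled unaffected control fibers, and each test fiber is
compared against the 95% prediction interval of that regression,

    yhat(x) ± t_{0.975, n-2} · s · sqrt(1 + 1/n + (x - x̄)² / Σ(xᵢ - x̄)²),

where s is the residual standard deviation of the control fit. Fibers below
the lower bound are "low" (OXPHOS-deficient), above the upper bound "high"
(overabundant), inside or on a bound "normal" — the boundary goes to normal
so that deficiency calls stay conservative. The same control model is reused
for a participant's pre- and post-training sections, so the post-minus-pre
change in class proportions (Δfibers) is not confounded by refitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PIModel",
    "ClassProportions",
    "fit_control_model",
    "classify_fibers",
    "class_proportions",
    "delta_proportions",
]

CHANNELS = ("ndufb8", "mtco1")
MASS_MARKER = "vdac1"


def _apply_transform(values: np.ndarray, transform: str) -> np.ndarray:
    if transform == "log2":
        if np.any(~np.isfinite(values)) or np.any(values <= 0):
            raise ValueError("log2 transform requires positive finite intensities")
        return np.log2(values)
    if transform == "none":
        return np.asarray(values, dtype=float)
    raise ValueError("transform must be 'log2' or 'none'")


@dataclass(frozen=True)
class PIModel:
    """Control regression with everything needed for its prediction interval.

    Fitted on pooled unaffected fibers: ``slope``/``intercept`` of
    transformed subunit signal on transformed mass-marker signal,
    ``resid_sd`` the residual standard deviation (n-2 denominator),
    ``x_mean`` and ``x_sumsq_centered`` the regressor mean and centered sum
    of squares, and ``t_crit`` the 97.5% Student-t quantile at n-2 degrees of
    freedom (two-sided 95% interval).
    """

    channel: str
    transform: str
    slope: float
    intercept: float
    resid_sd: float
    n_control: int
    x_mean: float
    x_sumsq_centered: float
    t_crit: float

    def __post_init__(self) -> None:
        if self.n_control < 3:
            raise ValueError("prediction interval needs >= 3 control fibers")
        if self.resid_sd < 0:
            raise ValueError("resid_sd must be non-negative")

    @property
    def key(self) -> tuple:
        """Fingerprint used to verify pre/post comparisons share one model."""
        return (self.channel, self.transform, self.slope, self.intercept,
                self.resid_sd, self.n_control)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def pi_halfwidth(self, x: np.ndarray) -> np.ndarray:
        """Half-width of the 95% prediction interval for a new fiber at x."""
        x = np.asarray(x, dtype=float)
        return self.t_crit * self.resid_sd * np.sqrt(
            1.0 + 1.0 / self.n_control + (x - self.x_mean) ** 2 / self.x_sumsq_centered
        )

    def bounds(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        hw = self.pi_halfwidth(x)
        yhat = self.predict(x)
        return yhat - hw, yhat + hw


def fit_control_model(
    control_fibers: pd.DataFrame,
    channel: str = "ndufb8",
    transform: str = "log2",
) -> PIModel:
    """Fit the unaffected-control regression for one subunit channel.

    ``control_fibers`` must carry positive ``vdac1`` and channel intensity
    columns; all rows are pooled (one control population). Raises on fewer
    than 3 fibers or zero variance in the mass-marker signal.
    """
    if channel not in CHANNELS:
        raise ValueError(f"channel must be one of {CHANNELS}")
    x = _apply_transform(np.asarray(control_fibers[MASS_MARKER], dtype=float), transform)
    y = _apply_transform(np.asarray(control_fibers[channel], dtype=float), transform)
    n = x.size
    if n < 3:
        raise ValueError("need >= 3 control fibers")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("mass-marker signal has zero variance; cannot regress")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    resid_sd = float(np.sqrt(np.sum(resid**2) / (n - 2)))
    return PIModel(
        channel=channel,
        transform=transform,
        slope=slope,
        intercept=intercept,
        resid_sd=resid_sd,
        n_control=n,
        x_mean=float(x.mean()),
        x_sumsq_centered=sxx,
        t_crit=float(stats.t.ppf(0.975, n - 2)),
    )


def classify_fibers(model: PIModel, fibers: pd.DataFrame) -> pd.Series:
    """Classify each fiber as ``low`` / ``normal`` / ``high`` for the model's channel.

    Fibers below the lower 95% prediction bound are ``low``, above the upper
    bound ``high``, inside or exactly on a bound ``normal``. Fibers whose
    mass-marker or channel intensity is missing or non-positive (and so
    cannot be log-transformed) are excluded: their class is NaN, and callers
    can count them via ``result.isna()``.
    """
    xr = np.asarray(fibers[MASS_MARKER], dtype=float)
    yr = np.asarray(fibers[model.channel], dtype=float)
    if model.transform == "log2":
        valid = np.isfinite(xr) & np.isfinite(yr) & (xr > 0) & (yr > 0)
    else:
        valid = np.isfinite(xr) & np.isfinite(yr)
    out = np.full(len(fibers), np.nan, dtype=object)
    if valid.any():
        x = _apply_transform(xr[valid], model.transform)
        y = _apply_transform(yr[valid], model.transform)
        lo, hi = model.bounds(x)
        cls = np.where(y < lo, "low", np.where(y > hi, "high", "normal"))
        out[valid] = cls
    return pd.Series(out, index=fibers.index, name=f"class_{model.channel}")


@dataclass(frozen=True)
class ClassProportions:
    """Empirical low/normal/high proportions for one section and channel."""

    p_low: float
    p_normal: float
    p_high: float
    n_fibers: int
    model_key: tuple | None = None

    def __post_init__(self) -> None:
        total = self.p_low + self.p_normal + self.p_high
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")


def class_proportions(classes: pd.Series, model: PIModel | None = None) -> ClassProportions:
    """Empirical class proportions from a classification result.

    Excluded fibers (NaN class) are dropped before counting. Passing the
    model stamps its fingerprint onto the result so that pre/post deltas can
    verify they share one control model.
    """
    valid = classes.dropna()
    n = len(valid)
    if n == 0:
        raise ValueError("no classified fibers")
    counts = valid.value_counts()
    return ClassProportions(
        p_low=counts.get("low", 0) / n,
        p_normal=counts.get("normal", 0) / n,
        p_high=counts.get("high", 0) / n,
        n_fibers=n,
        model_key=model.key if model is not None else None,
    )


def delta_proportions(
    pre: ClassProportions, post: ClassProportions
) -> tuple[float, float]:
    """Post-minus-pre change in class proportions: ``(Δfibers_high, Δfibers_low)``.

    Both timepoints must have been classified with the same control model
    (checked via the model fingerprint when available); a positive
    Δfibers_high means more overabundant fibers after training, a negative
    Δfibers_low means fewer deficient fibers.
    """
    if (
        pre.model_key is not None
        and post.model_key is not None
        and pre.model_key != post.model_key
    ):
        raise ValueError("pre and post proportions come from different control models")
    return post.p_high - pre.p_high, post.p_low - pre.p_low
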