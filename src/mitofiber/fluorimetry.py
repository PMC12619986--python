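"""Amplex-UltraRed H2O2 fluorimetry: calibration, emission rates, leak.

The horseradish-peroxidase / Amplex-UltraRed system converts H2O2 released by
the fiber bundle into a fluorescent product, so the chamber fluorescence
rises in proportion to cumulative H2O2. A daily calibration line (successive
additions of known H2O2 without tissue) converts the fluorescence slope into
a concentration slope; mass normalization then yields emission in
pmol H2O2 · min⁻¹ · mg⁻¹ wet mass:

    J_H2O2 = (dF/dt / gain) * V / m * 60

The free radical leak divides the H2O2 emission rate by the simultaneously
measured O2 flux (here under glutamate + malate + ADP + succinate),
expressing the fraction of electron flow escaping as superoxide-derived
H2O2 per unit of oxygen consumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .respirometry import StateRateTable, AnnotatedTrace, _fit_window

__all__ = [
    "CalibrationFit",
    "fit_calibration",
    "h2o2_rates",
    "free_radical_leak",
    "normalize_h2o2_by_index",
]


@dataclass(frozen=True)
class CalibrationFit:
    """A fitted fluorescence-vs-[H2O2] calibration line.

    ``gain`` is fluorescence units per concentration unit (AU per pmol/mL);
    a valid calibration has positive gain.
    """

    gain: float
    offset: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("calibration requires at least 2 points")


def fit_calibration(series: pd.DataFrame) -> CalibrationFit:
    """Ordinary least-squares line of fluorescence on known H2O2 concentration.

    ``series`` needs columns ``conc`` and ``fluor`` with at least two
    distinct concentrations.
    """
    conc = np.asarray(series["conc"], dtype=float)
    fluor = np.asarray(series["fluor"], dtype=float)
    if np.unique(conc).size < 2:
        raise ValueError("calibration needs >= 2 distinct concentrations")
    res = stats.linregress(conc, fluor)
    return CalibrationFit(
        gain=float(res.slope),
        offset=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=conc.size,
    )


def h2o2_rates(
    trace: AnnotatedTrace,
    cal: CalibrationFit,
    state_rates: StateRateTable,
) -> StateRateTable:
    """Fill per-state H2O2 emission rates into a state-rate table.

    Uses the same steady-state windows already chosen for the O2 fluxes, so
    respiration and emission refer to identical intervals. Rate per state is
    ``(fluorescence slope / gain) * V / m * 60`` in pmol·min⁻¹·mg⁻¹.
    """
    if cal.gain <= 0:
        raise ValueError("calibration gain must be positive")
    if trace.fluor is None:
        raise ValueError("trace has no fluorescence channel")
    out = state_rates.copy()
    for state in out.table.index:
        lo = out.table.loc[state, "window_start"]
        hi = out.table.loc[state, "window_end"]
        if not (np.isfinite(lo) and np.isfinite(hi)):
            continue
        slope, n, _ = _fit_window(trace.time, trace.fluor, lo, hi)
        if n < 2:
            continue
        out.table.loc[state, "h2o2_rate"] = (
            slope / cal.gain * trace.chamber_volume_ml / trace.wet_mass_mg * 60.0
        )
    return out


def free_radical_leak(
    h2o2_rate_gmads: float,
    o2_flux_gmads: float,
    electron_pair_percent: bool = False,
) -> float:
    """H2O2 emission divided by simultaneous O2 consumption.

    Both arguments are the glutamate + malate + ADP + succinate values:
    emission in pmol·min⁻¹·mg⁻¹ and flux in nmol·min⁻¹·mg⁻¹, so the default
    ratio is in pmol H2O2 per nmol O2. With ``electron_pair_percent`` the
    ratio is expressed as a percentage of electron pairs leaking,
    ``(H2O2 / (2 * O2)) * 100``, an alternative convention. Returns NaN when
    the O2 flux is not strictly positive (leak undefined).
    """
    if not np.isfinite(o2_flux_gmads) or o2_flux_gmads <= 0:
        return float("nan")
    ratio = h2o2_rate_gmads / o2_flux_gmads
    if electron_pair_percent:
        return ratio / 2.0 * 100.0
    return ratio


def normalize_h2o2_by_index(
    state_rates: StateRateTable, oxphos_index: float
) -> StateRateTable:
    """Divide every H2O2 emission rate by an OXPHOS protein content index."""
    if not np.isfinite(oxphos_index) or oxphos_index <= 0:
        raise ValueError("oxphos_index must be a positive finite scalar")
    out = state_rates.copy()
    out.table["h2o2_rate"] = out.table["h2o2_rate"] / oxphos_index
    return out
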