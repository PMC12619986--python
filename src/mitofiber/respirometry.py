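"""High-resolution respirometry state analysis.

Turns an event-annotated oxygraph trace (O2 concentration over time in a
closed chamber containing a weighed bundle of permeabilized muscle fibers)
into per-titration-state oxygen fluxes and derived coupling ratios.

The substrate-uncoupler-inhibitor titration (SUIT) protocol modelled here is
the classical permeabilized-fiber sequence: glutamate + malate (state II,
leak respiration on Complex I substrates), ADP (state III, maximal
ADP-stimulated respiration), succinate (convergent Complex I+II electron
input), oligomycin (ATP-synthase inhibited) and antimycin A (non-mitochondrial
residual). Fluxes are expressed per mg of wet fiber mass:

    J_O2 [nmol O2 min^-1 mg^-1] = -(d[O2]/dt) * V / m * 60

with d[O2]/dt the least-squares slope of chamber O2 concentration
(nmol mL^-1 s^-1) over a steady-state window, V the chamber volume (mL) and
m the wet mass (mg).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

#: Canonical titration-state labels in protocol order.
SUIT_STATES = ("GM", "ADP", "SUCC", "OLI", "AA")

#: Human-readable aliases for the classical respiratory states.
STATE_II = "GM"    # substrate-only (glutamate + malate)
STATE_III = "ADP"  # maximal ADP-stimulated respiration


@dataclass(frozen=True)
class WindowPolicy:
    """How steady-state windows are placed within each titration state.

    Parameters
    ----------
    window_s:
        Length of the trailing fit window, in seconds. The default window is
        the last ``window_s`` seconds before the next titration event.
    settle_s:
        Dead time after each titration during which the signal is still
        equilibrating (mixing, substrate diffusion); never included in a fit
        window.
    min_points:
        Minimum number of samples required to fit a slope.
    min_variance_search:
        If True, slide a ``window_s``-long window over the usable part of the
        state and keep the one with the smallest residual variance around the
        linear fit, instead of the fixed trailing window.
    search_stride_s:
        Stride of the optional window search, in seconds.
    """

    window_s: float = 60.0
    settle_s: float = 60.0
    min_points: int = 2
    min_variance_search: bool = False
    search_stride_s: float = 5.0


@dataclass
class AnnotatedTrace:
    """An event-annotated O2 (and optionally fluorescence) chamber trace.

    Attributes
    ----------
    time:
        Sample times in seconds, strictly increasing.
    o2_conc:
        Chamber O2 concentration, nmol per mL.
    events:
        Ordered ``(label, time_s)`` titration annotations. Labels are unique
        except for repeated calibration additions (``H2O2cal_k``).
    chamber_volume_ml, wet_mass_mg:
        Chamber volume (mL) and wet mass of the fiber bundle (mg).
    fluor:
        Optional Amplex-UltraRed fluorescence channel (arbitrary units).
    """

    time: np.ndarray
    o2_conc: np.ndarray
    events: list[tuple[str, float]]
    chamber_volume_ml: float
    wet_mass_mg: float
    fluor: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.o2_conc = np.asarray(self.o2_conc, dtype=float)
        if self.fluor is not None:
            self.fluor = np.asarray(self.fluor, dtype=float)
            if self.fluor.shape != self.time.shape:
                raise ValueError("fluor and time must have the same length")
        if self.time.ndim != 1 or self.time.size < 2:
            raise ValueError("trace needs at least two samples")
        if self.o2_conc.shape != self.time.shape:
            raise ValueError("o2_conc and time must have the same length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.chamber_volume_ml <= 0:
            raise ValueError("chamber_volume_ml must be positive")
        if self.wet_mass_mg <= 0:
            raise ValueError("wet_mass_mg must be positive")
        labels = [lab for lab, _ in self.events if not lab.startswith("H2O2cal")]
        if len(labels) != len(set(labels)):
            raise ValueError("non-calibration event labels must be unique")
        times = [t for _, t in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")

    def state_intervals(self) -> list[tuple[str, float, float]]:
        """``(label, start, end)`` per titration state, calibration events excluded."""
        ev = [(lab, t) for lab, t in self.events if not lab.startswith("H2O2cal")]
        out = []
        for i, (lab, t0) in enumerate(ev):
            t1 = ev[i + 1][1] if i + 1 < len(ev) else float(self.time[-1])
            out.append((lab, t0, t1))
        return out


@dataclass
class StateRateTable:
    """Per-state O2 flux (and optionally H2O2 emission) for one chamber run.

    ``table`` is indexed by state label with columns ``o2_flux``
    (nmol O2 min^-1 mg^-1), ``h2o2_rate`` (pmol H2O2 min^-1 mg^-1, NaN until
    filled in by the fluorimetry module), ``window_start``, ``window_end``,
    ``n_points`` and ``qc`` (semicolon-separated flags, empty when clean).
    """

    table: pd.DataFrame
    chamber_volume_ml: float
    wet_mass_mg: float
    flux_units: str = "nmol_O2.min-1.mg-1"

    def o2_flux(self, state: str) -> float:
        return float(self.table.loc[state, "o2_flux"])

    def h2o2_rate(self, state: str) -> float:
        return float(self.table.loc[state, "h2o2_rate"])

    @property
    def states(self) -> list[str]:
        return list(self.table.index)

    def copy(self) -> "StateRateTable":
        return replace(self, table=self.table.copy())


def _fit_window(time: np.ndarray, y: np.ndarray, lo: float, hi: float):
    """Least-squares slope of y on time restricted to [lo, hi]."""
    mask = (time >= lo) & (time <= hi)
    t, v = time[mask], y[mask]
    if t.size < 2:
        return np.nan, 0, np.nan
    slope, intercept = np.polyfit(t, v, 1)
    resid = v - (slope * t + intercept)
    return float(slope), int(t.size), float(np.var(resid))


def _place_window(t0: float, t1: float, policy: WindowPolicy):
    """Default window: last ``window_s`` s of the state, after the settle time."""
    usable_lo = t0 + policy.settle_s
    lo = max(t1 - policy.window_s, usable_lo)
    return lo, t1, lo > t1 - policy.window_s + 1e-12


def extract_state_rates(
    trace: AnnotatedTrace,
    policy: WindowPolicy | None = None,
    aa_correct: bool = False,
) -> StateRateTable:
    """Compute per-state O2 flux from an annotated trace.

    Flux per state is ``-(slope of o2_conc over the window) * V / m * 60``.
    States too short for the settle + window policy are fitted on whatever
    usable samples remain and flagged ``short_state``; states with fewer than
    ``policy.min_points`` usable samples get NaN flux and an
    ``insufficient_samples`` flag rather than a hard error.

    When ``aa_correct`` is True the antimycin-A (non-mitochondrial) flux is
    subtracted from every other state; the AA row itself is kept as measured.
    """
    policy = policy or WindowPolicy()
    rows = {}
    for label, t0, t1 in trace.state_intervals():
        qc: list[str] = []
        usable_lo = t0 + policy.settle_s
        if usable_lo >= t1:
            rows[label] = dict(
                o2_flux=np.nan, h2o2_rate=np.nan, window_start=np.nan,
                window_end=np.nan, n_points=0, qc="insufficient_samples",
            )
            continue
        if policy.min_variance_search:
            lo, hi = _search_min_variance_window(trace, t0, t1, policy)
            short = False
        else:
            lo, hi, short = _place_window(t0, t1, policy)
        slope, n, _ = _fit_window(trace.time, trace.o2_conc, lo, hi)
        if short:
            qc.append("short_state")
        if n < policy.min_points:
            qc.append("insufficient_samples")
            flux = np.nan
        else:
            flux = -slope * trace.chamber_volume_ml / trace.wet_mass_mg * 60.0
        rows[label] = dict(
            o2_flux=flux, h2o2_rate=np.nan, window_start=lo, window_end=hi,
            n_points=n, qc=";".join(qc),
        )
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "state"
    if aa_correct and "AA" in table.index and np.isfinite(table.loc["AA", "o2_flux"]):
        aa = table.loc["AA", "o2_flux"]
        others = table.index != "AA"
        table.loc[others, "o2_flux"] = table.loc[others, "o2_flux"] - aa
    return StateRateTable(
        table=table,
        chamber_volume_ml=trace.chamber_volume_ml,
        wet_mass_mg=trace.wet_mass_mg,
    )


def _search_min_variance_window(trace, t0, t1, policy):
    usable_lo = t0 + policy.settle_s
    best = (usable_lo, min(usable_lo + policy.window_s, t1))
    best_var = np.inf
    lo = usable_lo
    while lo + policy.window_s <= t1 + 1e-9:
        hi = lo + policy.window_s
        _, n, var = _fit_window(trace.time, trace.o2_conc, lo, hi)
        if n >= policy.min_points and var < best_var:
            best, best_var = (lo, hi), var
        lo += policy.search_stride_s
    return best


def write_trace(trace: AnnotatedTrace, csv_path, events_path) -> None:
    """Write a trace as long-format CSV plus a JSON event sidecar."""
    import json

    df = pd.DataFrame({"time_s": trace.time, "o2_nmol_per_ml": trace.o2_conc})
    if trace.fluor is not None:
        df["fluor_au"] = trace.fluor
    df.to_csv(csv_path, index=False)
    sidecar = {
        "events": [[lab, t] for lab, t in trace.events],
        "chamber_volume_ml": trace.chamber_volume_ml,
        "wet_mass_mg": trace.wet_mass_mg,
    }
    with open(events_path, "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_trace(csv_path, events_path) -> AnnotatedTrace:
    """Read a trace written by :func:`write_trace`."""
    import json

    df = pd.read_csv(csv_path)
    with open(events_path) as fh:
        sidecar = json.load(fh)
    return AnnotatedTrace(
        time=df["time_s"].to_numpy(),
        o2_conc=df["o2_nmol_per_ml"].to_numpy(),
        fluor=df["fluor_au"].to_numpy() if "fluor_au" in df.columns else None,
        events=[(lab, float(t)) for lab, t in sidecar["events"]],
        chamber_volume_ml=float(sidecar["chamber_volume_ml"]),
        wet_mass_mg=float(sidecar["wet_mass_mg"]),
    )


def acr(state_rates: StateRateTable) -> float:
    """Acceptor control ratio: state III / state II respiration.

    State III is maximal ADP-stimulated respiration (glutamate + malate +
    ADP), state II the substrate-only rate (glutamate + malate). Returns NaN
    (undefined) when the state II flux is not strictly positive.
    """
    s2 = state_rates.o2_flux(STATE_II)
    s3 = state_rates.o2_flux(STATE_III)
    if not np.isfinite(s2) or s2 <= 0:
        return float("nan")
    return s3 / s2


def normalize_by_oxphos_index(
    state_rates: StateRateTable, oxphos_index: float
) -> StateRateTable:
    """Divide every O2 flux by an OXPHOS protein content index.

    Expresses respiration per unit of OXPHOS complex content rather than per
    mg of wet mass, isolating intrinsic (per-complex) changes in respiratory
    function from changes in mitochondrial content.
    """
    if not np.isfinite(oxphos_index) or oxphos_index <= 0:
        raise ValueError("oxphos_index must be a positive finite scalar")
    out = state_rates.copy()
    out.table["o2_flux"] = out.table["o2_flux"] / oxphos_index
    out.flux_units = f"{state_rates.flux_units}.per_index_unit"
    return out


def average_duplicates(
    a: StateRateTable, b: StateRateTable, rel_tol: float = 0.20
) -> StateRateTable:
    """Combine duplicate chamber runs of the same sample by per-state mean.

    States whose duplicate fluxes differ by more than ``rel_tol`` relative to
    their mean are flagged ``duplicate_discordant`` (kept, not dropped).
    """
    if list(a.table.index) != list(b.table.index):
        raise ValueError("duplicate runs must share the same state set")
    out = a.copy()
    for col in ("o2_flux", "h2o2_rate"):
        out.table[col] = (a.table[col] + b.table[col]) / 2.0
    for state in out.table.index:
        fa, fb = a.table.loc[state, "o2_flux"], b.table.loc[state, "o2_flux"]
        m = (fa + fb) / 2.0
        flags = [f for f in str(out.table.loc[state, "qc"]).split(";") if f]
        if np.isfinite(fa) and np.isfinite(fb) and m != 0 and abs(fa - fb) / abs(m) > rel_tol:
            flags.append("duplicate_discordant")
        out.table.loc[state, "qc"] = ";".join(flags)
    out.table["n_points"] = np.minimum(a.table["n_points"], b.table["n_points"])
    return out
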