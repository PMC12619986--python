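"""Synthetic data generation for every pipeline input.

This module is the study-condition emulator: it produces per-fiber quadruple
immunofluorescence (QIF) intensity tables, event-annotated oxygraph /
fluorimeter traces, H2O2 calibration series, per-fiber histology flag tables
and the baseline cohort characteristics table, each with the statistical
structure the downstream analysis assumes. Every generator is deterministic
under a fixed integer seed, and ground truth (fiber class labels, generating
fluxes, marker probabilities) is carried alongside the data so recovery can
be tested end to end.

Intensities are generated and modelled on the log2 scale by default
(``transform="log2"``): fluorescence intensity distributions are
right-skewed and the control relationship between a subunit signal and the
mitochondrial mass signal is closer to linear after a log transform. This is
a modelling assumption of the emulator, selectable via the ``transform``
toggle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .respirometry import AnnotatedTrace

__all__ = [
    "FiberPopulationSpec",
    "TraceSpec",
    "split_seed",
    "generate_fiber_population",
    "generate_trace",
    "generate_calibration_series",
    "generate_histology_table",
    "cohort_fixture",
    "GROUP_CONDITIONS",
    "cohort_trace_specs",
]

MAX_SEED = 2**31 - 1


def split_seed(seed: int, n: int) -> list[int]:
    """Split one global seed into ``n`` independent per-stream sub-seeds.

    Allows each generator to be re-run independently while the whole cohort
    stays reproducible from a single integer.
    """
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, MAX_SEED, size=n)]


# ---------------------------------------------------------------------------
# Per-fiber QIF populations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FiberPopulationSpec:
    """Generative model of one section's fiber population.

    The control relationship is linear on the transformed scale:
    ``subunit = intercept + slope * mass + N(0, resid_sd)`` where ``mass`` is
    the mitochondrial mass-marker (VDAC1) signal drawn from
    ``N(mass_mean, mass_sd)``. A fraction ``frac_low`` of fibers receives the
    negative offset ``low_shift`` on both subunit channels (OXPHOS-deficient
    fibers) and ``frac_high`` receives the positive ``high_shift``
    (overabundant fibers).
    """

    n_fibers: int = 500
    mass_mean: float = 10.0   # log2 intensity units
    mass_sd: float = 0.6
    slope: float = 1.0
    intercept: float = 0.0
    resid_sd: float = 0.25    # log2 units; 0 is the noiseless limit
    frac_low: float = 0.0
    frac_high: float = 0.0
    low_shift: float = -1.5   # log2 units, must be negative when used
    high_shift: float = 1.5   # log2 units, must be positive when used
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be a positive count")
        if not (0 <= self.frac_low <= 1 and 0 <= self.frac_high <= 1):
            raise ValueError("frac_low and frac_high must lie in [0, 1]")
        if self.frac_low + self.frac_high > 1:
            raise ValueError("frac_low + frac_high must not exceed 1")
        if self.resid_sd < 0:
            raise ValueError("resid_sd must be non-negative")
        if self.mass_sd <= 0:
            raise ValueError("mass_sd must be positive")
        if self.frac_low > 0 and self.low_shift >= 0:
            raise ValueError("low_shift must be negative")
        if self.frac_high > 0 and self.high_shift <= 0:
            raise ValueError("high_shift must be positive")


def generate_fiber_population(
    spec: FiberPopulationSpec,
    section_id: str = "S1",
    participant: str = "P1",
    timepoint: str = "pre",
    transform: str = "log2",
) -> pd.DataFrame:
    """Draw one section's fiber table from a :class:`FiberPopulationSpec`.

    Returns a DataFrame with columns ``fiber_id, section_id, participant,
    timepoint, vdac1, ndufb8, mtco1, area, true_class``. Exactly
    ``round(frac_low * n)`` fibers carry the low shift and
    ``round(frac_high * n)`` the high shift; which fibers is randomized but
    seed-deterministic. ``true_class`` records the generating class for
    recovery tests.
    """
    if transform not in ("log2", "none"):
        raise ValueError("transform must be 'log2' or 'none'")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_fibers
    n_low = round(spec.frac_low * n)
    n_high = round(spec.frac_high * n)

    classes = np.array(["normal"] * n, dtype=object)
    order = rng.permutation(n)
    classes[order[:n_low]] = "low"
    classes[order[n_low : n_low + n_high]] = "high"
    shift = np.where(
        classes == "low", spec.low_shift, np.where(classes == "high", spec.high_shift, 0.0)
    )

    x = rng.normal(spec.mass_mean, spec.mass_sd, n)
    y_ndufb8 = spec.intercept + spec.slope * x + rng.normal(0, spec.resid_sd, n) + shift
    y_mtco1 = spec.intercept + spec.slope * x + rng.normal(0, spec.resid_sd, n) + shift
    if transform == "log2":
        vdac1, ndufb8, mtco1 = 2.0**x, 2.0**y_ndufb8, 2.0**y_mtco1
    else:
        vdac1, ndufb8, mtco1 = x, y_ndufb8, y_mtco1
        if np.any(vdac1 <= 0) or np.any(ndufb8 <= 0) or np.any(mtco1 <= 0):
            raise ValueError(
                "transform='none' produced non-positive intensities; "
                "raise mass_mean/intercept or use the log2 transform"
            )
    area = np.exp(rng.normal(np.log(4000.0), 0.35, n))  # μm², log-normal CSA

    return pd.DataFrame(
        {
            "fiber_id": [f"{section_id}_f{i:05d}" for i in range(n)],
            "section_id": section_id,
            "participant": participant,
            "timepoint": timepoint,
            "vdac1": vdac1,
            "ndufb8": ndufb8,
            "mtco1": mtco1,
            "area": area,
            "true_class": classes,
        }
    )


# ---------------------------------------------------------------------------
# Oxygraph / fluorimeter traces
# ---------------------------------------------------------------------------

#: Default SUIT titration schedule: (label, time s, O2 flux nmol·min⁻¹·mg⁻¹,
#: H2O2 emission pmol·min⁻¹·mg⁻¹). Fluxes here are placeholders overridden by
#: most callers.
DEFAULT_PROTOCOL = [
    ("GM", 0.0, 5.0, 10.0),
    ("ADP", 300.0, 15.0, 7.0),
    ("SUCC", 600.0, 25.0, 18.0),
    ("OLI", 900.0, 6.0, 30.0),
    ("AA", 1200.0, 2.0, 5.0),
]


@dataclass(frozen=True)
class TraceSpec:
    """Generative model of one chamber run.

    ``protocol`` lists ``(event_label, event_time_s, true_O2_flux,
    true_H2O2_rate)`` in nmol·min⁻¹·mg⁻¹ and pmol·min⁻¹·mg⁻¹ respectively.
    The chamber O2 concentration is piecewise-linear: within each state the
    slope is ``-flux * wet_mass / (chamber_volume * 60)`` nmol·mL⁻¹·s⁻¹; the
    fluorescence channel rises at ``fluor_gain * rate * wet_mass /
    (chamber_volume * 60)`` AU·s⁻¹. Additive iid Gaussian noise is applied
    per sample. Default wet mass sits in the 3-6 mg range typical of
    permeabilized fiber bundle preparations.
    """

    protocol: list[tuple[str, float, float, float]] = field(
        default_factory=lambda: list(DEFAULT_PROTOCOL)
    )
    wet_mass_mg: float = 4.0
    chamber_volume_ml: float = 2.0
    noise_sd: float = 0.0        # O2 signal units (nmol/mL)
    fluor_noise_sd: float = 0.0  # fluorescence AU
    sampling_interval_s: float = 2.0
    duration_s: float | None = None  # default: last event + 300 s
    o2_init: float = 220.0           # nmol/mL, near air saturation at 37 °C
    fluor_init: float = 50.0
    fluor_gain: float = 1.0          # AU per (pmol H2O2 / mL)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.protocol:
            raise ValueError("protocol must contain at least one event")
        times = [t for _, t, _, _ in self.protocol]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing (no overlaps)")
        if self.wet_mass_mg <= 0 or self.chamber_volume_ml <= 0:
            raise ValueError("wet_mass_mg and chamber_volume_ml must be positive")
        if self.sampling_interval_s <= 0:
            raise ValueError("sampling_interval_s must be positive")
        if self.noise_sd < 0 or self.fluor_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")


def _piecewise_linear(t, boundaries, slopes, v0):
    """Evaluate a continuous piecewise-linear signal at sample times ``t``."""
    # signal value at the start of each segment
    seg_len = np.diff(boundaries)
    cum = v0 + np.concatenate([[0.0], np.cumsum(slopes[:-1] * seg_len[:-1])])
    idx = np.searchsorted(boundaries, t, side="right") - 1
    idx = np.clip(idx, 0, len(slopes) - 1)
    return cum[idx] + slopes[idx] * (t - boundaries[idx])


def generate_trace(spec: TraceSpec) -> AnnotatedTrace:
    """Generate an event-annotated O2 + fluorescence trace from a :class:`TraceSpec`."""
    rng = np.random.default_rng(spec.seed)
    last_event = spec.protocol[-1][1]
    duration = spec.duration_s if spec.duration_s is not None else last_event + 300.0
    if duration <= last_event:
        raise ValueError("duration_s must extend past the last event")
    t = np.arange(0.0, duration + 1e-9, spec.sampling_interval_s)

    ev_times = np.array([e[1] for e in spec.protocol])
    fluxes = np.array([e[2] for e in spec.protocol])
    rates = np.array([e[3] for e in spec.protocol])
    # prepend a zero-flux baseline segment if the first event starts after t=0
    if ev_times[0] > 0:
        boundaries = np.concatenate([[0.0], ev_times, [duration]])
        o2_slopes = np.concatenate([[0.0], -fluxes * spec.wet_mass_mg / (spec.chamber_volume_ml * 60.0)])
        fl_slopes = np.concatenate([[0.0], spec.fluor_gain * rates * spec.wet_mass_mg / (spec.chamber_volume_ml * 60.0)])
    else:
        boundaries = np.concatenate([ev_times, [duration]])
        o2_slopes = -fluxes * spec.wet_mass_mg / (spec.chamber_volume_ml * 60.0)
        fl_slopes = spec.fluor_gain * rates * spec.wet_mass_mg / (spec.chamber_volume_ml * 60.0)

    o2 = _piecewise_linear(t, boundaries, o2_slopes, spec.o2_init)
    fl = _piecewise_linear(t, boundaries, fl_slopes, spec.fluor_init)
    if spec.noise_sd > 0:
        o2 = o2 + rng.normal(0, spec.noise_sd, t.size)
    if spec.fluor_noise_sd > 0:
        fl = fl + rng.normal(0, spec.fluor_noise_sd, t.size)

    return AnnotatedTrace(
        time=t,
        o2_conc=o2,
        fluor=fl,
        events=[(lab, tt) for lab, tt, _, _ in spec.protocol],
        chamber_volume_ml=spec.chamber_volume_ml,
        wet_mass_mg=spec.wet_mass_mg,
    )


# ---------------------------------------------------------------------------
# H2O2 calibration series
# ---------------------------------------------------------------------------

def generate_calibration_series(
    known_concs,
    gain: float,
    offset: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Fluorescence readings for successive additions of known H2O2.

    One row per addition: ``fluor = offset + gain * conc + N(0, noise_sd)``.
    Concentrations are in pmol/mL; at least two distinct levels are required
    for a calibration line to be identifiable.
    """
    concs = np.asarray(list(known_concs), dtype=float)
    if np.unique(concs).size < 2:
        raise ValueError("need at least 2 distinct H2O2 concentrations")
    rng = np.random.default_rng(seed)
    fluor = offset + gain * concs
    if noise_sd > 0:
        fluor = fluor + rng.normal(0, noise_sd, concs.size)
    return pd.DataFrame({"conc": concs, "fluor": fluor})


# ---------------------------------------------------------------------------
# Histology flag tables
# ---------------------------------------------------------------------------

HISTOLOGY_MARKERS = ("ncam_pos", "central_nucleus", "nuclear_clump", "damaged_laminin")


def generate_histology_table(
    n_fibers: int,
    marker_probs: dict[str, float],
    csa_mean: float = 4500.0,
    csa_sd: float = 1100.0,
    ncam_csa_ratio: float = 0.822,
    seed: int = 0,
    participant: str = "P1",
    timepoint: str = "pre",
) -> pd.DataFrame:
    """Per-fiber Bernoulli marker flags plus cross-sectional area.

    ``marker_probs`` maps marker names (subset of ``HISTOLOGY_MARKERS``) to
    per-fiber probabilities; unnamed markers default to 0. CSA is drawn from
    a truncated normal; denervated (NCAM+) fibers are atrophied by scaling
    their CSA by ``ncam_csa_ratio`` (default 0.822, i.e. a -17.8% mean
    contrast, the atrophy magnitude this emulator targets).
    """
    if n_fibers < 1:
        raise ValueError("n_fibers must be >= 1")
    for marker, p in marker_probs.items():
        if marker not in HISTOLOGY_MARKERS:
            raise ValueError(f"unknown marker {marker!r}")
        if not 0 <= p <= 1:
            raise ValueError(f"probability for {marker!r} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = {"participant": participant, "timepoint": timepoint}
    for marker in HISTOLOGY_MARKERS:
        p = marker_probs.get(marker, 0.0)
        out[marker] = rng.random(n_fibers) < p
    csa = np.clip(rng.normal(csa_mean, csa_sd, n_fibers), 100.0, None)
    csa = np.where(out["ncam_pos"], csa * ncam_csa_ratio, csa)
    out["csa"] = csa
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Baseline cohort characteristics fixture
# ---------------------------------------------------------------------------

_NA = float("nan")

# Per-participant baseline characteristics: nine unaffected women and nine
# women with DM1 (juvenile / adult / late phenotypes). "No data" cells are
# carried as NaN and excluded from summaries; CTG repeat length applies to
# DM1 participants only.
_COHORT_ROWS = [
    # participant, group, phenotype, age, weight, height, bmi, ctg, ncam_pct
    ("Unaffected_1", "unaffected", None, 24, 54.0, 165, 19.8, _NA, 0.35),
    ("Unaffected_2", "unaffected", None, 32, 68.0, 170, 23.5, _NA, 0.31),
    ("Unaffected_3", "unaffected", None, 22, 61.2, 159, 24.2, _NA, _NA),
    ("Unaffected_4", "unaffected", None, 25, 70.3, 165, 25.8, _NA, 2.40),
    ("Unaffected_5", "unaffected", None, 59, 67.2, 159, 26.7, _NA, 0.94),
    ("Unaffected_6", "unaffected", None, 58, 52.2, 157, 21.3, _NA, 0.75),
    ("Unaffected_7", "unaffected", None, 57, 58.8, 165, 21.5, _NA, 0.88),
    ("Unaffected_8", "unaffected", None, 63, 74.1, 159, 29.3, _NA, 0.0),
    ("Unaffected_9", "unaffected", None, 60, 56.1, 162, 21.4, _NA, _NA),
    ("P1", "DM1", "Juvenile", 52, 56.0, 150, 24.9, 509, 7.14),
    ("P2", "DM1", "Juvenile", 33, 52.5, 158, 21.0, 462, 0.0),
    ("P3", "DM1", "Juvenile", 33, 40.0, 168, 14.2, 832, 61.35),
    ("P4", "DM1", "Late", 39, 80.2, 167, 28.8, 70, 0.69),
    ("P5", "DM1", "Adult", 52, 42.8, 165, 15.7, 466, 8.70),
    ("P6", "DM1", "Juvenile", 24, 47.6, 162, 18.1, 488, 6.96),
    ("P7", "DM1", "Adult", 37, 78.5, 153, 33.5, 432, 2.07),
    ("P8", "DM1", "Juvenile", 25, 80.0, 161, 30.9, 300, 1.15),
    ("P9", "DM1", "Adult", 30, 84.3, 161, 32.5, 324, 1.39),
]


def cohort_fixture() -> pd.DataFrame:
    """Baseline per-participant characteristics table.

    Nine unaffected and nine DM1 participants with age, anthropometrics, CTG
    repeat length (DM1 only) and the percentage of NCAM+ (denervated) fibers.
    Missing measurements are NaN.
    """
    return pd.DataFrame(
        _COHORT_ROWS,
        columns=[
            "participant", "group", "phenotype", "age_years", "weight_kg",
            "height_cm", "bmi_kg_m2", "ctg_repeats", "ncam_pos_pct",
        ],
    )


# ---------------------------------------------------------------------------
# Whole-cohort trace conditions
# ---------------------------------------------------------------------------

# Group-level true state fluxes (nmol O2·min⁻¹·mg⁻¹) and H2O2 emission rates
# (pmol·min⁻¹·mg⁻¹) encoding the study's direction of effects: DM1 at
# baseline respires less than unaffected muscle and shows lower absolute H2O2
# emission but a higher free radical leak (H2O2/O2 under GM+ADP+SUCC);
# training partially restores respiration and lowers the leak. Magnitudes are
# typical of permeabilized human vastus lateralis fiber bundles.
GROUP_CONDITIONS: dict[str, dict[str, tuple[float, float]]] = {
    # state: (O2 flux, H2O2 rate)
    "unaffected": {"GM": (8.0, 12.0), "ADP": (24.0, 8.0), "SUCC": (40.0, 20.0),
                   "OLI": (9.0, 35.0), "AA": (2.0, 5.0)},
    "dm1_pre":   {"GM": (5.0, 9.0), "ADP": (14.0, 6.0), "SUCC": (24.0, 16.0),
                  "OLI": (6.0, 22.0), "AA": (2.0, 4.0)},
    "dm1_post":  {"GM": (6.5, 9.5), "ADP": (19.0, 6.5), "SUCC": (32.0, 17.6),
                  "OLI": (7.0, 24.0), "AA": (2.0, 4.2)},
}

_STATE_TIMES = {"GM": 0.0, "ADP": 300.0, "SUCC": 600.0, "OLI": 900.0, "AA": 1200.0}


def cohort_trace_specs(
    seed: int,
    n_per_group: int = 9,
    between_subject_cv: float = 0.10,
    noise_sd: float = 0.15,
    fluor_noise_sd: float = 0.2,
    conditions: dict[str, dict[str, tuple[float, float]]] | None = None,
) -> dict[tuple[str, str], TraceSpec]:
    """Per-participant chamber-run specs for a three-arm cohort.

    Each participant gets one multiplicative log-normal scale factor for all
    O2 fluxes and one for all H2O2 rates (coefficient of variation
    ``between_subject_cv``), so within-subject state structure and leak
    ordering are preserved while subjects differ realistically. DM1 pre and
    post runs of the same participant share the subject scale, emulating
    paired biopsies.
    """
    conditions = conditions or GROUP_CONDITIONS
    rng = np.random.default_rng(seed)
    sub_seeds = iter(split_seed(int(rng.integers(0, MAX_SEED)), 10 * n_per_group))
    sigma = np.sqrt(np.log(1 + between_subject_cv**2))

    specs: dict[tuple[str, str], TraceSpec] = {}
    # paired scales for DM1 participants, independent for unaffected
    dm1_scales = [
        (np.exp(rng.normal(-sigma**2 / 2, sigma)), np.exp(rng.normal(-sigma**2 / 2, sigma)))
        for _ in range(n_per_group)
    ]
    for group in conditions:
        for i in range(n_per_group):
            if group.startswith("dm1"):
                o2_scale, h2o2_scale = dm1_scales[i]
                pid = f"P{i + 1}"
            else:
                o2_scale = np.exp(rng.normal(-sigma**2 / 2, sigma))
                h2o2_scale = np.exp(rng.normal(-sigma**2 / 2, sigma))
                pid = f"U{i + 1}"
            protocol = [
                (state, _STATE_TIMES[state], flux * o2_scale, rate * h2o2_scale)
                for state, (flux, rate) in conditions[group].items()
            ]
            specs[(group, pid)] = TraceSpec(
                protocol=protocol,
                wet_mass_mg=float(rng.uniform(3.0, 6.0)),
                noise_sd=noise_sd,
                fluor_noise_sd=fluor_noise_sd,
                seed=next(sub_seeds),
            )
    return specs
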