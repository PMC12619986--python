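# mitofiber

Quantitative analysis pipeline for strength-training studies of skeletal
muscle in myotonic dystrophy type 1 (DM1): per-fiber OXPHOS deficiency
classification, high-resolution respirometry and H2O2 fluorimetry state
analysis, immunoblot OXPHOS-index normalization, and histological
muscle-integrity statistics — with seeded synthetic-data generators so the
whole chain is testable end to end without patient data.

## Who this is for

Muscle-physiology and mitochondrial-disease labs analysing paired biopsy
studies: per-fiber quadruple immunofluorescence (QIF) intensity tables,
Oroboros-style oxygraph/fluorimeter traces, blot densitometry tables and
per-fiber histology calls. The pipeline starts from tabular measurements —
image segmentation and instrument file parsing are upstream of it.

## The core methods

**Per-fiber OXPHOS phenotyping.** Subunit abundance scales with
mitochondrial mass, so a fiber is judged against its own mass signal: on
pooled unaffected control fibers we fit an OLS regression of log2 subunit
intensity (NDUFB8 for Complex I, MT-CO1 for Complex IV) on log2 VDAC1
intensity and form the 95% prediction interval

```
ŷ(x) ± t₀.₉₇₅,ₙ₋₂ · s · √(1 + 1/n + (x − x̄)² / Σ(xᵢ − x̄)²)
```

Fibers below the band are *low* (deficient), above it *high*
(overabundant), inside *normal*. Post-minus-pre changes in class
proportions (Δfibers^high, Δfibers^low) get percentile-bootstrap CIs,
pool-and-resplit permutation p-values, Benjamini–Hochberg FDR across the
whole family, and a direction-plus-significance call
(Δfibers^high > 0 ∧ p < 0.05, symmetrically for low).

**Respirometry / fluorimetry.** Per titration state of the
substrate–uncoupler–inhibitor protocol (glutamate+malate → ADP → succinate
→ oligomycin → antimycin A), O2 flux is the windowed least-squares slope
scaled to nmol O2·min⁻¹·mg⁻¹ wet mass; the acceptor control ratio is
state III / state II. H2O2 emission uses a daily Amplex-UltraRed
calibration line to convert fluorescence slopes to pmol·min⁻¹·mg⁻¹, and the
free radical leak divides H2O2 emission by simultaneous O2 flux.

**Blots and histology.** Band ODs are normalized to the stain-free lane
total, expressed as fold change vs. the unaffected-group mean, and summed
over the five representative subunits into an OXPHOS protein content index;
integrity markers (NCAM+, central nuclei, nuclear clumps, damaged laminin)
are reported as marker-positive percentages with a ≥100-fibers-per-sample
counting rule, plus the NCAM+/− cross-sectional-area contrast.

## Worked example

```python
import mitofiber as mf

# classify DM1 fibers against a control model and test the pre/post change
controls = mf.generate_fiber_population(mf.FiberPopulationSpec(n_fibers=5000, seed=11))
model = mf.fit_control_model(controls, channel="ndufb8")
pre = mf.classify_fibers(model, mf.generate_fiber_population(
    mf.FiberPopulationSpec(n_fibers=500, frac_high=0.05, seed=1)))
post = mf.classify_fibers(model, mf.generate_fiber_population(
    mf.FiberPopulationSpec(n_fibers=500, frac_high=0.25, seed=2)))
boot = mf.bootstrap_delta(pre, post, B=1000, seed=3)
perm = mf.permutation_test_delta(pre, post, n_perm=999, seed=4)
print(f"delta_high = {boot['delta_high']:.3f}, CI = "
      f"({boot['ci_high'][0]:.3f}, {boot['ci_high'][1]:.3f}), p = {perm['p_high']:.3f}")
print(mf.call_significance(boot["delta_high"], perm["p_high"], direction="high"))

# respirometry round trip on a noiseless synthetic titration trace
trace = mf.generate_trace(mf.TraceSpec())
rates = mf.extract_state_rates(trace)
print(f"state III = {rates.o2_flux('ADP'):.1f} nmol/min/mg, ACR = {mf.acr(rates):.1f}")
```

prints

```
delta_high = 0.188, CI = (0.140, 0.234), p = 0.001
significant_increase_high
state III = 15.0 nmol/min/mg, ACR = 3.0
```

The fiber change of +0.188 is the observed rise in the overabundant
fraction (true injected change 0.20, seen through classification and
sampling noise); the permutation p
at its add-one floor and the positive delta together trigger the
significant-increase call. The state III flux and acceptor control ratio
reproduce the generating trace's values exactly because the trace is
noiseless.

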