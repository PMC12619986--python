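# Methods

This note records the models, defaults and design choices behind the
pipeline, and what its synthetic-data tests do and do not demonstrate about
real data.

## Per-fiber classification model

Quadruple immunofluorescence yields, per fiber, a mitochondrial mass signal
(VDAC1) and subunit signals for Complex I (NDUFB8) and Complex IV (MT-CO1).
The control model is an ordinary least-squares regression of transformed
subunit intensity on transformed mass intensity over all pooled unaffected
fibers, one model per channel. Classification uses the 95% prediction
interval for a *new* observation,
ŷ(x) ± t₀.₉₇₅,ₙ₋₂ · s · √(1 + 1/n + (x − x̄)²/Sxx), with s the residual SD
(n−2 denominator). Choices that were genuinely open:

- **Transform.** Intensities are log2-transformed before regression
  (`transform="log2"`, toggle `"none"` available). Fluorescence intensities
  are right-skewed and multiplicative; on the log scale the mass–subunit
  relationship is close to linear with approximately constant spread, which
  the prediction interval assumes.
- **Control pooling.** All unaffected fibers are pooled into one control
  population per channel; per-participant models can be fitted by passing a
  subset, but pooling is the default because the interval then reflects the
  full between-fiber control variability.
- **Boundary rule.** Fibers exactly on an interval bound count as normal —
  deficiency calls stay conservative.
- **One model per comparison.** A participant's pre and post sections are
  classified with the same control model, so Δfibers is never confounded by
  refitting; `delta_proportions` checks a model fingerprint and rejects
  mixed-model comparisons.
- **Degenerate inputs.** Non-positive or missing intensities cannot be
  log-transformed; such fibers are excluded with a NaN class (countable by
  the caller), never imputed. Zero variance in the mass signal and control
  sets under 3 fibers are hard errors.

## Resampling and the call rule

The unit of resampling is the fiber; fibers are treated as exchangeable
within a section (no mixed-effects modelling of within-section
correlation). The bootstrap resamples fibers with replacement independently
within pre and within post (B = 1000 default) and reports 2.5/97.5
percentiles. The permutation null pools a participant's pre + post fibers
and re-splits them at random into the original group sizes (999 permutations
default); this pool-and-resplit null is a documented stand-in for an
exchangeable no-change null and is labelled as such in the run manifest.
Two-sided p-values use the add-one rule, so p ∈ (0, 1]. The family for
Benjamini–Hochberg FDR adjustment is all participant × channel × direction
tests in one run. The final call requires both direction and significance
(increase of high fibers: Δ > 0 and p < α; decrease of low fibers: Δ < 0
and p < α); significant changes in the opposite direction are reported
as `significant_negative_change`.

## Respirometry and fluorimetry

States follow the titration order GM (state II), +ADP (state III), +SUCC,
+OLI, +AA. Per state, flux = −slope·V/m·60 with slope the least-squares
O2-concentration slope (nmol·mL⁻¹·s⁻¹) over the analysis window, V the
chamber volume (mL, default 2) and m the wet mass (mg, typically 3–6).
Window policy: a fixed trailing window (default last 60 s before the next
titration) after a settle time (default 60 s) — deterministic and simple; an
optional minimal-residual-variance window search exists but is not the
default, and no automatic plateau detection is attempted. States too short
for the policy are fitted on what remains and QC-flagged rather than
dropped; non-monotone time is a hard error. Antimycin-A background
subtraction is available (`aa_correct`) but OFF by default, since the
residual AA state is also reported as its own condition. Duplicate chamber
runs are combined by per-state arithmetic mean, flagged when the two fluxes
differ by more than 20% of their mean.

H2O2 emission shares the respirometry windows: rate = (fluorescence
slope/gain)·V/m·60 in pmol·min⁻¹·mg⁻¹, with the gain from a daily
calibration line (OLS of fluorescence on known H2O2 concentration, ≥ 2
distinct levels). No baseline-drift or probe-consumption correction is
applied beyond the linear offset. The free radical leak is the plain ratio
of the GM+ADP+SUCC H2O2 emission to the simultaneous O2 flux
(pmol H2O2 per nmol O2); an `electron_pair_percent` mode
((H2O2/2·O2)·100) is provided because conventions differ, but the plain
ratio is the default and the leak is undefined (NaN) at non-positive O2
flux.

## Densitometry

Subunit ODs are divided by the stain-free lane total (loading control),
then expressed as fold change against the unaffected-group mean — which
maps that group's mean to exactly 1 — and summed over NDUFB8, SDHB, UQCRC2,
MT-CO1 and ATP5A into the OXPHOS protein content index. The index is
computed on the fold-change scale (a raw-scale sum can be had by skipping
the fold-change step); missing bands are never imputed — the sample is
excluded from the index with a warning naming it.

## Cohort statistics

Independent groups are compared by two-sided Mann–Whitney (exact
enumeration when the combined n ≤ 12 without ties, tie-corrected
asymptotics otherwise), paired timepoints by two-sided Wilcoxon signed-rank
(exact for ≤ 15 non-zero differences without tied magnitudes; all-zero
differences give p = 1 by convention). Group × state designs use two-way
ANOVA — repeated-measures with both factors within-subject for paired
designs, requiring a complete subject × cell table — with per-state
pairwise t-tests adjusted by Šídák (1 − (1 − p)^k). Results with
0.05 ≤ p < 0.1 are labelled trends. Summaries use the sample SD and exclude
missing values listwise; the packaged baseline cohort table carries its
missing cells explicitly. Exact-test conventions are validated against
enumeration oracles in the test suite, not against any published p-values,
since the conventions of commercial software differ in unknowable ways.

## Synthetic-data generator

The generator is the study-condition emulator and its defaults are the
conditions under which all stochastic guarantees are stated:

- **Fiber populations**: log2 VDAC1 ~ N(10, 0.6); subunit = x plus
  N(0, 0.25) residuals around a unit-slope control line; deficient /
  overabundant fibers get ∓1.5 log2-unit shifts (≈ 6 residual SDs, i.e.
  clearly separated classes). Exactly round(frac·n) fibers per class.
- **Traces**: piecewise-linear O2 and fluorescence with per-state slopes
  set by the generating fluxes, 2 s sampling, 300 s per state, additive iid
  Gaussian noise; chamber volume 2 mL, wet mass drawn from 3–6 mg.
- **Cohort conditions** (`GROUP_CONDITIONS`): group-level fluxes encode the
  studied effect directions — DM1 baseline respiration below unaffected
  (state III 14 vs 24 nmol·min⁻¹·mg⁻¹), partial restoration after training
  (19), lower absolute H2O2 emission at baseline but higher free radical
  leak (0.67 vs 0.50 pmol/nmol), reduced by training (0.55). Between-subject
  variability is one multiplicative log-normal scale per participant per
  modality (CV 10%), shared between a DM1 participant's pre and post runs to
  emulate paired biopsies. Magnitudes are in the range typical of
  permeabilized human vastus lateralis bundles.
- **Histology**: Bernoulli marker flags; truncated-normal CSA
  (4500 ± 1100 μm²) with NCAM+ fibers scaled by 0.822, targeting a −17.8%
  denervation-atrophy contrast.
- **Seeding**: one global seed splits into independent per-stream sub-seeds
  (`split_seed`); fixed seed ⇒ bit-identical outputs.

What the emulator does *not* reproduce about real data: intensity
distributions are exactly log-normal and residuals homoscedastic (real QIF
sections show section-to-section staining batch effects and
spatially correlated fibers); traces are exactly piecewise-steady with iid
noise (no drift, re-oxygenation events or probe consumption); fiber class
counts are fixed exactly by the rounding rule rather than binomially
sampled. That last point matters for interpreting the stochastic checks:
with injected class fractions, the observed Δ is *under*dispersed relative
to iid sampling, so bootstrap CIs over-cover (coverage near 100% rather
than the nominal 95%) and such populations cannot serve as a permutation
null. The type-I-error study therefore uses pure control sections (800
fibers/timepoint, a realistic whole-section count), where labels are iid
and the permutation assumption holds; measured rejection is slightly below
α because the discrete statistic's ties are counted conservatively under
the add-one rule. Passing these tests shows the machinery is correct and
calibrated under its stated assumptions, not that real fiber sections
satisfy them.

## Problem sizes

Stochastic guarantees are verified at: 5000 control fibers for the model,
10,000 held-out fibers for coverage; 200 replicates of the Δ = 0.20
recovery at 500 fibers/timepoint (B = 1000, 999 permutations); 1000 null
simulations for type-I error; 500 seeds for calibration-gain recovery; a
25-replicate responder/null cohort study at 300 fibers/side (B = 300, 299
permutations), where the large injected effect keeps power saturated. The
acceptance script uses 100 CI-coverage replicates and 500 null simulations.

## Known limitations

- No instrument-native file parsing; traces arrive as CSV + JSON sidecar.
- No O2-solubility/temperature corrections: fluxes are whatever the
  declared concentration units imply.
- No modelling of within-section fiber correlation; resampling treats
  fibers as exchangeable.
- The repeated-measures ANOVA path requires complete designs; incomplete
  paired data must be handled upstream (or analysed with the nonparametric
  paired test, which drops incomplete pairs).
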