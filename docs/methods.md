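# Methods

## The shielding model

The generator and all downstream contracts assume antibody staining follows
a Langmuir isotherm per cell,

    stain(c) = [background + Bmax · c / (c + Kd_eff)] · L · M,
    Kd_eff   = Kd · (1 + β_g),

where `c` is the staining concentration in nM (converted from µg/mL as
`c_nM = 1000·c/MW_kDa`, IgG molar mass 150 kDa by default), `β_g ≥ 0` is the
genotype's dimensionless shielding factor (0 for WT, and 0 again in the
double knockout when shielding is glycosphingolipid-driven), and `L`, `M`
are independent unit-mean log-normal factors for cell-to-cell and
measurement variation.

Shielding acts on Kd, not on Bmax. This is the one modelling decision that
everything else leans on: at saturation (`c ≫ Kd_eff` for every genotype)
all genotypes stain equally — which is what makes the equal-expression QC at
a saturating concentration meaningful — while at sub-saturating
concentrations the expected KO/WT ratio is

    r(c) = (c + Kd) / (c + Kd·(1 + β)),

strictly decreasing in Kd at fixed `c` and `β`. Two study-level behaviors
therefore *emerge* rather than being programmed: expression QC passes under
arbitrary shielding (as long as the top concentration truly saturates the
shielded genotype too), and lower-affinity antibodies are more shielded,
giving the negative correlation between shielding ratio and log₁₀ Kd. An
optional epitope-height factor `h ∈ (0,1]` scales β to represent epitopes
partially escaping the glycocalyx.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| Bmax | 1000 | a.u. | arbitrary fluorescence scale |
| Kd | 2–20 (panel grid), 5 (single-antibody examples) | nM | typical monoclonal affinities; see below |
| background | 0 (panel), 50 (fit examples) | a.u. | secondary-only level |
| β (shielded) | 1.5 | — | gives r ≈ 0.57 at c = Kd, well outside the band |
| cv_cell | 0.30 | — | realistic cell-to-cell spread of surface expression |
| cv_meas | 0.05 | — | instrument-level noise |
| concentrations | 20, 1, 0.05 | µg/mL | the experimental dilution series |
| barcode separation | 100× | fold | two-decade dye separation |
| background death | 2 | % | typical viability loss |
| similarity band | (0.8, 1.2) | — | 1.25 upper bound available by config |
| saturation tolerance τ | 0.10 | — | plateau rule, WT curve only |
| positivity factor κ | 2.0 | fold | stain vs secondary-only control |
| min events | 500 | cells | MFI reliability floor |

The panel Kd grid (2–20 nM, log-spaced across clones) is chosen from the
closed form: at the 1 µg/mL analysis concentration (≈6.7 nM) the band rule
detects β = 1.5 shielding only when Kd > 0.2·c ≈ 1.3 nM, so the grid keeps
every shielded clone detectable while the 20 µg/mL top concentration
(≈133 nM) still saturates `Kd_eff` up to ~50 nM. This mirrors the
experimental design premise: shielding is read at sub-saturating staining,
expression at saturating staining.

## Titration analysis choices

* **MFI** defaults to the arithmetic mean; geometric mean and median are
  available since flow conventions vary.
* **Saturation** has no standard operational definition; we use a plateau
  rule on the WT curve: concentration `c` is saturating iff
  `MFI_WT(c) ≥ (1 − τ)·max_c MFI_WT`, and the analysis concentration is the
  highest non-saturating one. Flat curves yield no analysis concentration;
  single-concentration curves pass through flagged `undetermined`.
* **Demultiplexing** gates each barcode channel at the geometric midpoint
  between its two intensity modes, found by a deterministic 1D two-means
  split of log₁₀ intensities (scan of all sorted split points minimising
  within-class sum of squares). A channel whose modes are separated by less
  than 1.5-fold is treated as unimodal: a warning is issued and all events
  are called low, which degrades gracefully to chance-level assignment.
  Viability gating (same midpoint construction) precedes all statistics.
* **Ratios** are computed at the single chosen analysis concentration, not
  averaged across concentrations; fusion-protein style dose–response data
  can instead be classified per concentration by calling `classify_epitope`
  on each ratio.
* **Band bounds** are strict inequalities as printed (0.8/1.2 default); the
  alternate 1.25 upper bound is configurable and both are echoed in the run
  report. A ratio of exactly 0.8 is *unaffected*.
* **nsGSL dependence** is keyed on double-knockout restoration
  (`r_DKO > 0.8`): restoration in the double knockout is the informative
  signal for glycosphingolipid-driven shielding, while the single-B3GNT5
  knockout ratio is logged on every call but does not decide the label.

## Protrusion statistic

The protrusion of an extracellular segment is the maximal Euclidean
distance between the Cα of the membrane-adjacent anchor residue and any
segment Cα; the reported value for a protein is the maximum over its
extracellular segments, rounded to 0.1 Å. The anchor is the segment residue
adjacent to a transmembrane span — the last residue of an extracellular
N-terminal segment, otherwise the first residue after the preceding span.
An all-pairs `diameter` metric is available where the anchor convention is
unwanted. Transmembrane spans are explicit configuration (e.g. transcribed
from UniProt), never predicted; model 1 only; alternate locations resolve
to the highest occupancy. No pLDDT filtering is applied to predicted models
by default.

The packaged reference table of 15 ECD sizes reproduces the shielded-group
statistics (mean 55 Å, sample SD 20 Å, n = 7). The non-shielded group's
printed summary (126 ± 22 Å) is *not* exactly recoverable from the listed
values under either inclusion choice for HLA-I (mean ≈118 with it, ≈125
without); the package therefore reports both variants side by side rather
than asserting either.

## Effector assays

Specific death is the plain subtraction `%dead(with) − %dead(without)`;
negative values are kept and flagged (clipping would bias replicate means).
The trogocytosis threshold is the 99.5th percentile of the effector-only
control's DiO channel, so the control scores ≤0.5% against itself by
construction. Statistics are Student's t (pooled variance; Welch optional),
paired t (zero-variance differences are flagged rather than producing
infinities), or one-way ANOVA with Tukey HSD, significance at p ≤ 0.05;
ANOVA is computed per E:T ratio.

## What the generator does and does not emulate

It emulates: barcoded 1:1:1:1 four-genotype mixtures, saturation behavior,
genotype-dependent shielding with double-knockout rescue, log-normal
positive-valued fluorescence, background death, and binomial well-level
killing counts. It does not emulate: spectral spillover/compensation,
scatter channels, autofluorescence, doublets, acquisition drift, donor
effects, or any distributional estimate fit to real data — no distributional
description of the original flow data exists, so all noise parameters are
generator choices. Passing tests therefore demonstrate the correctness and
internal consistency of the analysis rules under the stated model, not
robustness to every artefact of real cytometry data.

## Problem sizes and numerics

The analysis scripts use 2 000 events per genotype per well (10 proteins ×
4 clones × 3 concentrations); recovery checks in the test suite run up to
10⁴ events per well, and Monte-Carlo checks of closed-form expectations use
10⁵ draws with 3·SE tolerances. Binding curves are fit with non-negative
bounded least squares (scipy `curve_fit`), rejecting flat curves (dynamic
range < 5% of maximum) as unidentifiable. Equal-expression QC robustness is
assessed over β ∈ {0.5, 1.5, 3} × 100 seeded runs; for much larger β the
fixed 20 µg/mL top concentration no longer saturates `Kd_eff` and the QC
premise itself breaks — a faithful reflection of the experimental design's
own limitation, documented rather than patched.

## Known limitations

* The classification is threshold-based by design; no uncertainty is
  attached to individual ratios (the experimental analysis used fixed
  bands, not tests).
* The CD9 worked example (40.5 Å from the largest extracellular loop of the
  AlphaFold model) requires the external AF-P21926-F1 structure and its
  exact value is contingent on model version and transcribed TM boundaries.
* Affinities and epitope categories for the 13-clone panel are a synthetic
  stand-in (the real values live in the cited antibody-panel literature);
  the correlation direction, not its numeric value, is the reproducible
  claim.
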