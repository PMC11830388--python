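# glycoshield

Tumor cells that lose the intramembrane protease **SPPL3** accumulate
neolacto-series glycosphingolipids (nsGSLs), because SPPL3 normally degrades
the nsGSL-synthesis enzyme **B3GNT5**. The thickened glycolipid layer
sterically shields membrane-proximal protein epitopes from antibodies and
immune-receptor fusion proteins, blunting recognition by NK cells, γδ T
cells and neutrophils. `glycoshield` implements the quantitative core of
that analysis for researchers working on glycocalyx-mediated immune escape:

* **Titration analysis** (`glycoshield.cytometry`) — demultiplexing of
  barcoded four-genotype mixtures (WT, *SPPL3*⁻/⁻, *B3GNT5*⁻/⁻, double KO),
  MFI computation, saturation detection and the quality-control rules
  (positive stain over the secondary-only control; equal expression at a
  saturating concentration).
* **Epitope-accessibility classification** (`glycoshield.classify`) — the
  band rule on shielding ratios r = MFI(KO)/MFI(WT) at the sub-saturating
  analysis concentration: r < 0.8 → accessibility decreased, r > 1.2 →
  increased, otherwise unaffected; nsGSL dependence from restoration of
  binding in the *SPPL3*⁻/⁻*B3GNT5*⁻/⁻ double knockout; protein grouping
  (fully / partially affected, unaffected, increased, B3GNT5-specific).
* **Extracellular-domain protrusion** (`glycoshield.protrusion`) — for a Cα
  trace and transmembrane topology, the maximal distance
  max_i ‖Cα(anchor) − Cα(i)‖ (Å) from the membrane-adjacent anchor residue
  over each extracellular segment, plus the affected-vs-non-affected group
  comparison (Student's t).
* **Affinity–shielding relation** (`glycoshield.affinity`) — per-antibody
  shielding ratios for a single-target panel, correlation with log₁₀ Kd, and
  a one-way ANOVA across epitope-position categories.
* **Effector assays** (`glycoshield.assays`) — specific death
  (%dead with effectors − %dead without), trogocytosis as the DiO⁺ fraction
  of effector-gated cells, and t/ANOVA+Tukey statistics.
* **Synthetic data** (`glycoshield.synthetic`) — the ground-truth generator:
  a Langmuir isotherm with genotype-dependent effective dissociation
  constant,

  ```
  stain(c) = [background + Bmax · c / (c + Kd·(1 + β_g))] · L · M
  ```

  with log-normal cell (`L`) and measurement (`M`) noise. Shielding inflates
  Kd multiplicatively (β = 0 for WT), so saturating stains are
  genotype-equal while sub-saturating stains reveal shielding — and
  lower-affinity antibodies are automatically more shielded.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic data
with known ground truth (outputs under `results/analysis/`):

```bash
python analysis/01_simulate_panel.py
python analysis/03_classify_epitopes.py
python analysis/04_protrusion.py
python analysis/06_affinity_correlation.py
```

prints, among other things:

```
ground truth: 22/40 clones shielded (beta=1.5), rest unshielded
epitope-label recovery:  100.0% of 40 clones
protein-group recovery:  100.0% of 10 proteins
shielded 55 ± 20 Å vs non-shielded (without_HLA-I) 125 ± 16 Å; t = -7.16, p = 1.2e-05
pearson: r = -0.984, p = 1.3e-09 (n = 13)
position-category ANOVA: F = 0.49, p = 0.63
```

Reading: the band rule recovers every simulated shielding label; proteins
whose epitopes are all shielded protrude far less from the membrane
(≈55 Å) than proteins with at least one escaping epitope (≈125 Å); across a
13-clone panel with uniform shielding, the shielding ratio tracks antibody
affinity (strong negative correlation with log₁₀ Kd) but not epitope
position. The same steps are available as a config-driven pipeline:
`glycoshield run --outdir results/pipeline --seed 1`.

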