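# pzqma

Pharmacokinetics of praziquantel (PZQ) enantiomers and their main
metabolite across three sampling matrices — plasma, venous whole blood
and dried blood spots (DBS) — as a tested, reusable analysis pipeline.

Praziquantel is the drug of choice for the liver fluke *Opisthorchis
viverrini* and is given as a racemate of *R*- and *S*-PZQ; *R*-PZQ is
rapidly cleared into the monohydroxylated metabolite *R-trans*-4-OH-PZQ.
PK field studies in endemic areas increasingly rely on DBS
microsampling, which uses a different matrix than the plasma on which
exposure targets are defined.  Bridging the two requires (i) standard
non-compartmental analysis (NCA), (ii) a formal agreement analysis
between matrices, and (iii) bioanalytical quality control.  This package
implements all three, plus parasitological efficacy statistics, driven
by a synthetic cohort generator that emulates a nine-patient
triple-dose (3 × 25 mg/kg at 0/4/8 h) study design — so every stage can
be tested against known truth without any external data.

## What it computes

* **`pzqma.simulate`** — multi-dose one-compartment cohorts with
  first-order absorption and dose superposition,
  `C(t) = Σ_d s·(D/V)·ka/(ka−ke)·(e^{−ke(t−τ_d)} − e^{−ka(t−τ_d)})`,
  blood = `r_bp`·plasma, proportional assay noise, LLOQ censoring, two
  interleaved 6-point DBS schedules, ISR replicates, spiked
  blood:plasma partition experiments and Kato-Katz egg counts.
* **`pzqma.nca`** — linear-trapezoid AUC₀–₂₄ (with exponential tail
  extrapolation for short schedules), Cmax/Tmax, terminal λz by
  log-linear OLS with automatic point selection, t½ = ln2/λz, and
  median (range) cohort summaries.
* **`pzqma.agreement`** — pooled Pearson correlation and Bland-Altman
  95% limits of agreement on percentage ratios (100·test/plasma), both
  conventional (`mean ± 1.96·SD`) and adapted for multiple measurements
  per individual via one-way ANOVA variance components
  (σ²_total = σ²_between + σ²_within), with subject-level t-based
  confidence intervals.
* **`pzqma.qc`** — incurred sample reanalysis
  (`%diff = (repeat−original)·100/mean`, acceptance: ≥2/3 of pairs
  within 20%), calibration-range censoring (LLOQ 0.01/0.1 µg/ml, ULOQ
  2.5/25 µg/ml), and IS-normalised blood:plasma partition ratios.
* **`pzqma.efficacy`** — EPG = 6 × sum of quadruplicate smear counts,
  geometric means, cure rate and egg-reduction rate.

## Worked example

```bash
pzqma run --seed 42 --out runs/demo
```

runs simulate → qc → nca → agreement → efficacy and writes every table
plus a JSON manifest.  With seed 42 the plasma NCA medians are

```
parameter     auc_0_24   cmax  t_half  tmax
analyte
R-PZQ             1.18   0.19    1.17   8.5
R-trans-4-OH    200.81  14.51    6.64   9.0
S-PZQ            10.55   0.88    3.52   9.0
```

i.e. *S*-PZQ carries roughly ninefold the AUC₀–₂₄ (µg/ml·h) of
*R*-PZQ, and the metabolite dominates both by more than an order of
magnitude — the expected enantioselective first-pass pattern.  The
matrix agreement table for the same run:

```
     analyte matrix  n  pearson_r  mean_ratio_pct  loa_lower_pct  loa_upper_pct
       R-PZQ  blood 81      0.988          80.8           64.3           97.4
       R-PZQ    DBS 40      0.985          82.5           64.5          100.5
R-trans-4-OH  blood 90      0.983         116.9           95.3          138.5
R-trans-4-OH    DBS 45      0.991         114.4           90.5          138.3
       S-PZQ  blood 89      0.989          79.8           62.3           97.4
       S-PZQ    DBS 44      0.987          77.8           59.4           96.3
```

Parent-enantiomer blood/plasma ratios sit near 80% (high plasma protein
binding keeps PZQ out of erythrocytes) while the metabolite exceeds
100%; the generator truth is 80%/115%, so the repeated-measures
Bland-Altman estimates recover the configured partition within a couple
of points.  The ISR stage reports 358/363 pairs (98.6%) within 20% —
comfortably above the 2/3 guideline — and the efficacy stage a 100%
cure rate with ERR 100%.

Each stage is also available standalone (`pzqma simulate`, `pzqma nca`,
`pzqma agree`, `pzqma qc isr|partition`, `pzqma efficacy`) on the CSV
schemas documented in the module docstrings, and as plain library
functions.  Custom designs go in a YAML config, e.g.

```yaml
n_subjects: 12
assay_cv: 0.10
regimen: {dose_mg_per_kg: 40.0, dose_times_h: [0.0]}
analyte_models:
  R-PZQ: {r_blood_plasma: 0.9}
```

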