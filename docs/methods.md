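# Methods

## The problem

Dried blood spots (DBS) make pharmacokinetic field studies feasible in
settings without cold chains, but DBS measure a different matrix than
plasma.  For praziquantel (PZQ) — dosed as a racemate whose *R*
enantiomer is largely converted to *R-trans*-4-OH-PZQ on first pass —
the question is whether concentrations and non-compartmental exposure
metrics measured in whole blood or DBS can stand in for plasma values.
This package implements the full analysis chain for that question and a
synthetic cohort generator that reproduces the structure of a
nine-patient triple-dose study, so the chain can be validated end to
end against known truth.

## Simulation model

Latent kinetics are a one-compartment model with first-order absorption
and superposition over the doses actually taken:

    C_p(t) = Σ_d s · (D/V) · ka/(ka−ke) · (e^{−ke(t−τ_d)} − e^{−ka(t−τ_d)})

with dose D in mg/kg and V the apparent volume per kg, so body weight
cancels.  `s` (exposure_scale) lumps bioavailability and, for the
metabolite, the formation fraction: the metabolite is simulated with
its own (ka, ke, s) rather than an explicit formation model, which is
adequate because all downstream stages see only concentrations.  No
structural model is claimed for the real drug — the paper-style NCA is
the estimand; the kinetic model is simulation plumbing whose defaults
are *calibration targets*.

Whole blood is `r_bp ·` plasma (r_bp the blood:plasma partition ratio)
and DBS measure whole blood with extra error.  Measurement error is
proportional Gaussian, truncated at zero; concentrations below the
assay LLOQ are censored (flag set, value cleared).

### Default parameters

| parameter | R-PZQ | S-PZQ | R-trans-4-OH | rationale |
|---|---|---|---|---|
| ke (1/h) | ln2/1.1 | ln2/3.3 | ln2/6.4 | ln2 / reference median t½ |
| ka (1/h) | 1.5 | 1.5 | 2.5 | places the noiseless Tmax at 9 h (one sample after the last dose) and, for the metabolite, centres Cmax/AUC in its narrow observed range |
| exposure_scale | 0.011219 | 0.024465 | 0.312518 | solved so the noiseless schedule-sampled trapezoid AUC₀–₂₄ equals the reference medians 1.1 / 9.0 / 188.7 µg/ml·h |
| V/F (l/kg) | 1.0 | 1.0 | 1.0 | arbitrary; only s/V is identified |
| r_blood_plasma | 0.80 | 0.80 | 1.15 | parents are ~80% plasma-protein-bound and penetrate erythrocytes poorly; the metabolite partitions into red cells |
| bsv_cv (ke, V/F) | 0.15 | 0.15 | 0.10 | lognormal between-subject CV, set from the relative width of the reference parameter ranges (metabolite spread is visibly narrower) |
| assay_cv / dbs_extra_cv | 0.08 / 0.06 | | | within the ±15% bioanalytical validation envelope |
| LLOQ–ULOQ (µg/ml) | 0.01–2.5 | 0.01–2.5 | 0.1–25 | assay calibration ranges |
| outlier_fraction | 1/9 | | | one high-exposure subject per nine expected, exposure × Uniform(2, 10); optionally skips the third dose |

Design: 9 subjects; 3 × 25 mg/kg at 0/4/8 h; venous schedule
0, 2, 4, 6, 8, 8.5, 9, 10, 11, 12, 24 h for plasma and blood; DBS
schedule A (0, 4, 8, 9, 11, 24 h) for cohort positions 1–5 and B
(0, 2, 6, 8.5, 10, 12 h) for positions 6–9, cycling for larger cohorts.
Nominal times only — no actual-vs-nominal deviation is simulated.
Weights Uniform(40, 77) kg (inert, since dosing is per kg); hematocrit
Normal(0.355, 0.041), recorded per subject but not used to correct DBS
values (the analysis chain applies none).  Egg counts: negative-
binomial smear counts (dispersion 2) scaled so expected EPG is 5 000 —
a moderate-intensity cohort — with guaranteed baseline positivity;
clearance probability defaults to 1.

Seeding: a single integer seed; each subject draws from an independent
`SeedSequence((seed, index))` substream, so enlarging the cohort never
perturbs earlier subjects.  Fixed seed ⇒ byte-identical output tables.

### What the generator does *not* emulate

Absorption variability beyond ka, saturable first-pass or
food/hepatic-function covariates, actual sampling-time deviations,
assay batch effects, DBS hematocrit bias as a function of each
subject's hematocrit, or correlated errors between matrices drawn from
the same venipuncture.  Passing recovery tests therefore shows the
*estimators* are correct and the pipeline coherent — not that real DBS
bridging holds for PZQ; that evidence must come from real paired
samples.

## NCA conventions

* AUC₀–₂₄ by the linear trapezoidal rule over quantifiable points.
* BLQ: leading BLQ → 0; embedded BLQ excluded (interval bridges);
  trailing BLQ truncate the profile.  "Insufficient profile" (<2
  quantifiable points) in practice means an all-BLQ cell, because
  leading BLQ become explicit zeros.
* λz: OLS of ln C on t over the last m points strictly after Tmax,
  m = 3…all, maximising adjusted r² (ties → more points); λz ≤ 0 ⇒
  parameters flagged missing, never an error.  On sparse profiles
  (6-point DBS schedules the peak falls too late for three
  strictly-post-peak points) the Tmax point itself is admitted and the
  cell flagged `terminal_includes_tmax`.  The chosen points are
  reported for audit, and can be overridden per profile.
* When the last quantifiable sample precedes 24 h (DBS schedule B ends
  at 12 h) and λz is estimable, the AUC is completed with
  `C_last/λz·(1−e^{−λz·Δ})` and flagged `extrapolated`; otherwise
  truncated and flagged.  Under the default kinetics this succeeds for
  R-PZQ and the metabolite on schedule B; S-PZQ peaks one sample later
  still and its schedule-B cells are truncated.
* Tmax ties break to the earliest time; medians for even n average the
  two central order statistics.

## Agreement statistics

Ratios, not differences: each pair contributes 100·test/plasma, and
BLQ or nonpositive-reference pairs are excluded (counted), never
imputed.  Conventional limits of agreement: mean ± 1.96·SD (n−1
denominator).  Repeated-measures variant for concentration data: the
grand mean is pooled over all observations, and the total SD combines
one-way-ANOVA variance components

    MS_b = Σ nᵢ(d̄ᵢ−d̄)²/(k−1),  MS_w = ΣΣ(dᵢⱼ−d̄ᵢ)²/(N−k)
    n₀ = (N − Σnᵢ²/N)/(k−1)
    σ²_w = MS_w,  σ²_b = max(0, (MS_b−MS_w)/n₀)

(negative component estimates truncated at zero; all subjects singleton
⇒ conventional fallback, flagged).  1.96 is kept literal in the LoA —
it is the definition being matched, not a tunable quantile.  Confidence
intervals use m = number of subjects as the effective unit count
(within-subject observations are dependent) with t quantiles:
CI(mean) = mean ± t₀.₉₇₅,ₘ₋₁·SD/√m and
CI(limit) = limit ± t₀.₉₇₅,ₘ₋₁·SD·√(1/m + 1.96²/(2(m−1))), the exact
form of the classical 1.71·SD/√m approximation.

## QC and efficacy conventions

ISR percentage difference uses the mean denominator, making it
antisymmetric and bounded by ±200%; "not deviating by more than 20%"
is boundary-inclusive and the pass fraction is compared against exactly
2/3.  Above-ULOQ values are flagged but retained (dilution/reassay is
out of scope).  EPG is 6 × the sum of the quadruplicate smear counts;
geometric means switch to the shifted exp(mean(log(x+1)))−1 form only
when zeros are present (flagged); infection intensity classes are
light <1 000, moderate 1 000–10 000, heavy >10 000 EPG.

## Numerical and design choices

* ka = ke is a removable singularity; configured equality is perturbed
  by 1e-9 relative.
* Intermediate CSVs carry `%.12g` precision; rounding to one decimal is
  presentation-only.
* The ISR sample count is deterministic (`round(fraction·N)` without
  replacement), matching a planned reanalysis campaign.
* Problem sizes in the Monte-Carlo test suites — 20 seeds of the full
  9-subject design — follow the package's own acceptance checks; each
  seed takes well under a second, keeping the whole suite interactive.

## Known limitations

The terminal-slope selection rule is one defensible automation of a
manual practice; reference analyses using other point choices will
produce different t½ (especially for the fast R-PZQ phase, where the
terminal window is short).  AUC extrapolation versus truncation for
12 h-ending DBS profiles is a genuine methodological fork; both paths
are implemented, flagged, and auditable.  The repeated-measures LoA
assume a common within-subject variance across subjects and
approximately ratio-scale-stationary error; heavily skewed ratios would
call for a log-scale analysis, which this package deliberately does not
switch to, to keep outputs on the conventional percentage-ratio scale.
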