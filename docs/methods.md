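# Methods

## The problem and the estimand

Silent atrial fibrillation (SAF) — ECG-confirmed AF in a subject without AF
symptoms — can only be observed under prolonged continuous monitoring, so a
clinical risk score is derived to stratify elderly populations before
monitoring. The package implements the full derivation chain on per-subject
cohort tables and, because no individual-level data are deposited anywhere,
ships a synthetic-cohort generator that reproduces the statistical structure
the analysis assumes. The headline quantity is the c-statistic (AUC) of the
derived integer score on derivation cohorts, averaged over the five-draw
split-resampling procedure.

## Generative model

For each of `n_subjects` (default 3014, the study size):

* **Age** ~ Normal(77.5, 7.9²) truncated below at 65 years. Outcome models
  use age in 5-year units above 65, `age5 = (age − 65)/5`, the scale on
  which the published age odds ratio is expressed.
* **Binary covariates** (male sex, MI, CHD, thyroid disease, pulmonary
  disease, thromboembolism, LEAD, stroke/TIA, PCI/CABG, heart-failure
  history, physical activity, plus the latent condition flags DM, HA, CKD,
  obesity and the two biomarker flags) are thresholded latent Gaussians at
  the normal quantile of each published whole-population prevalence
  (male 50.9 %, CKD 33.3 %, NT-proBNP > 125 pg/mL 75.9 %, …). The latent
  correlation matrix is the identity by default — the study publishes only
  marginals, so real-world covariate correlation (e.g. CKD with heart
  failure) is *not* modelled; `CohortSpec.copula_corr` switches on pairwise
  Gaussian-copula correlations when wanted.
* **Laboratory values** are drawn conditionally on the latent flags from
  truncated normal/lognormal distributions cut at the diagnostic threshold
  on the side the flag dictates (e.g. untreated diabetics get
  HbA1c ≥ 6.5 %, non-diabetics < 6.5 %; CKD subjects get a target eGFR
  inverted through the closed-form CKD-EPI 2009 inverse to a creatinine
  value, 80 % via eGFR < 60 and 20 % via albuminuria at preserved eGFR).
  This makes guideline phenotyping recover the latent flags exactly, so
  specified prevalences survive the raw-table → phenotype round trip. The
  distribution parameters are clinically plausible values for an elderly
  European population and live in `CohortSpec.lab_distributions`, not in
  code.
* **Outcomes** (default `outcome_mode="saf_first"`): silent AF is Bernoulli
  with `logit p = b0 + x·β_SAF`, where `β_SAF` are the published adjusted
  silent-AF log-odds-ratios (age/5y 1.36, male 2.58, stroke/TIA 1.59,
  DM 1.48, HF 2.06, CKD 1.39, NT-proBNP 2.37, …) and `b0` is calibrated by
  bisection so the mean predicted probability equals the 9.3 % target
  (tolerance far below the 0.002 contract). Symptomatic AF is then drawn
  among the remaining subjects from the overall-AF log-ORs, calibrated so
  total AF reaches 22.6 %. This mode makes the silent-AF effect sizes
  exactly the published ones — the property score derivation exercises, and
  the one the parameter-recovery tests verify. The alternative
  `"af_first"` mode draws overall AF first and then symptoms among AF
  subjects from a CHD/obesity/thyroid symptom model (the factors that
  predict overall but not silent AF), calibrated so the silent fraction of
  AF is 9.3/22.6 ≈ 41 %.
* **ECG episodes**: every AF-positive subject receives ≥ 1 episode of
  30 s + lognormal duration (plus optional sub-30-s extras); 8 % of
  AF-negative subjects receive only sub-30-s episodes so the > 30 s filter
  is genuinely exercised. Effective monitoring time is lognormal with
  median 23 d 10 h 26 min, truncated below at 12 min; episodes are placed
  uniformly within it. Symptoms occur in 5 % of AF-negative subjects
  (symptoms without detected AF classify as no-AF).

What the generator does **not** emulate: covariate correlation (see above),
within-subject episode clustering and circadian structure, missing data
(complete-case machinery exists but synthetic cohorts are complete),
survey-design clustering, and any ECG waveform content. Tests passing on
synthetic cohorts therefore validate the analysis machinery and its
calibration, not clinical transportability.

## Phenotyping

CKD-EPI 2009: `eGFR = 141·min(Scr/κ,1)^α·max(Scr/κ,1)^−1.209·0.993^age·1.018[female]`,
κ = 0.7/0.9 and α = −0.329/−0.411 (female/male); the race coefficient is
fixed at 1 for this population and exposed as config. Boundary semantics
are preserved exactly per flag: BP/HbA1c/ACR/BMI are `≥`, eGFR is `<`,
NT-proBNP and hsCRP are strict `>`, and the AF rule is strictly
"longer than 30 s", compared on the stored value without rounding.
Hypertension uses the mean over recorded measurements (the alternative —
requiring the criterion at each visit — is not distinguishable from the
published definition; the mean was chosen as the conventional reading).
Missing required labs exclude the subject with a per-field log.

## Association analysis

Wald inference throughout (matching the SPSS convention of the original
analysis): 2×2 ORs with `SE = sqrt(Σ 1/cell)` and Haldane 0.5-correction on
zero cells (flagged); Pearson χ² without continuity correction;
pooled-variance t-test for age (Welch by flag); multivariable logistic
regression via iteratively reweighted least squares (statsmodels GLM,
binomial family), which is Newton's method for the canonical logit link,
with convergence tolerance 1e−10 and a hard failure naming the offending
predictor on separation or rank deficiency. Poststratification weights are
cell ratios target/sample rescaled to mean 1 and enter fits as frequency
weights; they move point estimates only — design-based variance is out of
scope and outputs are labelled accordingly.

A selection subtlety worth knowing: the analysis contrast for silent AF
(silent vs no-AF, overt AF excluded) conditions on an outcome-correlated
event and therefore does *not* recover the generating silent-AF ORs from
synthetic data; the recovery tests fit the generating contrasts instead
(silent AF vs all; symptomatic AF within non-silent).

## Score derivation

`split_population` sorts ids, permutes with a seeded generator and takes
`round(2n/3)` for derivation (1742/871 at the study's 2613 eligible); the
primitive splits any n ≥ 2 while the derivation procedure refuses
populations under 10. Draw *d* of the five uses a child seed spawned from
`(seed, d)`, so the whole procedure is a pure function of (cohort, config).
"Sum of the rounded ORs" is operationalized as `round(mean OR across all
five draws)` per factor, half away from zero, floored at 1, applied only to
factors significant in ≥ 4 of 5 draws; others score 1. Averaging only the
significant draws is available as a config option and yields identical
points on the published per-draw table; both reproduce the published
assignment M2 R1 D1 A3 S2 H2 (max 11). The published table's summary row
prints 1 point for heart failure while the stated rule and the prose assign
2; the implementation follows the rule, and `points_override` reproduces
the 1-point variant when wanted.

## ROC evaluation

Candidate cutoffs are midpoints between consecutive distinct scores plus
sentinels (half-integers for an integer score); "screen positive" is
score **strictly greater** than the cutoff, so a 4.5 cutoff means scores
≥ 5 are positive. AUC is the trapezoid integral along descending cutoff
order, which equals tie-aware pair counting (`P(case > control) + ½P(tie)`)
to machine precision — both the equality and agreement with an independent
ROC implementation are enforced in tests. The AUC interval is DeLong's
(placement-value variance), chosen over the bootstrap for determinism;
the implementation matches an external reference implementation to 1e−10
on a frozen instance. The operating point minimizes
`sqrt((1−sens)² + (1−spec)²)` with ties broken toward the lower cutoff.
Per draw, the cutoff is selected on derivation data only and applied
unchanged to validation; an independently re-derived validation cutoff is
reported alongside for comparison, never used for the headline metrics.
Draws with a one-class subset or a constant score are flagged degenerate
and excluded from summary means.

## Problem sizes and determinism

Default analyses run at the study size n = 3014; calibration and
parameter-recovery checks use n = 50,000, where binomial sampling error is
well below the 10 % tolerance on odds ratios. The reproduction script
averages the five-draw mean derivation AUC over 10 independent cohort
replicates, reflecting that the quantity is a property of the generating
conditions rather than of one random cohort. Every random draw flows from
a single integer seed through `numpy.random.SeedSequence` spawning; equal
configs give byte-identical outputs.

## Known limitations

* Independent covariates compress the risk distribution relative to a real
  elderly population; with correlated comorbidities the achievable AUC
  would differ somewhat in either direction.
* The symptom-ascertainment process is not modelled; `symptomatic` is a
  given boolean, as in the source data.
* Weighted analyses provide point estimates only (no design-based SEs).
* The score comparison stubs (Framingham-style beta scaling, CHARGE-AF)
  are out of scope.
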