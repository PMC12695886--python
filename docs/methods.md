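# Methods

This note documents the models, parameter choices and limitations of the
`csf_nathist` pipeline in the order the stages run. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Synthetic cohort generator

The generator emulates the inputs of an untreated-MS CSF natural-history
study: a samples × somamers raw-RFU matrix with plate labels, a sample
table (diagnosis, treatment state, age at lumbar puncture, sex), a
per-visit clinical/imaging table, an nTPM cell-type expression table, a
GMT pathway file and an external age/sex reference list.

**Value model.** Log-RFU values are Gaussian (so raw RFUs are log-normal,
matching the multiplicative noise of fluorescence assays):

```
log RFU[s, j] = mu_j + a_j * age_s + g_j * male_s
             + sum_L beta_{jL} * latent_L(s) + c_j * G_{grp(j)}(patient)
             + b_{patient, j} + e_{s, j}
```

with `b ~ N(0, clin_sd^2)` a per-patient biological effect shared across
visits and `e ~ N(0, tech_sd^2)` visit-level technical noise. Defaults
`tech_sd = 0.5`, `clin_sd = 1.5` put a null somamer's signal-to-noise
ratio at `(1.5^2 + 0.5^2 vs 0.5^2)` ≈ 0.91, i.e. a clearly
high-signalling assay with a visible failure margin below the 0.8 gate.

**Latents.** Three per-visit latent variables drive both the clinical
table and the planted somamer effects, so cross-sectional associations and
composite outcomes are internally consistent: physical disability (the
CombiWISE generator, advancing by a per-patient slope drawn
`N(1.45, 1.2^2)` units/year — the mean matches the reported progression
rate of untreated cohorts), brain damage (atrophy/cognition: drives BPFr
down and SDMT down), and lesion activity (drives Poisson CEL counts, T2
lesion load and NEFL; highest in RRMS and declining with age). Healthy
controls sit at latent 0: their somamer variation is purely physiological
(age, sex, patient effect, technical noise).

**Study-condition defaults.** 40 HC patients (12 with a repeat visit),
100 patients per MS subtype with RRMS drawn youngest (ages ~N(35, 8) vs
~N(50–52, 9) for progressive subtypes; HC uniform 18–75), 500 somamers,
10 % age-associated (slope ±`effect_scale·clin_sd/30` per year — about one
biological SD across the age range), 6 % sex-associated
(±`effect_scale·clin_sd`), and 10 %/4 %/6 % loading on the
disability/brain-damage/lesion latents (±`effect_scale·clin_sd`). Half the
MS patients are longitudinal with 2–5 LPs 1.5–3 years apart plus
clinic-only visits; 90 % of first LPs are untreated and 40 % of patients
start a named therapy at a random later visit. Outliers (rate 0.001)
replace a value with `mu ± k·SD_total`, `k ∈ [5, 10]`, guaranteeing they
trip 1.5·IQR fences. Plate assignment keeps a patient's samples on one
plate; the additive plate effect defaults to 0 because plate calibration
is vendor-internal and modelled only as an optional stage. Two somamers
are designated the NEFL/NEFH aptamers (positive lesion loading) so the
lesion model's exclusion rule is exercised.

Cluster co-regulation factors `G` are drawn per *patient*, not per visit:
they represent biology, so they belong in the between-patient variance and
must not inflate the within-patient (technical) SD of longitudinal HC.
The loading `2·clin_sd` gives within-group pairwise |rho| ≈ 0.8 among
untreated MS, comfortably above the 0.7 seed threshold.

**What the generator does not emulate** (hence what passing tests do not
show about real data): aptamer cross-reactivity and epitope effects,
plate/hybridization chemistry, informative dropout in follow-up,
treatment effects on biomarkers (treatment changes labels, not values),
non-Gaussian heavy tails beyond the planted outliers, and realistic
correlation structure outside the planted pathway/cluster groups.

## Preprocessing

- Outlier fences default to Tukey form (Q1 − k·IQR, Q3 + k·IQR); a
  `center="median"` switch computes median ± k·IQR instead, since both
  conventions appear in the field. k = 1.5 flags HC values, k = 3 floors
  MS values. Quantiles use linear interpolation between order statistics.
- HC samples with > 15 % flagged somamers are dropped from the whole
  matrix; individual HC outlier values are otherwise left in place. MS
  outliers are floored, not removed — MS heterogeneity can be real, but
  unbounded extremes would dominate downstream OLS.
- Flooring is idempotent: clipped values lie inside fences recomputed on
  the clipped data.
- σ_tech comes from a dedicated profile-REML optimizer for the one-way
  random-intercept model (the restricted likelihood is profiled to the
  variance ratio and minimized on a bounded log grid, xatol 1e-10); the
  method-of-moments two-level ANOVA estimator is the fallback and the
  boundary behaviour (ratio → 0 collapses to the pooled variance). On
  balanced designs REML and ANOVA coincide, which the tests exploit as an
  oracle; statsmodels MixedLM is the independent cross-check on unbalanced
  designs. Negative moment estimates are truncated at zero so SNR stays in
  [0, 1].
- σ_clin uses untreated MS samples only. The SNR cutoff (default 0.8) is
  inclusive. Degenerate somamers (zero total variance) are flagged and
  treated as failed.

## Age/sex adjustment

- Sex is coded female = 0, male = 1; age is age at LP in years,
  continuous.
- Step 1 keeps a referenced covariate when its HC coefficient has
  unadjusted p ≤ 0.05 *and* the reference direction; retention is per
  covariate, and the retained design is refit alone so HC residuals are
  exact. Step 2 BH-adjusts the whole-model p-value of `value ~ age + sex`
  across the remaining somamers (the asymmetry — unadjusted step 1, FDR
  step 2 — is deliberate: the external reference supplies the prior).
- The scaling SD is computed on the *adjusted* HC values, which makes the
  HC mean-0/SD-1 contract exact on the fitting cohort (the acceptance
  script measures ~1e-16). MS samples never influence the fit.

## Outcomes

- CombiWISE weights are configuration: the published weights belong to an
  external instrument, so the default is a documented placeholder that
  inverts the synthetic generator's component model (weights
  4.29/0.36/1.07/1.43 for EDSS/SNRS/T25FW/9HPT with SNRS inverted,
  offset 5.71). Real-data use should supply the published weights.
- "Normalized" in GMSD is read as z-scoring over the analysis cohort
  (min–max available as an option). Brain damage is the PC1 of
  standardized BPFr and SDMT, sign-fixed to correlate negatively with
  BPFr; the PCA cohort is whatever table the caller passes (the pipeline
  uses all visits).
- SC disability is the OLS residual of CombiWISE on Brain damage (mean 0,
  orthogonal to Brain damage by construction).

## Association engine

- One OLS per somamer and outcome with outcome, sex and their interaction;
  the engine solves the shared-design normal equations once for all
  somamers and matches statsmodels to 1e-8 (tested).
- "Sex-affected" is operationalized as significant AND (sex p ≤ 0.05 OR
  interaction p ≤ 0.05); both sub-flags are stored so either reading can
  be recovered.
- The HLA genotype outcome is coded 0/1/2 risk-allele copies, linear; BMI
  is analysed continuously (a <30/≥30 split is a caller choice).
- Enrichment is a one-sided chi-squared without continuity correction:
  the two-sided p is halved when the observed in-set specific count
  exceeds expectation, folded otherwise; tests with zero expected counts
  are skipped and flagged.

## Lesion model

- The mixing grid `linspace(0, 1, 20)` includes both endpoints; the
  penalty path is log-spaced over two decades below the smallest
  all-zero penalty at each mixing value (floored at mixing 0.05 for the
  ridge end, where no finite all-zero penalty exists). CV folds are
  stratified by MS subtype and derived deterministically from the seed;
  the winning (mixing, penalty) pair minimizes pooled 10-fold MSE and the
  model is refit on the full training set. Features are standardized on
  the training cohort; CEL counts are left untransformed by default.
- Lin's CCC uses sample (ddof = 1) moments; the attenuation property
  |CCC| ≤ |r| holds for any consistent choice.
- The HC prediction gate fits predicted-CEL# on age over HC only and uses
  the standard OLS 95 % prediction interval; by construction ~2.5 % of HC
  exceed the upper bound.

## Pathways and clustering

- Scores are plain direction-weighted sums of HC-scaled members; with
  members aligned to a shared anchor, averaging reduces member-level noise
  and the pooled score correlates more strongly with the anchor than the
  median member (tested on the planted pathways).
- Zero or undefined anchor correlations default to +1 with a warning.
- The greedy accretion order is made deterministic: the candidate with the
  highest minimum |rho| to current members joins first; ties break by
  somamer ID. Membership requires |rho| ≥ 0.5 against members at admission
  time (the post-hoc complete-linkage check against the final cluster is
  available but admission-time is authoritative). Negative-rho members are
  admitted on |rho|; their scoring direction comes from the anchor.

## Stratification and matching

- Residuals inside [Q1, Q3] are dropped inclusively (boundary values are
  removed). The univariate propensity logit is affine in the covariate, so
  greedy nearest-neighbour matching on it is invariant to the fitted
  scale; on perfect separation the z-scored covariate is used as a
  monotone-equivalent score. 1:1 matching without replacement with a
  0.2-SD caliper keeps the paired t-test well-defined; a weighted
  full-matching mode was deliberately not implemented.
- Analytes with zero within-pair variance are skipped and flagged rather
  than assigned p-values.

## Longitudinal analyses

- All slopes are per-patient OLS of value against age (shift-invariant;
  exact on two points). The baseline-predictor analysis takes outcome
  slopes from every clinic visit at or after the first untreated LP
  (treated visits included — the outcome trajectory is observed under
  care as it happened); the slope-reflector analysis restricts to visits
  between the first and last LP inclusive.
- Anchor-slope outliers beyond ±3·IQR are removed before tertile
  assignment; tertiles are rank thirds with ties broken by patient ID
  (sizes differ by at most one). The default anchor outcome is CombiWISE.

## Pipeline

- A single global seed fans out per stage as
  `(seed·1000003 + crc32(stage)) mod 2^31`, so stages are independently
  reproducible and adding a stage never shifts another stage's stream.
- Every written file enters a SHA-256 manifest; two runs with identical
  config and seed produce identical manifests (tested end to end).
- Skipping a stage disables its dependents with an explicit note instead
  of running them on missing inputs.
- Problem sizes in the default run (500 somamers, ~750 samples, ~1200
  visits) were chosen as a faithful, desk-scale rendition of a
  thousand-sample cohort: large enough for the planted effects to be
  recovered at the stated thresholds, small enough that the full run and
  its tests complete in seconds to minutes.

## Known limitations

- The adjustment transfers HC-fitted physiology to MS samples; if disease
  alters the age slope itself, the residual carries that difference (by
  design, but worth remembering).
- The SNR gate treats any within-patient HC variation as technical,
  including true short-term biology.
- Elastic-net CV standardizes features on the full training cohort before
  fold splitting (a small optimism; support recovery is unaffected at the
  tested sizes).
- The cell-specificity rule is winner-takes-all; proteins with two strong
  source cell types are assigned to the larger one.
- Greedy clustering is order-deterministic but not globally optimal; it is
  validated against exhaustive re-derivation only at small variable
  counts.
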