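# Methods

`radpet` re-implements, as a tested pipeline, a whole-body PET-CT radiomics
analysis for predicting treatment response and progression-free survival
(PFS) under first-line checkpoint-inhibitor therapy in advanced NSCLC. The
original study's images and per-patient feature values were never deposited,
so the pipeline is driven by a synthetic phantom-cohort generator whose
statistical structure matches what the analysis assumes. This note documents
the models, the conventions chosen where the source analysis was silent, the
problem sizes used in the verification studies, and what those studies do and
do not demonstrate.

## Phantom cohort model

Each patient is a paired PET (SUV-valued) and low-dose CT (HU-valued) volume
on the same grid (default 64 x 64 x 48 voxels at 4 x 4 x 4 mm, a PET-like
resolution small enough for desk-scale runs), with:

* **Liver reference region** — a fixed ellipsoid (~2,300 voxels) with voxel
  values Normal(`liver_mean_suv` = 2.0, `liver_sd_suv` = 0.25). The implied
  PERCIST-style threshold is 1.5 x 2.0 + 2 x 0.25 = 3.5 SUV, a typical
  clinical value.
* **Background** — Normal(`background_suv` = 0.8, 0.1), clipped positive.
* **Lesions** — one to four random ellipsoids (semi-axes 2–4.5 voxels) placed
  away from the liver, with a bounded retry loop. Each patient carries two
  latent lesion-intensity parameters drawn uniformly: the **median**
  (6–12 SUV) and the **skewness** (0.1–2.5). Intensities for the union of all
  lesion voxels are drawn from a shifted gamma whose shape is fixed by the
  closed form skewness = 2/sqrt(shape) (mirrored gamma for negative targets,
  normal limit below |skew| = 1e-3), scaled to spread `lesion_sigma_suv` =
  0.8 SUV, and shifted so the empirical median equals the latent median
  exactly. The closed form lets tests verify the sampler against an analytic
  oracle. Config validation enforces a 3-sigma margin between the lowest
  lesion median and the implied threshold, with a runtime clip as a belt, so
  PERCIST segmentation provably recovers every planted voxel.
* **Lesion rim and readers** — the painted FDG-avid region is the lesion
  core plus a one-voxel halo, all above threshold. Reader 1 keeps the core
  and a random half of the halo; reader 2 starts from reader 1 and re-edits
  the halo for `reader2_perturb_iters` rounds (each round randomly flips 20%
  of halo voxels: partial dilation/erosion). This emulates two readers who
  manually adjust the *same* threshold-defined volume and differ only at the
  partial-volume rim — mean Dice is 1.0 / 0.94 / 0.90 / 0.86 at 0/1/2/4
  rounds, decreasing monotonically, and intensity statistics stay
  reader-stable while rim-sensitive features vary. An earlier design that
  applied whole-mask dilation/erosion rounds produced Dice ~0.4 and polluted
  reader-2 intensities with flat-background voxels, which destroyed the
  skewness statistic for both readers equally — unrealistic for manual rim
  adjustment and abandoned for that reason.
* **CT** — a smoothed Gaussian HU texture (soft-tissue offsets in liver and
  tumor) that deliberately carries **no outcome signal**, matching the null
  CT finding of the clinical study.

### Outcome links

With latent skewness *s* and median *m*:

* **Response**: P(non-responder) = logistic(beta0 + beta_skew * s +
  beta_median * m), defaults beta0 = -3.5, beta_skew = 3.0, beta_median =
  -0.25. Non-responders are RECIST PD; responders draw CR/PR/SD in the
  reference cohort's proportions (1:17:15).
* **PFS**: Weibull proportional hazards, shape 1.2, base scale 2.8 months,
  log hazard gamma_skew * s + gamma_median * m with defaults 0.7 and -0.30.
  Censoring at min(24 months, an administrative follow-up time drawn uniform
  over 6–57 months). The overall-progression flag is the PFS event
  indicator.
* **TPS group**: multinomial with the reference proportions 21/44, 13/44,
  10/44, independent of outcome.

The directions (higher skewness and lower median -> worse outcome) mirror
the clinical report. Because no per-patient feature values were published,
the effect sizes are free parameters; they were calibrated once, at the
tabular level before the pipeline was assembled, to a clear-signal regime:
non-responder rate ~0.28 (clinical: 0.25), univariate skewness AUC ~0.88,
event rate ~0.70 (clinical: 0.75), median PFS ~7.6 months (clinical: 8).
The clinical AUCs (0.69/0.75) are *not* targeted: with unknown real effect
sizes, the generator aims for unambiguous recovery, not calibration to
numbers that cannot be checked without the original images.

One simplification worth noting: given the latent covariates, the response
label and the PFS time are drawn independently, whereas clinically PD at
second follow-up *is* a PFS event. Both outcomes share the same latent
drivers, which is all the selection and survival stages need.

Determinism: one global seed fans out to per-patient substreams
(seed + patient index), so cohorts are extensible without rewriting earlier
patients; a fixed draw order inside each patient makes cohorts bit-identical
under a fixed seed.

## Segmentation

Threshold T = 1.5 x mean liver SUV + 2 x SD (sample SD, n-1 denominator; the
PERCIST literature does not state one). Voxel inclusion is SUV >= T (ties
kept). Physiological uptake removal is modeled by exclusion masks (the liver
mask in the pipeline). Connected components use 26-neighbourhood; components
below `min_voxels` = 2 are dropped. An empty result raises a no-tumor error
and the patient is excluded with a log entry. Label maps transfer to the CT
grid as identity when grids coincide, otherwise by nearest-neighbour
resampling (grids must cover the same physical extent).

## Feature catalog (84 per modality)

The source analysis reports "36 first-order and 48 GLCM features" per
modality without enumerating them. **The catalog here is a reconstruction**,
with IBSI-style definitions, fixed so the counts match and the two reported
predictive features exist by name (`PET-Skewness`, `PET-Median`):

* 12 shape/size (voxel count, volume, mesh surface area, surface/volume,
  compactness 1 and 2, spherical disproportion, sphericity, maximum 3-D
  diameter, three PCA axis lengths) + 24 first-order intensity statistics
  = 36;
* 24 GLCM statistics x 2 offset distances (1 and 2 voxels) = 48.

Conventions (the source is silent on all of them):

* discretization: equal-width bins over the masked range, default 64 bins,
  top value maps to the top bin, constant regions map to bin 1;
* skewness/kurtosis: population moment ratios (kurtosis non-excess);
  zero-variance regions return 0 by convention; percentiles use linear
  interpolation;
* GLCM: symmetric pair counting, matrices averaged (unweighted) over the 13
  unique 3-D directions per distance — making direction-averaged features
  invariant to 90-degree rotations — logs base 2, undefined statistics of
  degenerate matrices (correlation, IMC1/2) return 0;
* surface area comes from a marching-cubes mesh of the padded mask, not from
  counting exposed voxel faces: face counting overestimates smooth surfaces
  by a factor approaching 1.5 (staircase bias), which would cap the
  sphericity of a digital ball near 2/3 instead of approaching 1. The mesh
  area of a single voxel is the octahedron through its face centers,
  sqrt(3) x spacing^2;
* features are computed on the union of all lesions (total tumor burden),
  never per lesion and never averaged across lesions.

Features are extracted twice (once per reader mask) for both modalities; the
CT block reuses the transferred mask, so the shape features duplicate across
modalities by construction — kept, as the 84-per-modality count requires it.

## Reliability filter

Lin's concordance correlation coefficient with population (n) denominators,
CCC = 2 cov(x, y) / (var x + var y + (mean x - mean y)^2), per feature across
patients; features with CCC >= 0.8 ("excellent") are kept and merged as the
arithmetic mean of the two readers. Degenerate conventions: identical
constants -> 1, otherwise zero covariance with zero denominator -> 0.

## Normalization, split, selection

* **Normalization**: per-feature z-score followed by min-max to [0, 1],
  fit on training rows only and reapplied (never refit) to test rows, which
  may therefore fall slightly outside [0, 1]. The composition resolves the
  internally inconsistent prescription "z-scores normalized to a range
  between 0 and 1" (z-scores are unbounded). Constant features are dropped
  with a warning.
* **Split**: 70/30, stratified by the outcome label ("balanced" is read as
  outcome-stratified); within each stratum round(0.7 n) patients train.
* **Boruta**: each iteration appends column-wise permuted shadow copies,
  fits a random forest (mean-decrease-in-impurity importance; permutation
  importance behind a flag), and scores a hit when a real feature beats the
  best shadow. Two-sided binomial tests against a fair coin decide features:
  confirmation/rejection at per-tail level alpha / (2 x #features), with the
  Bonferroni denominator held at the full feature count throughout (letting
  it shrink as features are rejected inflates false confirmation sharply).
  Features still tentative at `max_iter` are *reported* as tentative; a
  median-importance rough fix is computed separately
  (`resolved_decision_`) and folded in only on request, because the rough
  fix systematically confirms noise features that happen to correlate with
  the outcome in-sample (see Calibration below). The pipeline's signature
  uses binomially confirmed features only.
* **Correlation pruning**: among confirmed features, visit by decreasing
  median Boruta importance (name ascending on ties) and drop any candidate
  with |Pearson r| >= 0.8 against an already-kept feature. Verified against
  a brute-force greedy oracle.

Both analysis targets — response at second follow-up, and overall
progression — get their own split, selection and models. alpha = 0.01 and
r_max = 0.8 are package defaults, both config-exposed.

## Response model and cutpoints

Univariate logistic models per signature feature are the primary reported
objects (the clinical study reported per-feature AUCs); the multivariate
model is fitted alongside. Logistic fits use IRLS with a tiny ridge
(1e-6), escalating the penalty and flagging the fit when separation drives
coefficients beyond +/-30. Fitting is on training rows; AUC and cutpoints
are evaluated on held-out test rows (the source text's "fit on the test
set" wording would leak and is read as ambiguity). The positive class is
the adverse outcome, so higher score = worse.

ROC uses the tie-corrected Mann-Whitney rank estimator; the curve scans all
unique scores under the rule score >= t -> positive. Youden's J = max(sens +
spec - 1), ties broken toward higher sensitivity then lower threshold.
Univariate cutpoints are mapped back to the normalized [0, 1] feature scale
(orientation by the sign of the coefficient, with the risk side reported),
consistent with the clinical cutoffs (0.2014, 0.5233) living in [0, 1].

## Survival

Kaplan-Meier, Mantel-Cox log-rank and Cox proportional hazards are delegated
to lifelines (Efron tie handling — months-resolution PFS ties often; Wald
95% CIs). The stratified Cox variant is exposed through a `strata` argument;
the default dichotomized analyses run unstratified, with the low-risk group
(below the Youden cut for a positively-oriented feature, above it otherwise)
as the exposure, so a protective level yields HR < 1. Non-convergence
(monotone likelihood) is flagged and retried with a small penalty. TPS
subgroup runs re-execute the same code path on the subset; degenerate
subgroup splits are recorded and skipped.

## Verification studies and problem sizes

All studies are seeded and live in `radpet.studies`; the acceptance script
re-runs them from scratch.

* **Log-rank type-I error**: 1,000 replicates, Exp(1) in both arms, n =
  50/arm, no censoring; rejection rate at p < 0.05 lands in [0.03, 0.07].
* **Cox CI coverage**: 500 replicates, Weibull PH with true HR 0.5, balanced
  binary covariate, n = 150, administrative censoring at the 80th
  percentile; Wald 95% CI coverage lands in [0.92, 0.98].
* **Boruta null**: 50 runs, n = 200, 10 iid Normal features, random binary
  labels, alpha = 0.01, 100 trees, 20-iteration budget. Zero features are
  confirmed in roughly 90–94% of runs (seed-dependent). The residual
  confirmations are *not* a bug in the decision rule: about 7% of pure-noise
  datasets at n = 200 contain a feature whose in-sample correlation with the
  labels (|r| ~ 0.2, nominal p ~ 0.005) lets it beat the best of ten shadows
  in ~90% of iterations. Boruta's all-relevant semantics — relevance means
  "more informative than its own permuted copy for *this* sample" —
  eventually confirm such features under any consistent rule, and making the
  rule strict enough to suppress them (e.g. Bonferroni over iterations as
  well as features) measurably destroys power to confirm the true skewness
  signal in the 168-feature recovery problem, whose sustained hit rate is
  only ~0.8 because importance spreads across many correlated informative
  features. The per-iteration rule at alpha/(2m) with m fixed at the full
  feature count is the best calibrated rule found that retains that power;
  the remaining few-percent false-confirmation rate is an inherent property
  of shadow-max Boruta at this sample size, not removable by tuning.
* **End-to-end recovery**: 25 seeds; each run simulates a strong-effect
  cohort of n = 300 (study grid 48 x 48 x 36 — only empty background is
  smaller than the default grid; lesion and liver geometry are unchanged),
  then runs segmentation, dual-reader extraction, CCC filtering, 70/30
  split, Boruta (120 trees, 50 iterations) and pruning for the response
  target. `PET-Skewness` is confirmed in >= 80% of seeds; its held-out
  univariate AUC has median ~0.88; dichotomizing all patients at the Youden
  cut gives a low-skewness hazard ratio with median ~0.5 and a CI excluding
  1 in most seeds — reproducing the qualitative direction of the clinical
  finding (protective low skewness; clinical HR 0.17).

Tree counts and iteration budgets in the studies are compute-scaled versions
of the selector defaults (500 trees, 100 iterations); the statistical
parameters (alpha, cutoffs, sample sizes of the stated designs) are not
scaled.

## What the phantoms do not emulate

No scanner point-spread function, reconstruction noise texture, partial-
volume blur, respiratory motion, or anatomically realistic organ context;
lesions have crisp boundaries and spatially unstructured intensities, so
texture features carry less independent information than in real FDG-PET.
Passing tests therefore demonstrate that the pipeline's logic — thresholding,
feature mathematics, reliability filtering, leakage-free selection and
modelling, survival analysis — is correct and recovers known signal, not
that the specific clinical effect sizes or the published AUCs/HRs would be
reproduced on patient data. The default-size cohort (n = 44) frequently
yields an empty signature under the strict selector: at 31 training samples
against ~160 features, that is the statistically honest outcome, and it is
why the recovery study uses n = 300.

## Known limitations

* The feature catalog is a reconstruction; numerical values will not match
  any specific radiomics package bin-for-bin (binning, aggregation and log
  bases differ across tools).
* The progression target's signal (median-driven, AUC ~0.72 at the tabular
  level) is weaker than the response target's by design; at moderate cohort
  sizes the selector often confirms nothing for it.
* Lost-to-follow-up censoring is emulated only through the administrative
  accrual window; no competing risks.
* The Cox "stratified" variant is exposed but unused by default, as the
  source analysis does not name its strata.
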