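# radpet

Whole-body PET-CT radiomics for predicting treatment response and
progression-free survival (PFS) under first-line checkpoint-inhibitor
therapy in advanced non-small-cell lung cancer — re-implemented as a tested,
reusable Python pipeline, driven by a synthetic phantom-cohort generator in
place of the original (undeposited) patient images.

It is aimed at researchers who want to study or extend this class of
analysis — PERCIST-style segmentation, dual-reader radiomics, reliability
filtering, all-relevant feature selection, cutpoint-based survival analysis
— with every stage unit-tested against independent oracles and a known
ground truth to recover.

## The analysis

1. **Segmentation.** The FDG-positive tumor volume is delineated on PET with
   the liver-referenced threshold

       T = 1.5 * mean(SUV_liver) + 2 * SD(SUV_liver),

   physiological uptake removed via exclusion masks, small components
   dropped, and the label map transferred to the CT grid.
2. **Features.** 84 features per modality from the union of all lesions:
   12 shape + 24 first-order intensity statistics (36) + 24 gray-level
   co-occurrence (GLCM) statistics at offset distances {1, 2} voxels (48).
   Two readers' masks give two extractions per modality.
3. **Reliability.** Lin's concordance correlation coefficient per feature
   across readers,

       CCC = 2 cov(x, y) / (var x + var y + (mean x - mean y)^2),

   keeping features with CCC >= 0.8 and merging readers by mean.
4. **Selection.** Features are z-scored and min-max normalized to [0, 1]
   (fit on the training rows of an outcome-stratified 70/30 split), reduced
   by Boruta (random-forest importance vs permuted shadow features, binomial
   hit tests at alpha = 0.01), and pruned at |Pearson r| >= 0.8.
5. **Models.** Univariate logistic models per selected feature (and the
   multivariate model), evaluated on the held-out test rows by ROC/AUC, with
   the operating cutpoint from Youden's J = max(sensitivity + specificity - 1)
   on the normalized feature scale.
6. **Survival.** Patients dichotomized at the cutpoint: Kaplan-Meier curves,
   Mantel-Cox log-rank, and Cox proportional-hazards HR with 95% CI for the
   low-risk group, overall and within PD-L1 TPS subgroups.

The synthetic generator plants a known signal for the pipeline to recover:
each phantom's lesion intensities have a latent median and skewness (shifted
gamma with closed-form skewness), linked to non-response through a logistic
model and to PFS through Weibull proportional hazards, with two correlated
reader masks and a liver reference region. Higher skewness and lower median
mean worse outcome, the direction reported clinically. See
`docs/methods.md` for every convention and default.

## Worked example

Run the whole pipeline on a simulated 200-patient cohort:

```bash
radpet run-all --seed 7 --n-patients 200 --out runs/demo
```

prints

```
response: signature ['PET-MedianAbsoluteDeviation', 'PET-GLCM-SumAverage-d1', 'PET-GLCM-MaximumProbability-d2']
progression: signature []
report written to runs/demo/report.json
```

and `report.json` records, for the response target (non-responder = positive
class), the per-feature test-set models

| feature | test AUC | Youden cutpoint | high-risk side |
|---|---|---|---|
| PET-MedianAbsoluteDeviation | 0.838 | 0.496 | below |
| PET-GLCM-SumAverage-d1      | 0.889 | 0.216 | below |
| PET-GLCM-MaximumProbability-d2 | 0.841 | 0.114 | above |

(multivariate AUC 0.882) and the dichotomized PFS analyses, e.g. for
PET-MedianAbsoluteDeviation: low-risk-group HR 0.48 (95% CI 0.35–0.67),
log-rank p = 8.8e-06 — patients on the favourable side of the cutpoint
progress later, with TPS-subgroup re-runs alongside.

Interpretation: the generator links *lower* lesion-intensity median and
*higher* skewness to worse outcome, so dispersion- and intensity-level
features dominate the selected signature; AUCs near 0.85 reflect the
generator's deliberately clear signal, and HR < 1 for the low-risk group
reproduces the qualitative clinical finding. The empty progression signature
is honest behaviour: that target's planted signal is weaker, and the
selector does not confirm features it cannot distinguish from shadows. At
the clinical cohort size (n = 44, the default), the signature is usually
empty for both targets — 31 training patients against ~160 features is below
this selector's power.

Individual stages are also exposed (`radpet simulate | segment | extract |
filter | select | model | survive`), reading and writing NIfTI, CSV and
JSON, and the same operations are importable from `radpet` as a library.

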