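# lungrisk

External validation and updating of cardiopulmonary-morbidity risk models
for anatomic lung resection.

## The problem

Before lung-cancer surgery, clinicians want a calibrated estimate of the
probability of a postoperative cardiopulmonary complication (pneumonia,
prolonged air leak, arrhythmia, …, as defined by the European Society of
Thoracic Surgeons). Several published risk scores exist — the logit and
aggregate forms of Eurolung1 (2016E1, 2019E1, aE1), the Brunelli model and
the Age-adjusted Charlson Comorbidity Index (ACCI) — but a score developed
in one population usually drifts when applied in another: its ranking of
patients (discrimination) may survive while its absolute probabilities
(calibration) do not. `lungrisk` implements the full external-validation
and model-updating workflow for this setting, aimed at clinical
biostatisticians validating risk scores on their own cohort tables.

## What it computes

For a logistic score with linear predictor
`LP = β₀ + Σ βᵢxᵢ` and risk `p = 1/(1+e^(−LP))`, and for integer-point
aggregate scores, the package provides:

- **Scoring** from JSON model registries (the five models above ship as
  data; a registry edit, not a code change, fixes a coefficient).
- **Discrimination**: AUC as the Mann–Whitney statistic with 95% CI by the
  DeLong method (seeded bootstrap optional).
- **Calibration**: Hosmer–Lemeshow test with the adaptive group count
  `g = max[10, min(m/2, (n−m)/2, 2 + 8n²/10⁶)]` (floored; g = 10 outside
  1000 < n ≤ 25000), plus the weak-calibration slope/intercept from a
  logistic fit of outcomes on logit(p) and a decile calibration curve.
- **Threshold metrics** at the Youden index J = sensitivity + specificity − 1:
  sensitivity, specificity, PPV, NPV, accuracy.
- **Updating** (logistic models only), as scikit-learn estimators:
  recalibration-in-the-large (`InterceptRecalibrator`), logistic
  recalibration (`LogisticRecalibrator`, new LP = α + β·LP_old) and full
  revision (`ModelRevision`). The first two are monotone transforms and
  provably leave the AUC unchanged.
- **Spirometry covariates**: percent-of-predicted FEV1/FVC from banded
  reference equations (with linear extrapolation of the parameters past
  the oldest tabulated age band) and segment-counted ppoFEV1%.
- **Synthetic cohorts**: a seeded generator matching the marginals of a
  1085-patient Chinese resection cohort (age 60 [52–65], 38.99% male,
  ppoFEV1% 76 [68–86], 97.7% VATS, ESTS event rate 91/1085), with
  configurable true model and a three-step inclusion/exclusion filter.

## Worked example

```sh
lungrisk simulate --n 20000 --seed 42 --out cohort.csv
lungrisk validate --cohort cohort.csv --out reports --format tsv
lungrisk update --cohort cohort.csv --model 2016E1 --out updated
```

The validation table (`reports/performance_table.tsv`) on this synthetic
cohort prints:

```
        2016E1   2019E1   Brunelli  aE1      ACCI
AUC     0.621    0.617    0.563     0.595    0.566
95% CI  0.607-0.635  0.603-0.630  0.548-0.577  0.581-0.608  0.552-0.579
Goodness-of-fit test (P value)  0.000  0.005  0.002  -  -
Sensitivity  0.622  0.591  0.690  0.398  0.330
Specificity  0.573  0.597  0.401  0.735  0.761
PPV     0.118    0.119    0.096     0.122    0.113
NPV     0.943    0.941    0.934     0.930    0.925
Accuracy 0.577   0.597    0.426     0.707    0.725
```

Read: every model ranks events above non-events only modestly better than
chance here (AUC ≈ 0.56–0.62 — the generator draws covariates
independently, which weakens the signal a real cohort would carry), and
the logistic models are miscalibrated (HL p < 0.05) because the cohort's
8.4% event rate is below the ~11.6% the original 2016E1 intercept implies.
Aggregate models get no HL/calibration row — those diagnostics need
probability outputs. Updating repairs exactly that drift
(`updated/updating_2016E1.tsv`):

```
                  Original  Method 1  Method 2  Method 3
age                  0.026     0.026     0.026     0.026
male_sex             0.497     0.497     0.503     0.538
ppo_fev1_percent    -0.015    -0.015    -0.015    -0.014
thoracotomy          0.497     0.497     0.503     0.474
extended_resection   0.514     0.514     0.521     0.413
cad                  0.231     0.231     0.234     0.326
cvd                  0.371     0.371     0.376     0.299
ckd                  0.152     0.152     0.154     0.012
Intercept           -2.465    -3.111    -3.121    -3.246
```

Method 1 moves only the intercept (−2.465 → −3.111, absorbing the
event-rate gap); method 2 additionally scales every coefficient by the
common calibration slope (here ≈ 1.012); method 3 refits everything. After
any method the mean predicted risk equals the observed event rate exactly
(the intercept score equation), and methods 1–2 keep the AUC bit-for-bit.

The same flow runs on a real cohort CSV with columns
`age, sex, bmi, fev1_percent, fvc_percent, ppo_fev1_percent, cad, cvd,
ckd, copd, diabetes, …, approach, resection, extended_resection,
complication_ests, increased_pleural_effusion` (see
`lungrisk.cohort.ESSENTIAL_COLUMNS`; records with missing essential data
are excluded, never imputed).

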