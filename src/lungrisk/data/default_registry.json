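[
  {
    "name": "2016E1",
    "family": "logistic",
    "intercept": -2.465,
    "coefficients": {
      "age": 0.026,
      "male_sex": 0.497,
      "ppo_fev1_percent": -0.015,
      "thoracotomy": 0.497,
      "extended_resection": 0.514,
      "cad": 0.231,
      "cvd": 0.371,
      "ckd": 0.152
    },
    "coding": {
      "age": {"kind": "numeric", "source": "age"},
      "male_sex": {"kind": "equals", "source": "sex", "value": "male"},
      "ppo_fev1_percent": {"kind": "numeric", "source": "ppo_fev1_percent"},
      "thoracotomy": {"kind": "equals", "source": "approach", "value": "thoracotomy"},
      "extended_resection": {"kind": "flag", "source": "extended_resection"},
      "cad": {"kind": "flag", "source": "cad"},
      "cvd": {"kind": "flag", "source": "cvd"},
      "ckd": {"kind": "flag", "source": "ckd"}
    },
    "provenance": "Logit form of Eurolung1 (Brunelli et al. 2017, ESTS database); coefficient set as republished in the validation study's updating table ('Original' column)."
  },
  {
    "name": "2019E1",
    "family": "logistic",
    "intercept": -2.852,
    "coefficients": {
      "age": 0.021,
      "male_sex": 0.472,
      "ppo_fev1_percent": -0.015,
      "thoracotomy": 0.662
    },
    "coding": {
      "age": {"kind": "numeric", "source": "age"},
      "male_sex": {"kind": "equals", "source": "sex", "value": "male"},
      "ppo_fev1_percent": {"kind": "numeric", "source": "ppo_fev1_percent"},
      "thoracotomy": {"kind": "equals", "source": "approach", "value": "thoracotomy"}
    },
    "provenance": "Parsimonious Eurolung1 (Brunelli et al. 2019 update). UNVERIFIED transcription from the source publication, not from a primary document; replace from the original table before clinical use."
  },
  {
    "name": "Brunelli",
    "family": "logistic",
    "intercept": -2.93,
    "coefficients": {
      "age": 0.035,
      "fvc_percent": -0.014,
      "extended_resection": 0.9,
      "cardiac_comorbidity": 0.73
    },
    "coding": {
      "age": {"kind": "numeric", "source": "age"},
      "fvc_percent": {"kind": "numeric", "source": "fvc_percent"},
      "extended_resection": {"kind": "flag", "source": "extended_resection"},
      "cardiac_comorbidity": {"kind": "flag", "source": "cad"}
    },
    "provenance": "Brunelli et al. 2006 cardiopulmonary-morbidity model (age, FVC%, extended resection, cardiac comorbidity). UNVERIFIED transcription; replace from the original table before clinical use."
  },
  {
    "name": "aE1",
    "family": "aggregate",
    "coefficients": {
      "male_sex": 1,
      "age_over_65": 1,
      "ppo_fev1_below_70": 1,
      "thoracotomy": 2
    },
    "coding": {
      "male_sex": {"kind": "equals", "source": "sex", "value": "male"},
      "age_over_65": {"kind": "threshold", "source": "age", "op": "gt", "value": 65},
      "ppo_fev1_below_70": {"kind": "threshold", "source": "ppo_fev1_percent", "op": "lt", "value": 70},
      "thoracotomy": {"kind": "equals", "source": "approach", "value": "thoracotomy"}
    },
    "provenance": "Aggregate form of Eurolung1 (Brunelli et al. 2019), integer points over dichotomized predictors. UNVERIFIED transcription; replace from the original table before clinical use."
  },
  {
    "name": "ACCI",
    "family": "aggregate",
    "coefficients": {
      "age_50_59": 1,
      "age_60_69": 2,
      "age_70_79": 3,
      "age_80_plus": 4,
      "cad": 1,
      "cvd": 1,
      "copd": 1,
      "diabetes": 1,
      "ckd": 2
    },
    "coding": {
      "age_50_59": {"kind": "band", "source": "age", "low": 50, "high": 59},
      "age_60_69": {"kind": "band", "source": "age", "low": 60, "high": 69},
      "age_70_79": {"kind": "band", "source": "age", "low": 70, "high": 79},
      "age_80_plus": {"kind": "band", "source": "age", "low": 80, "high": 200},
      "cad": {"kind": "flag", "source": "cad"},
      "cvd": {"kind": "flag", "source": "cvd"},
      "copd": {"kind": "flag", "source": "copd"},
      "diabetes": {"kind": "flag", "source": "diabetes"},
      "ckd": {"kind": "flag", "source": "ckd"}
    },
    "provenance": "Age-adjusted Charlson Comorbidity Index: original Charlson weights (myocardial/coronary disease 1, cerebrovascular disease 1, COPD 1, uncomplicated diabetes 1, renal disease 2) plus 1 point per decade from 50-59 to >=80; restricted to the comorbidities captured in the cohort schema."
  }
]
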