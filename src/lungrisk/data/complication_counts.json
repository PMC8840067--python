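{
  "denominator": 1085,
  "ests_defined": {
    "prolonged_mechanical_ventilation": 2,
    "pneumonia": 5,
    "atelectasis": 4,
    "empyema": 2,
    "chylothorax": 7,
    "respiratory_failure": 2,
    "pulmonary_embolism": 1,
    "arrhythmia": 2,
    "acute_myocardial_infarction": 3,
    "acute_kidney_injury": 1,
    "prolonged_air_leak": 61,
    "postoperative_bleeding": 1
  },
  "other": {
    "increased_pleural_effusion": 94
  }
}
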