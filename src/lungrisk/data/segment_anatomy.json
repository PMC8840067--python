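{
  "total_functional_segments": 19,
  "lobe_segments": {
    "RUL": 3,
    "RML": 2,
    "RLL": 5,
    "LUL": 5,
    "LLL": 4
  },
  "resection_segments": {
    "segmentectomy": 2,
    "lobectomy": 4,
    "bilobectomy": 7,
    "pneumonectomy": 10
  }
}
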