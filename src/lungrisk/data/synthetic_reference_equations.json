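{
  "synthetic": true,
  "note": "Synthetic stand-in for a sex- and age-band-stratified spirometry reference-equation table (predicted litres = const + height*height_cm + age*age_years per band). Values are physiologically plausible but are NOT the published Chinese reference equations; replace with a transcription of the published table for real analyses.",
  "age_min": 18,
  "age_max": 81,
  "measures": {
    "fev1": {
      "male": [
        {"age_lo": 18, "age_hi": 40, "const": -1.60, "height": 0.0350, "age": -0.0120},
        {"age_lo": 41, "age_hi": 50, "const": -1.70, "height": 0.0355, "age": -0.0135},
        {"age_lo": 51, "age_hi": 60, "const": -1.80, "height": 0.0360, "age": -0.0150},
        {"age_lo": 61, "age_hi": 70, "const": -1.90, "height": 0.0365, "age": -0.0165},
        {"age_lo": 71, "age_hi": 81, "const": -2.00, "height": 0.0370, "age": -0.0180}
      ],
      "female": [
        {"age_lo": 18, "age_hi": 40, "const": -1.20, "height": 0.0280, "age": -0.0100},
        {"age_lo": 41, "age_hi": 50, "const": -1.28, "height": 0.0284, "age": -0.0112},
        {"age_lo": 51, "age_hi": 60, "const": -1.36, "height": 0.0288, "age": -0.0124},
        {"age_lo": 61, "age_hi": 70, "const": -1.44, "height": 0.0292, "age": -0.0136},
        {"age_lo": 71, "age_hi": 81, "const": -1.52, "height": 0.0296, "age": -0.0148}
      ]
    },
    "fvc": {
      "male": [
        {"age_lo": 18, "age_hi": 40, "const": -2.10, "height": 0.0430, "age": -0.0110},
        {"age_lo": 41, "age_hi": 50, "const": -2.20, "height": 0.0435, "age": -0.0122},
        {"age_lo": 51, "age_hi": 60, "const": -2.30, "height": 0.0440, "age": -0.0134},
        {"age_lo": 61, "age_hi": 70, "const": -2.40, "height": 0.0445, "age": -0.0146},
        {"age_lo": 71, "age_hi": 81, "const": -2.50, "height": 0.0450, "age": -0.0158}
      ],
      "female": [
        {"age_lo": 18, "age_hi": 40, "const": -1.60, "height": 0.0340, "age": -0.0090},
        {"age_lo": 41, "age_hi": 50, "const": -1.67, "height": 0.0343, "age": -0.0100},
        {"age_lo": 51, "age_hi": 60, "const": -1.74, "height": 0.0346, "age": -0.0110},
        {"age_lo": 61, "age_hi": 70, "const": -1.81, "height": 0.0349, "age": -0.0120},
        {"age_lo": 71, "age_hi": 81, "const": -1.88, "height": 0.0352, "age": -0.0130}
      ]
    }
  }
}
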