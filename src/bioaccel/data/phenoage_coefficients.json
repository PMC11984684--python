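{
  "version": "1.0",
  "description": "Published PhenoAge coefficients (Gompertz mortality model on nine clinical biomarkers plus chronological age). Weights apply to values in the coefficient-native units listed under 'units'; CRP enters on the natural-log scale.",
  "intercept": -19.90667,
  "weights": {
    "albumin": -0.03359,
    "creatinine": 0.00951,
    "glucose": 0.19532,
    "log_crp": 0.09537,
    "lymphocyte_pct": -0.012,
    "mcv": 0.02676,
    "rdw": 0.33062,
    "alkaline_phosphatase": 0.00187,
    "wbc": 0.05542,
    "age": 0.08035
  },
  "gamma": 0.007692696,
  "horizon_months": 120,
  "outer": {
    "offset": 141.50225,
    "scale": -0.0055305,
    "denominator": 0.090165,
    "denominator_alt": 0.09165
  },
  "units": {
    "albumin": "g/L",
    "creatinine": "umol/L",
    "glucose": "mmol/L",
    "crp": "mg/dL (natural log taken)",
    "lymphocyte_pct": "%",
    "mcv": "fL",
    "rdw": "%",
    "alkaline_phosphatase": "U/L",
    "wbc": "1000 cells/uL",
    "age": "years"
  },
  "sha256": "458df9ee1bd9707d5b2192dac052e73e8de06d1c92cbb458f9c40a722561638a"
}
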