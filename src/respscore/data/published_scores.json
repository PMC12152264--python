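{
  "_comment": "Published clinical-practice response scores (training set, N=1152) with responder thresholds equal to the log of the whole-group HR per outcome. Disease-duration logs are base 10. Two reconciliations against the printed worked examples: the EDSS relapse coefficient is stored as +0.05 (the printed table shows -0.05, which does not reproduce either worked patient), and the SDMT disease-duration coefficient is stored as -0.15 (the running text shows -0.19, which does not reproduce the worked scores).",
  "EDSS": {
    "intercept": -1.23,
    "coefficients": {"age": 0.01, "edss": 0.08, "relapses_2y": 0.05},
    "threshold_hr": 0.79
  },
  "9HPT": {
    "intercept": -0.39,
    "coefficients": {"age": 0.005},
    "threshold_hr": 0.86
  },
  "T25FW": {
    "intercept": -0.58,
    "coefficients": {
      "age": 0.01,
      "edss": 0.11,
      "log10_disease_duration": -0.19,
      "relapses_2y": -0.09
    },
    "threshold_hr": 0.95
  },
  "SDMT": {
    "intercept": -0.56,
    "coefficients": {"edss": 0.1, "male": 0.34, "log10_disease_duration": -0.15},
    "threshold_hr": 0.75
  }
}
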