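{
  "name": "beluga_sex_model",
  "trait": "sex_logistic",
  "intercept": 0.6717,
  "coefficients": {
    "cg15451847": -1.1579
  },
  "provenance": {
    "species": "Delphinapterus leucas",
    "coding": "female=1, male=0; p_female = 1 / (1 + exp(-(0.6717 - 1.1579 * beta)))",
    "probe_note": "single Y-linked CpG (KDM5D in humans); low beta indicates absence of a Y chromosome",
    "training": "LASSO logistic regression (alpha=1) on the 67 calibration samples",
    "note": "published model transcribed digit-for-digit"
  }
}
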