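{
  "schema_version": 1,
  "name": "EarlyGuard",
  "pairs": [
    ["miR-12120", "miR-6075"],
    ["miR-1233-5p", "miR-4651"],
    ["miR-4656", "miR-575"],
    ["miR-4725-3p", "miR-7110-5p"],
    ["miR-4787-5p", "miR-6125"]
  ],
  "coefficients": [4.16, -3.82, 1.63, 1.93, -6.3],
  "intercept": 5.19,
  "cutoff": 0.0892,
  "meta": {
    "n_training": 174,
    "n_training_malignant": 34,
    "n_training_benign": 140,
    "source": "published serum training cohort; coefficients fixed, not refit"
  }
}
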