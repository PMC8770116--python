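{
  "name": "default-saliva-migration-regression",
  "intercept": 3.23,
  "slopes": {
    "log10_dp": 0.73,
    "log10_c0": 0.92,
    "log10_kow": -0.06
  },
  "included": ["log10_dp", "log10_c0", "log10_kow"],
  "p_values": null,
  "fit_r2": 0.89,
  "fit_se": 0.68,
  "n_obs": 437,
  "units": {
    "response": "log10(ug/10cm2/min)",
    "log10_dp": "log10(cm2/s)",
    "log10_c0": "log10(ug/g)",
    "log10_kow": "dimensionless"
  },
  "provenance": "published multiple linear regression for migration into saliva (forward selection on the harmonized experimental dataset)"
}
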