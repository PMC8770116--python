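# Material QSPR coefficient library (synthetic representative defaults).
#
# One record per material. The functional forms are fixed by the code
# (see migrisk.qspr): log10 D_p linear in MW, and log10 K_ms linear in
# log10 Kow and in the ethanol-equivalency fraction of the medium.
# The coefficient VALUES shipped here are representative defaults
# constructed to reproduce the qualitative ordering reported for
# children's-product materials (diffusion coefficients in wood, silicone
# and EVA roughly three orders of magnitude above PVC/PP at equal MW;
# K_ms driven primarily by Kow). They are not transcribed from any
# published coefficient table: replace them with values from your
# preferred QSPR source for quantitative work. Edits here require no
# code change.
materials:
  PVC:
    density_g_cm3: 1.30
    dp_qspr:
      name: log_linear_mw
      coefficients: {intercept: -6.5, slope_mw: -0.0100}
      mw_domain: [50.0, 1000.0]
    kms_qspr:
      name: log_kow_etoh_linear
      coefficients: {intercept: 0.5, slope_log_kow: 0.50, etoh_sensitivity: 2.0}
    provenance: synthetic representative default (see header)
  PP:
    density_g_cm3: 0.90
    dp_qspr:
      name: log_linear_mw
      coefficients: {intercept: -6.2, slope_mw: -0.0105}
      mw_domain: [50.0, 1000.0]
    kms_qspr:
      name: log_kow_etoh_linear
      coefficients: {intercept: 0.6, slope_log_kow: 0.52, etoh_sensitivity: 2.0}
    provenance: synthetic representative default (see header)
  EVA:
    density_g_cm3: 0.94
    dp_qspr:
      name: log_linear_mw
      coefficients: {intercept: -4.6, slope_mw: -0.0060}
      mw_domain: [50.0, 800.0]
    kms_qspr:
      name: log_kow_etoh_linear
      coefficients: {intercept: 0.4, slope_log_kow: 0.48, etoh_sensitivity: 2.0}
    provenance: synthetic representative default (see header)
  silicone:
    density_g_cm3: 1.10
    dp_qspr:
      name: log_linear_mw
      coefficients: {intercept: -4.8, slope_mw: -0.0055}
      mw_domain: [50.0, 800.0]
    kms_qspr:
      name: log_kow_etoh_linear
      coefficients: {intercept: 0.3, slope_log_kow: 0.46, etoh_sensitivity: 2.0}
    provenance: synthetic representative default (see header)
  wood:
    density_g_cm3: 0.60
    dp_qspr:
      name: log_linear_mw
      coefficients: {intercept: -5.0, slope_mw: -0.0065}
      mw_domain: [50.0, 600.0]
    kms_qspr:
      name: log_kow_etoh_linear
      coefficients: {intercept: 0.2, slope_log_kow: 0.42, etoh_sensitivity: 2.2}
    provenance: synthetic representative default (see header)
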