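{
  "comment": "Published reference constants for the 169Yb Model M42 HDR source characterisation (FLUKA benchmark dataset).",
  "dose_rate_constant_cGy_per_h_per_U": 1.14,
  "dose_rate_constant_unc": 0.04,
  "air_kerma_strength_U_per_mCi": 1.082,
  "air_kerma_strength_unc": 2.6e-06,
  "air_kerma_rate_printed_cGy_per_h_per_mCi": 0.0001981,
  "reference_dose_rate_cGy_per_h_per_mCi": 1.229,
  "poly_coeffs_a0_a5": [0.919, 0.0952, -0.0139, 0.00277, -0.000412, 1.96e-05],
  "fit_R2": 0.999,
  "active_length_cm": 0.6
}
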