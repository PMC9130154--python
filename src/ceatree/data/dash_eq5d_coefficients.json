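{
  "provenance": "Synthetic placeholder coefficient set. No published DASH-to-EQ-5D mapping exists for finger fractures; these values are plausible in sign and scale only (full pre-injury health with zero pain maps to utility 1.0) and must be replaced by a regression fitted on real paired DASH/EQ-5D data before any applied use.",
  "intercept": 0.10,
  "beta_eq5d_pre": 0.60,
  "beta_dash_pain": -0.0035,
  "beta_eq5d_function": 0.30,
  "beta_interaction": -0.001
}
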