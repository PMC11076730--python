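{
  "n_screened": 84460,
  "n_male": 41115,
  "n_female": 43345,
  "n_referred": 4679,
  "n_is_diagnosed": 929,
  "n_is_male": 357,
  "n_is_female": 572,
  "n_other_scoliosis": 309,
  "n_observation": 459,
  "n_rehabilitation_or_brace": 338,
  "n_surgery": 132,
  "n_severe_cobb_ge40": 121,
  "bmi_counts": {
    "is": {"ge_18_5": 496, "lt_18_5": 433},
    "normal": {"ge_18_5": 43752, "lt_18_5": 39470}
  },
  "education_counts": {
    "is": {"primary": 262, "junior": 369, "senior": 298},
    "normal": {"primary": 38915, "junior": 18342, "senior": 25965}
  }
}
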