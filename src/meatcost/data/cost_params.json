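{
  "_comment": "Synthetic annual BRL cost-series generator defaults, anchored so the fitted linear trend projects to roughly the published colorectal-cancer cost levels (about US$ 450 million PPP both sexes in 2030). noise_sd_brl is a realistic registry-level year-to-year wobble.",
  "male": {
    "intercept_brl": 77905091,
    "slope_brl_per_year": 20192271,
    "noise_sd_brl": 8000000,
    "year_start": 2008,
    "year_end": 2019,
    "base_year": 2008
  },
  "female": {
    "intercept_brl": 81733802,
    "slope_brl_per_year": 19191187,
    "noise_sd_brl": 8000000,
    "year_start": 2008,
    "year_end": 2019,
    "base_year": 2008
  }
}
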