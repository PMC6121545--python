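cvd_risk:
- age_low: 35
  age_high: 44
  probability: 0.0015
  se: 0.0004
- age_low: 45
  age_high: 54
  probability: 0.0071
  se: 0.0018
- age_low: 55
  age_high: 64
  probability: 0.0149
  se: 0.0037
- age_low: 65
  age_high: 74
  probability: 0.0266
  se: 0.0067
- age_low: 75
  age_high: 84
  probability: 0.0478
  se: 0.012
- age_low: 85
  age_high: null
  probability: 0.0681
  se: 0.017
values:
  rr_cvd_prior: 1.965
  p_anxiety_base: 0.18
  rr_anx_cvd: 1.66
  rr_cvd_noise: 1.14
  rr_anx_noise: 1.79
  anxiety_odds_ratio: 2.0
  cost_cvd_direct: 23229.0
  cost_cvd_indirect: 12837.0
  cost_anx_direct: 2814.0
  cost_anx_indirect: 313.0
  exposure_op_cost_pp: 1516.0
  exposure_prod_loss_pp: 238.0
  disutil_cvd_event: 0.283
  disutil_anxiety: 0.16
  u_prior_cvd: 0.844
  u_no_cvd: 1.0
  cvd_prevalence_init: 0.35
  cvd_case_fatality: null
  prior_cvd_mort_multiplier: 1.0
  start_age: 41
  discount_rate: 0.03
  population_60db: 83807
  population_65db: null
distributions:
  p_anxiety_base:
    family: beta
    mean: 0.18
    se: 0.007
  rr_cvd_prior:
    family: lognormal
    mean: 1.965
    ci:
    - 1.67
    - 2.3
  rr_anx_cvd:
    family: lognormal
    mean: 1.66
    ci:
    - 1.49
    - 1.82
  rr_cvd_noise:
    family: lognormal
    mean: 1.14
    ci:
    - 1.08
    - 1.2
  rr_anx_noise:
    family: lognormal
    mean: 1.79
    ci:
    - 1.0
    - 3.06
  cost_cvd_direct:
    family: gamma
    mean: 23229.0
    se: 5807.0
  cost_cvd_indirect:
    family: gamma
    mean: 12837.0
    se: 3209.0
  cost_anx_direct:
    family: gamma
    mean: 2814.0
    se: 704.0
  cost_anx_indirect:
    family: gamma
    mean: 313.0
    se: 78.0
  exposure_op_cost_pp:
    family: gamma
    mean: 1516.0
    se: 379.0
  exposure_prod_loss_pp:
    family: gamma
    mean: 238.0
    se: 59.0
  disutil_cvd_event:
    family: beta
    mean: 0.283
    se: 0.013
  disutil_anxiety:
    family: beta
    mean: 0.16
    se: 0.04
  u_prior_cvd:
    family: beta
    mean: 0.844
    se: 0.0096
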