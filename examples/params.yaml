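# Baseline parameter file. Every field is optional: anything omitted is
# filled from the same built-in defaults shown here, so an empty file (or no
# --params flag at all) reproduces the base case.
cea:
  wtp: 36832.95            # USD per QALY (3x 2022 per-capita GDP threshold)
  arms:
    low:                   # 5 mg/day oral aripiprazole
      p_discontinue_ae: 0.023
      p_posthoc: 0.405     # responders with >50% total-tic-score reduction
      p_partial: 0.333     # 25-50% reduction
      daily_dose_mg: 5.0
    high:                  # 10 mg/day
      p_discontinue_ae: 0.156
      p_posthoc: 0.571
      p_partial: 0.314
      daily_dose_mg: 10.0
    placebo:
      p_discontinue_ae: 0.023
      p_posthoc: 0.167
      p_partial: 0.548
      daily_dose_mg: 0.0
  econ:
    weekly_direct_medical_cost: 31.50   # USD/week, all patients
    drug_price_per_5mg: 0.72            # USD per 5 mg
    horizon_weeks: 52
    ae_treatment_weeks: 8               # drug exposure before AE dropout
    days_per_horizon: null              # defaults to horizon_weeks * 7 = 364
    discount_rate: 0.0                  # no within-horizon discounting
  util:
    u_posthoc: 0.934
    u_partial: 0.919
    u_nonresponse: 0.902
    disutility_ae: -0.090               # ~10% of the mapped baseline utility
    baseline_ygtss_total: 30.37
    mapping_intercept: 0.9881           # reference total-score linear mapping
    mapping_slope: -0.0035
    ae_utility_convention: baseline_minus_disutility

cohort:
  n: 144
  seed: 0
  male_fraction: 0.8699
  age_mean: 9.01
  age_sd: 2.47
  motor_mean: 11.28
  motor_sd: 5.07
  vocal_mean: 4.95
  vocal_sd: 6.36
  utility_intercept: 0.9881
  utility_slope: -0.0035
  noise_sd: 0.075

psa:
  n_iterations: 1000
  seed: 20240807

ceac:
  wtp_max: 200000.0
  step: 1000.0

# Sensitivity ranges default to +/-20% for costs and the baseline tic score,
# +/-10% for probabilities, +/-50% for the AE disutility, and the observed
# market band 0.32-1.52 for the drug price. Override by listing entries:
# ranges:
#   - {name: drug_price_per_5mg, base: 0.72, low: 0.32, high: 1.52, distribution: gamma}
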