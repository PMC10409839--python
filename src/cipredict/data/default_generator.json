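{
  "n_patients": 124,
  "seed": 0,
  "age_mean": 67.45,
  "age_sd": 13.9,
  "age_range": [
    25.0,
    86.0
  ],
  "pta_mean": 93.0,
  "pta_sd": 21.0,
  "pta_range": [
    47.0,
    130.0
  ],
  "threshold_offsets": [
    -7.5,
    -2.5,
    2.5,
    7.5
  ],
  "threshold_spread_sd": 4.0,
  "audiometer_max_db": 120.0,
  "contra_mean": 54.0,
  "contra_sd": 26.0,
  "contra_range": [
    3.0,
    95.0
  ],
  "p_wrsmax_zero_slope": 0.08,
  "p_wrsmax_zero_intercept": -8.6,
  "wrsmax_logit_intercept": 3.8,
  "wrsmax_logit_slope": -0.05,
  "wrsmax_logit_sd": 0.8,
  "ha_attenuation": 0.15,
  "max_ha_percent": 50.0,
  "max_resample": 1000,
  "n_items": 20,
  "trajectory_tau_log_mean": 0.0,
  "trajectory_tau_log_sd": 0.3,
  "followup_months": [
    1.0,
    2.0,
    3.0,
    6.0,
    12.0
  ],
  "pattern_rate_flat": 0.02,
  "pattern_rate_fluctuating": 0.02,
  "flat_asymptote_frac": 0.3,
  "fluctuating_level_frac": 0.4,
  "fluctuating_sd": 0.15,
  "coefficients": {
    "beta0": 0.84,
    "beta1": 0.012,
    "beta2": -0.0094,
    "beta3": 0.0059,
    "se0": 0.18,
    "se1": 0.0015,
    "se2": 0.0025,
    "se3": 0.0026,
    "label": "published"
  }
}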