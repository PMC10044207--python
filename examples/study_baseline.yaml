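# Baseline PTA study: cefepime-like one-compartment population model,
# 2000 mg q8 h over 30 min (intermittent arm) vs 6000 mg/day continuous,
# fT 60% > MIC 8 mg/L, 50 patients x 200 repetitions.
model:
  tvCL: 13.6            # L/h at the covariate reference
  V: 18.0               # L central volume
  fu: 0.8               # fraction unbound
  cv_CL: 0.228          # between-subject variability of clearance (CV)
  ruv_prop_sd: 0.2      # proportional residual error SD (used when ruv enabled)
  covariate_model:
    kind: power_sCr
    reference_value: 0.47   # mg/dL
    exponent: 0.51
regimen:
  mode: intermittent
  dose: 2000            # mg
  interval: 8           # h
  infusion_duration: 0.5  # h
target:
  metric: fT_above_MIC
  required_fraction: 60   # % of the dosing interval
  mic: 8                  # mg/L
settings:
  n_patients: 50
  n_reps: 200
  dt: 0.2               # h sampling interval
  seed: 0
  phase: first_dose
  success_threshold: 90
cohort:
  n: 50
  sCr_mode: fixed
  sCr: 0.47             # mg/dL
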