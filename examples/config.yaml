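# Full-chain pipeline configuration: simulate a two-wave cohort, push it
# through accelerometer reduction and FTS scoring, apply the exclusion
# cascade and fit both cross-lagged panel models.
seed: 1

synth:
  n: 120                 # participants at baseline
  scale: natural         # FTS points and min/day files
  missing_rate: 0.3      # wave-2 attrition
  missing_mechanism: MAR # dropouts older, less educated, more sedentary
  mvpa:
    a_frailty: 0.6
    a_behaviour: 0.5
    c_behaviour_to_frailty: -0.126   # MVPA protects against later frailty
    c_frailty_to_behaviour: 0.0
    r_t1: -0.2
    r_resid: -0.1
  sb:
    a_frailty: 0.6
    a_behaviour: 0.5
    c_behaviour_to_frailty: 0.0
    c_frailty_to_behaviour: 0.167    # frailty precedes later sitting time
    r_t1: 0.2
    r_resid: 0.1

accel:
  enabled: true
  days: 7

fts:
  enabled: true

report:
  planted_invalid_accel: 2     # completers with insufficient wear time
  planted_invalid_fts: 1       # completers with only 8 of 12 items
  planted_missing_covariates: 1

clpm:
  covariates: []
  include_wear_time: false
  estimator: fiml
  alpha: 0.05
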