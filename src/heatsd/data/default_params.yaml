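# Shipped default calibration.
#
# Produced by fitting the free coefficients against the packaged 2013-like
# synthetic heat-wave fixture and the y2013 city profile (least squares on
# the scenario ratios plus the cool-day mortality anchor); see
# docs/methods.md for what is calibrated and why.  The background rate is
# the observed cool-day mortality level (114 per ten million per day) minus
# the model's own cool-day equilibrium death flow.
exposure:
  t_morb: 36.6
  t_mort: 37.6
  beta_morb: 23.816
  r_base: 245.97
  mu: 0.05838
adaptation:
  af0: 0.79177
  af_cap: 0.95
  factor_floor: 0.001
  factor_cap: 10.0
  weights:
    ac_rate: 0.5
    income: 0.5
    staff: 0.3
    beds: 0.9962
    hospitals: 0.3
    allowance: 0.5238
    insurance: 0.5
  reference_city:
    pop_under14: 2410000.0
    pop_15_64: 18075000.0
    pop_over65: 3615000.0
    hospitals: 338.0
    beds: 115000.0
    staff: 190000.0
    ac_rate: 0.95
    income: 3600.0
    allowance: 790.0
    insurance: 0.85
tables:
  MA:
    - [35.0, 1.0]
    - [37.6, 1.0]
    - [38.5, 1.0]
    - [39.5, 1.792]
    - [40.5, 1.794]
    - [43.0, 1.797]
  HDAF:
    - [0.0, 1.0]
    - [1.0, 1.0]
    - [5.0, 1.0]
    - [10.0, 3.0]
    - [20.0, 4.99]
background_rate: 97.109
bed_capacity: 0.0052417
allowance_elasticity: 0.8725
elderly_vulnerability: 0.0
hot_threshold: 35.0
cf_on_apf: false
tpf_delay: false
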