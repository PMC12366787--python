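{
  "uptake_prey_per_h": 202.0,
  "uptake_sd": 103.0,
  "uptake_median": 191.0,
  "n_cells_inspected": 960,
  "prey_mcv_um3": 0.081,
  "predator_length_um": 17.1,
  "predator_length_sd_um": 1.4,
  "predator_width_um": 8.5,
  "predator_width_sd_um": 1.3,
  "predator_mcv_um3": 661.0,
  "gge_low": 0.30,
  "gge_high": 0.40,
  "tracer_fraction": 0.18,
  "incubation_min_ciliate": 10.0,
  "incubation_min_hnf": 60.0,
  "growth_rate_aug11_per_day": 0.136,
  "growth_rate_aug25_per_day": 0.116,
  "pct_standing_stock_daily": 12.3,
  "temperature_c": 5.8,
  "q10": 2.5
}
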