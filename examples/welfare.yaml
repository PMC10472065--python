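geometry:
  depth_m: 1.0
seed: 1
fish:
  initial_count: 50000
  initial_mean_weight_g: 200.0
  initial_sd_weight_g: 30.0
control:
  mode: welfare
scenario:
  variant: welfare
  name: welfare
  horizon_d: 5
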