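version: 1
presets:
  no_stimulus:
    tdiv0_mean: 80.0
    tdiv0_sd: 10.0
    tdiv1_mean: 10.0
    tdiv1_sd: 2.0
    f0: 0.0
    death_hazard: 0.02
    generation_cap: 6
    n_founders: 1000
    timepoints:
    - 0.0
    - 24.0
    - 36.0
    - 48.0
    - 72.0
    - 96.0
  low_cd40:
    tdiv0_mean: 76.9
    tdiv0_sd: 10.0
    tdiv1_mean: 35.2
    tdiv1_sd: 6.0
    f0: 0.044
    death_hazard: 0.012
    generation_cap: 6
    n_founders: 1000
    timepoints:
    - 0.0
    - 24.0
    - 36.0
    - 48.0
    - 72.0
    - 96.0
  medium_cd40:
    tdiv0_mean: 68.6
    tdiv0_sd: 10.0
    tdiv1_mean: 7.8
    tdiv1_sd: 1.5
    f0: 0.184
    death_hazard: 0.008
    generation_cap: 6
    n_founders: 1000
    timepoints:
    - 0.0
    - 24.0
    - 36.0
    - 48.0
    - 72.0
    - 96.0
  high_cd40:
    tdiv0_mean: 68.5
    tdiv0_sd: 10.0
    tdiv1_mean: 6.1
    tdiv1_sd: 1.0
    f0: 0.468
    death_hazard: 0.005
    generation_cap: 6
    n_founders: 1000
    timepoints:
    - 0.0
    - 24.0
    - 36.0
    - 48.0
    - 72.0
    - 96.0
  co_low:
    tdiv0_mean: 72.0
    tdiv0_sd: 10.0
    tdiv1_mean: 8.0
    tdiv1_sd: 1.5
    f0: 0.25
    death_hazard: 0.008
    generation_cap: 6
    n_founders: 1000
    timepoints:
    - 0.0
    - 24.0
    - 36.0
    - 48.0
    - 72.0
    - 96.0
  co_high:
    tdiv0_mean: 66.0
    tdiv0_sd: 10.0
    tdiv1_mean: 6.0
    tdiv1_sd: 1.0
    f0: 0.4
    death_hazard: 0.015
    generation_cap: 6
    n_founders: 1000
    timepoints:
    - 0.0
    - 24.0
    - 36.0
    - 48.0
    - 72.0
    - 96.0
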