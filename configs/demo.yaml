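# Demo pipeline configuration: small synthetic cohort, completes on one
# CPU in well under two minutes.
seed: 21
bands: [alpha2]
epoch_len_s: 2.0
amp_threshold_uv: 150.0
min_epochs: 1          # demo cohorts have only 30 epochs per subject
edge_trim: 0.05
pooled: false
synth:
  n_per_group: 10
  channels: 8
  fs: 128.0
  duration_s: 60.0     # 30 epochs of 2 s
  signal_bands: [alpha2]
  base_bias: 0.2
  group_effects:
    alpha2:
      topology: star_bias
      bias_weight: 0.35
stats:
  m: 9
  log_power: true
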