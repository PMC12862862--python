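# Smoke profile: 20 athletes, 12 bi-weekly points, tiny model; completes in
# well under a minute.
cohort:
  n_per_group: [7, 7, 6]
  n_timepoints: 12
  seed: 0
hybrid:
  temporal:
    embed_dim: 8
    layer_sizes: [8]
    bidirectional: [false]
    max_epochs: 20
    early_stop_patience: 5
  boost:
    n_estimators: 30
    max_depth: 3
  fusion_dim: 4
  fusion_epochs: 100
n_folds: 3
val_window: 1
n_boot: 100
max_lag: 4
seed: 0
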