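# Full-size profile: printed hyperparameters (embedding 52->128, LSTM 128,
# biLSTM 256, LSTM 64; 500 boosting rounds, depth 6; 5000 bootstrap draws).
cohort:
  seed: 0
hybrid:
  temporal:
    embed_dim: 128
    layer_sizes: [128, 256, 64]
    bidirectional: [false, true, false]
    max_epochs: 100
  boost:
    n_estimators: 500
    max_depth: 6
  fusion_dim: 16
n_boot: 5000
seed: 0
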