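# Desk-scale profile: published cohort conditions with a shrunken model
# (32/64/16 recurrent layers, 100 boosting rounds) and 1000 bootstrap draws.
cohort:
  seed: 0
hybrid:
  temporal:
    embed_dim: 32
    layer_sizes: [32, 64, 16]
    bidirectional: [false, true, false]
    max_epochs: 60
  boost:
    n_estimators: 100
    max_depth: 4
  fusion_dim: 8
n_boot: 1000
seed: 0
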