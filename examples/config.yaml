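# Example experiment config for the `snndelays` CLI.
#
#   snndelays compare --config examples/config.yaml --seed 1 --out runs/demo
#   snndelays ablate  --config examples/config.yaml --out runs/ablation
#   snndelays morans  runs/demo/rf/rf_class00_trained.csv
seed: 1
out: runs/demo
data:
  kind: class_pattern        # or planted_structure (+ informative_fraction)
  n_channels: 16
  T: 40
  n_classes: 10
  n_samples: 800
  n_features: 6
  T_d: 12
  noise_rate: 0.04
network:
  n_hidden: 64
  T_d: 12
  dropout_p: 0.0
  batch_norm: true
  dale: true
  learn_structure: true
  learn_delays: true
  sparsity_level: 0.875
train:
  epochs: 30
  batch_size: 100
  lr_weights: 0.1
  lr_delays: 0.1
  l1_lambda: 1.0e-4
  sigma:                     # kernel-width annealing, calibrated to T_d
    sigma_init: 6.0
    sigma_min: 0.5
    anneal_frac: 0.75
morans:
  n_perm: 2000
ablate:
  sparsity_levels: [0.5, 0.75, 0.875]
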