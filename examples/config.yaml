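# Desk-scale end-to-end run: `pathshap run -c examples/config.yaml -o runs/full`
seed: 1
paper_scale: false   # true restores the cluster-scale search spaces

cohort:
  n_train: 15
  n_test: 7
  n_per_category: 40
  n_volumes: 485
  n_ics: 125
  tr_seconds: 2.5
  noise_sd: 0.5
  effect_size: 1.0

screening:
  n_stimuli: 200
  n_per_group: 40

features:
  volume_offset: 3          # third volume after onset -> +6.5 s
  standardize_mode: train_stats

train:
  lr_grid: [0.01]
  momentum_grid: [0.9]
  epochs: 30
  n_restarts: 2
  init_scale: 0.5
  n_hidden: 10

retrain:
  lr_grid: [1.0e-9, 1.0e-3]
  momentum_grid: [0.85]
  epochs: 30
  n_restarts: 1

explain:
  background_n: 40
  n_permutations: 64
  n_instances: 48
  top_n: 20
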