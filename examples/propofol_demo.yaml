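run_id: demo
simulate:
  n_subjects: 4
  n_conditions: 4
  n_frames: 197
  grid_dims: [16, 18, 16]
  k_true: 4
  gains:
    - [1.0, 1.0, 1.0, 1.0]
    - [0.8, 1.0, 0.6, 1.0]
    - [0.5, 1.0, 0.2, 1.0]
    - [0.9, 1.0, 0.9, 1.0]
cluster:
  k: 8
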