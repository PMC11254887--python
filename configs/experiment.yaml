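# Reference configuration for `splitgfr run-all` — the scaled-down learning
# experiment: 300 noisy phantoms, 4-fold rotation, reduced-width U-Net at the
# native 64x64 resolution (~10-15 min on one CPU).
phantom:
  n: 300
  gfr_range: [20, 150]
  split_range: [0.35, 0.65]
  noise: true
  liver: false
training:
  input_size: 64
  base_filters: 8
  levels: 3
  epochs: 25
  batch_size: 8
  learning_rate: 1.0e-2
  folds: 4
gates:
  depth_formula: tonnesen
  window_frames: [9, 12]
background:
  gap_px: 2
  annulus_width_px: 3
evaluation:
  abs_threshold: 5.0
  rel_thresholds: [10.0, 20.0]
seed: 1
make_plots: true
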