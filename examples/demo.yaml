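# Two-season demo pipeline on a simulated landscape.
# Run:  nomadsel all --config examples/demo.yaml
outdir: demo_out
seed: 3
growing_start: [5, 9]
growing_end: [8, 29]
simulate:
  n_individuals: 4
  n_years: 2
  grid_nx: 96
  grid_ny: 96
  cell_size: 250.0
  correlation_length: 2000.0
  temporal_persistence: 0.6
  beta1: 13.0
  beta2: -14.0
  step_scale: 2000.0
  drop_fraction: 0.05
rsf:
  multipliers: [1, 2, 5, 10, 20]
  report_multiplier: 20
  weight_available: 1000.0
ssf:
  lags: [1, 5, 10]
  k_values: [25, 50, 100, 200, 400]
  report_k: 100
  alpha: 0.05
  min_steps: 20
rss:
  trim: 0.05
  n_grid: 200
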