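# Demo configuration for the end-to-end pipeline:
#   strfkit run --config examples/pipeline_demo.yaml
# 10 simulated units with 5-minute estimation segments; takes a few minutes
# on one CPU and writes per-unit artifacts plus population_summary.csv.
out_dir: scratch/pipeline_demo
seed: 1
n_units: 10
duration_est: 300.0
duration_val: 30.0
n_trials: 20
n_null: 200
null_stride: 8
baseline_rate: 8.0
trial_jitter_sd: 0.2
n_cv_iter: 10
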