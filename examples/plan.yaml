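# Machine-readable analysis plan for a threshold-crossing program.
# Run with:  thresholdcross run --config examples/plan.yaml
estimand:
  population: treatment-eligible adults per protocol criteria
  variable: standardized outcome score at 12 weeks
  effect_measure: mean difference vs historical control
design:
  delta: 0.2      # assumed standardized effect
  sigma: 1.0      # known endpoint SD
  alpha: 0.025    # one-sided significance level
  power: 0.80
rules: [naive, ci, ci+0.1, ci+0.2, ci+0.3]
historical:
  cohorts:
    - {source_id: registry, n: 600, mean: 0.05, sd: 1.0}
    - {source_id: rct_control_arm, n: 400, mean: -0.10, sd: 0.95}
pooling: random
grid:
  n_h: [150, 300, 500, 1000, 2000]
  drifts: [0.0, 0.05, 0.1]
  n_reps_type1: 20000
  n_reps_power: 5000
flow:
  stage2: rct
  alpha2: 0.025
  true_delta: 0.2
  n_reps: 20000
seed: 2026
out_dir: results_plan
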