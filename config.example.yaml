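# Example pipeline configuration (twinstage run-all --config config.example.yaml)
# Omitted keys take the study-design defaults; block seeds left unset are
# derived deterministically from the top-level seed.
seed: 1
output_dir: results/run

generator:
  n_mz: 167
  n_dz: 208
  age_mean: 16.55
  age_sd: 0.51
  female_fraction: 0.58
  outcomes:
    wellbeing:
      proportions: wellbeing        # named default table, or explicit a/c/e matrices
    mentalhealth:
      proportions: mentalhealth
  trajectory:
    baseline_mean: 0.0
    control_increment: 0.0
    intervention_increment: 0.07    # SD units per occasion, from the intervention on
    age_effect: 0.0
    sex_effect: 0.0
  missingness: [0.005, 0.015, 0.03, 0.01]

preprocessing:
  rank_normalize: true
  per_stage_transform: true
  correct_age_sex: true

models:
  stages: [1, 2, 3, 4]
  ci_level: 0.95
  compute_ci: false                 # profile CIs for every table cell are slow
  restarts: 5
  missing_mode: fiml                # or "complete"

power:
  run: false
  n_mz: 167
  n_dz: 208
  a2: 0.40
  c2: 0.0
  alpha: 0.05
  reps: 500
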