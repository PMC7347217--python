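# Simulation-mode pipeline config: a laptop-scale cohort with graded
# heritability across six measures. Run with:
#   twinherit run examples/config.yaml --seed 1 --out results/
simulation:
  design:
    n_mz_pairs: 149
    n_dz_pairs: 90
    n_unrelated: 700
    n_retest: 46
  specs:
    - {measure_id: matrix_reasoning,  a2: 0.6, e2: 0.4, domain: task}
    - {measure_id: vocabulary,        a2: 0.5, c2: 0.2, e2: 0.3, domain: task}
    - {measure_id: processing_speed,  a2: 0.3, e2: 0.7, domain: task}
    - {measure_id: neuroticism,       a2: 0.4, e2: 0.6, domain: questionnaire}
    - {measure_id: life_satisfaction, a2: 0.2, c2: 0.2, e2: 0.6, domain: questionnaire}
    - {measure_id: daily_stress,      e2: 1.0, domain: questionnaire}
seed: 1
out_dir: twinherit_out
n_perm_identification: 1000
n_perm_domain: 10000
ml:
  n_iterations: 1000
  n_alpha_iterations: 200
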