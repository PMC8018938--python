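# Three competing sex-ratio strategies in a 26-class age-structured population
# with sex-asymmetric survival schedules, started from a very young population.
# This is the scenario returned by agerep.fixtures.fisher_scenario().
kind: sexratio
strategies: [0.05, 0.55, 0.95]
brood_size: 6.0
n_classes: 26
survival_female: "0.95 until 10 then 0.80"
survival_male: "0.88 until 15 then 0.72"
male_window: [8, 20]
female_window: [8, 15]
carrying_capacity: 10000.0
initial:
  n: 40.0
  gene_frequencies: [0.9, 0.05, 0.05]
  adult_class_frequency: 0.001
  infant_sex_ratios: [0.7, 0.1, 0.1]
  adult_sex_ratios: [0.9, 0.8, 0.8]
solver:
  rtol: 1.0e-8
  atol: 1.0e-10
  max_time: 2000.0
  steady_state_tol: 1.0e-9
  output_dt: 1.0
  method: LSODA
  stop_at_steady_state: true
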