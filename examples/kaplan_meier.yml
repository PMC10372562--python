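# Federated Kaplan-Meier curves and log-rank test from per-silo event
# tables; results are identical to the pooled analysis.
n_parties: 3
seed: 33
proportions: [0.3, 0.3, 0.4]
workflow:
  - app: kaplan_meier
dataset:
  task: survival
  n_samples: 228
  n_features: 4
  censoring_rate: 0.37
  seed: 7
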