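# Ensemble-merged federated random forest: 100 trees total, allocated
# to silos in proportion to their sample counts.
n_parties: 5
seed: 5
proportions: [0.10, 0.15, 0.15, 0.30, 0.30]
workflow:
  - app: cv
    params: {k: 10}
  - app: normalization
  - app: random_forest
    params: {n_trees: 100}
  - app: eval_classification
dataset:
  task: classification
  n_samples: 579
  n_features: 10
  effect: 1.2
  intercept: 0.9
  seed: 7
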