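# Five uneven silos run 10-fold CV -> federated standardization ->
# exact federated linear regression -> federated RMSE evaluation.
n_parties: 5
seed: 42
proportions: [0.10, 0.15, 0.15, 0.30, 0.30]
workflow:
  - app: cv
    params: {k: 10}
  - app: normalization
  - app: linear_regression
  - app: eval_regression
dataset:
  task: regression
  n_samples: 442
  n_features: 10
  noise_sd: 1.0
  seed: 7
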