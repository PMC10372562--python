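# Federated logistic regression with additive-secret-sharing secure
# aggregation: the coordinator only ever sees summed gradients/Hessians.
n_parties: 3
seed: 11
proportions: [0.3, 0.3, 0.4]
secure_aggregation: true
workflow:
  - app: cv
    params: {k: 5}
  - app: normalization
  - app: logistic_regression
  - app: eval_classification
dataset:
  task: classification
  n_samples: 579
  n_features: 10
  effect: 1.2
  intercept: 0.9
  seed: 7
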