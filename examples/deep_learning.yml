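# FedAvg training of a small MLP on a large regression cohort with a
# local 20% holdout at each silo.
n_parties: 5
seed: 21
proportions: [0.10, 0.15, 0.15, 0.30, 0.30]
workflow:
  - app: deep_learning
    params: {n_features: 12, rounds: 50, local_epochs: 1, batch_size: 32,
             learning_rate: 0.05}
  - app: eval_regression
dataset:
  task: regression
  n_samples: 5000
  n_features: 12
  noise_sd: 0.5
  seed: 7
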