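# fedsilo

A cross-silo federated-learning simulator for tabular biomedical data.
Several institutions (hospitals, registries, biobanks) each hold the same
features for different patients and cannot pool raw records; `fedsilo`
runs the standard federated workflow over a simulated star topology — one
coordinator, N participants, an audited in-memory message log — so that
the *algorithms* of federated analysis can be studied, verified against
centralized oracles, and costed in messages and bytes, without any real
networking.

Chained "apps" compose into workflows the way federated platforms run
them: local k-fold cross-validation → federated standardization → a model
→ federated evaluation, with intermediate results kept at each party and
only aggregation statistics crossing silo boundaries.

## What is federated, and how

| App | Statistic exchanged | Guarantee |
| --- | --- | --- |
| `normalization` | per-party (n, Σx, Σx²) | identical to pooled standardization |
| `linear_regression` | Gram blocks (XᵀX, Xᵀy, n) | β from (ΣXᵀX)β = ΣXᵀy equals pooled OLS |
| `logistic_regression` | per-round score Xᵀ(y−p) and information Xᵀdiag(p(1−p))X | Newton trajectory identical to pooled IRLS |
| `random_forest` | sample counts, then serialized trees | fixed 100-tree global forest, per-party quota ∝ nᵢ (largest remainder) |
| `deep_learning` | (nᵢ·θᵢ, nᵢ) after local SGD epochs | FedAvg; one full-batch step equals the pooled gradient step exactly |
| `kaplan_meier` | per-time event tables | S(t) = Π(1 − dᵢ/nᵢ) and log-rank χ² identical to pooled analysis |
| `eval_classification` / `eval_regression` | confusion matrices / (n, SSE, SAE) | global F1 and RMSE equal pooled metrics |
| `one_hot`, `cv`, `identity` | category names / nothing | shared column order; local fold splits |

The exact estimators exploit that their sufficient statistics are sums
over rows: partitioning rows across silos is algebraically invisible, so
federated and centralized coefficients agree to floating-point round-off.
The forest and FedAvg learners are approximate by construction and are
compared to centralized baselines distributionally.

Any summable exchange can be routed through **additive secret sharing**
(`secure_aggregation: true`): vectors are fixed-point encoded (scale 10⁶)
into a 62-bit prime ring, split into N random shares relayed blindly via
the coordinator, and only per-party partial sums are ever revealed — the
coordinator learns the global sum, never a local model. The scheme costs
n(n−1) share messages per summation and is undefined below 3 parties.

A synthetic-data module generates classification, regression and survival
cohorts (configurable effect size, noise, class imbalance, censoring
rate) and partitions them across silos either IID or with label skew, in
the canonical uneven five-silo layout (10/15/15/30/30 %).

## Worked example

Simulate a five-silo linear-regression study (442 samples, 10 features,
silos holding 10/15/15/30/30 % of the data):

```sh
fedsilo simulate examples/linear_regression.yml --out results
```

prints, after the per-step reports:

```
network traffic by payload kind:
  ack                  15 messages           15 bytes
  broadcast           150 messages        34765 bytes
  error_sums           50 messages         1200 bytes
  final_result          5 messages         2300 bytes
  gram                 50 messages        53200 bytes
  moments              50 messages         8400 bytes
  sample_count          5 messages           12 bytes
```

— 50 `gram` messages are the 5 parties × 10 folds sending their local
(XᵀX, Xᵀy, n); no payload kind carries raw data. The evaluation report in
`results/report.json` ends with the 10-fold RMSE summary:

```json
{ "median": 1.048, "q1": 0.993, "q3": 1.206, "min": 0.821, "max": 1.250 }
```

The generating model has unit noise, so a cross-validated RMSE of ≈1.05
means the federated fit extracts essentially all the signal — and because
Gram aggregation is exact, these per-fold RMSEs equal a centralized
standardize→OLS pipeline on the pooled rows to 1e-8 (this is asserted in
the test suite). Other ready-made configs in `examples/` cover secure
logistic regression, the merged random forest, FedAvg training, and
federated Kaplan–Meier with a log-rank test; each runs in seconds.

The library is usable without the CLI:

```python
from fedsilo import WorkflowConfig, WorkflowStep, run_workflow
from fedsilo import DatasetSpec, PartitionSpec, generate, partition

parties = partition(generate(DatasetSpec(task="regression")),
                    PartitionSpec())
result = run_workflow(
    WorkflowConfig(steps=[WorkflowStep("cv", {"k": 10}),
                          WorkflowStep("normalization"),
                          WorkflowStep("linear_regression"),
                          WorkflowStep("eval_regression")],
                   n_parties=5, seed=42),
    parties,
)
print(result.per_step_reports[-1]["summary"])
```

## Documentation

`docs/methods.md` describes the models, the exactness arguments, the
secret-sharing scheme, what the synthetic generator does and does not
emulate, and the package's numerical choices and limitations.
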