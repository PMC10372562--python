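# Methods

## Setting and model of computation

`fedsilo` simulates horizontal, cross-silo federated learning: a handful of
organizations each hold the same features for different samples, and a star
topology connects N data-holding *participants* to one *coordinator* that
aggregates. The coordinator may itself hold data (dual role, the default).
Execution is in-process and single-machine: the real system's container
and relay-server transport is replaced by an in-memory message bus with
byte-size accounting, because the algorithms — not the transport — are the
reusable content. Every cross-party exchange passes through this bus, so
the communication pattern is enforced structurally rather than by
convention: participants may only address the coordinator (relayed secret
shares are the single exception), broadcasts originate only at the
coordinator, and every payload carries a kind drawn from a whitelist that
contains no raw-data kind. An audit over the full log therefore certifies
that no feature matrix or label vector ever crossed a silo boundary.

Aggregation is barrier-synchronized: the coordinator waits for all
participants before combining. An eager schedule (start summing as
submissions arrive) would give identical results for every sum-based
aggregator used here, but the barrier makes runs deterministic and the
message log reproducible, which we value more in a simulator.

Workflows chain *apps* (cross-validation, normalization, one-hot, a model,
an evaluation) through named data slots; each app's per-party outputs stay
in a local slot store and only its aggregation statistics travel. Apps are
round-driven state machines; an iterative app (logistic regression,
FedAvg) simply spans many rounds.

## Exact federated estimators

The linchpin of the GLM apps is that their sufficient statistics are sums
over rows, so any partition of rows across silos is algebraically
invisible:

* **Linear regression.** Each party reports (XᵀX, Xᵀy, n); the coordinator
  solves (ΣXᵀX)β = ΣXᵀy. This equals pooled OLS exactly (observed
  deviations ~1e-14, from floating-point summation order only). A singular
  aggregate Gram matrix falls back to the pseudoinverse with a warning.
* **Logistic regression.** Newton–Raphson with aggregated score and
  information: per round each party evaluates g = Xᵀ(y − p) and
  H = Xᵀdiag(p(1−p))X at the broadcast β, and the coordinator updates
  β ← β + (ΣH)⁻¹Σg. The method named for the exchange is gradient/Hessian
  sharing; Newton is chosen as the update rule because it is the scheme of
  the GWAS lineage this design follows and converges in a handful of
  rounds (5–10 on our synthetic cohorts). Convergence is declared at
  max|Δβ| < 1e-8 (default) with a 25-round cap; ill-conditioned aggregate
  Hessians (separable toy data) receive a 1e-8 ridge with a warning rather
  than aborting. The centralized reference in tests is an unpenalized
  maximum-likelihood fit (lbfgs, tight tolerance); agreement is ~1e-7.
* **Standardization.** Parties report (n, Σx, Σx²); pooled mean and sample
  standard deviation (Bessel's n−1, chosen to match the centralized
  convention exactly) come from the sums. Zero-variance features get σ=1
  and pass through centred, with a warning.
* **Evaluation.** Classification needs only summed confusion matrices,
  regression only summed (n, SSE, SAE); F1 = 2TP/(2TP+FP+FN) (0 when the
  denominator vanishes) and RMSE = √(SSE/n) from aggregated counts equal
  the pooled metrics to round-off. Binary positive-class F1 is the
  default; macro-F1 is a flag.
* **Survival.** Each party reduces its records to an event table: distinct
  event times with event counts, censoring times with counts, and the
  cohort size. Tables aggregate by summing counts over the union of
  times, which reproduces the pooled event table *exactly*, hence
  Kaplan–Meier curves (S(t) = Π(1 − dᵢ/nᵢ)) and the log-rank test
  (hypergeometric expected events and covariance, χ² with k−1 df) are
  identical to the centralized analysis. Ties follow the standard
  convention: deaths precede censorings. Sharing exact per-time counts is
  a small-cell disclosure risk in real deployments; counts can optionally
  be routed through secure aggregation, and time binning (not implemented)
  would be the stronger mitigation.

## Approximate federated learners

* **Random forest.** Three steps: parties report sample counts; the
  coordinator apportions a fixed global budget (default 100 trees)
  proportionally by largest-remainder (Hamilton) rounding — "proportional"
  alone does not fix a rounding rule, and largest remainder is the one
  that guarantees the constant total and monotonicity in sample counts,
  with ties broken by party index; parties train their quota of unpruned
  CART trees (Gini / variance splitting, √p feature sampling, bootstrap
  resamples — grown by scikit-learn) and ship them serialized as nested
  JSON; the coordinator concatenates. Prediction is unweighted majority
  vote (classification) or mean (regression) — hard voting needs only the
  tree structures, not calibrated leaf distributions. Federated and
  centralized forests are compared distributionally, never bitwise: the
  bootstrap makes exact agreement neither expected nor meaningful. On the
  default synthetic cohort the federated median F1 sits within ~0.02 of a
  centralized 100-tree forest across 10-fold CV.
* **FedAvg MLP.** A plain-numpy multilayer perceptron (default one tanh
  hidden layer of 32 units, Glorot init, plain SGD without momentum, MSE
  or logit cross-entropy) alternates local mini-batch epochs with
  count-weighted parameter averaging, implemented as summed (nᵢ·θᵢ, nᵢ)
  so the same path works under secure aggregation. Count weighting makes
  the one-full-batch-step identity exact: losses are means per sample, so
  the weighted mean of locally updated parameters equals one pooled
  gradient step (verified to 1e-16). Evaluation uses a local 20% holdout
  per party rather than CV, the usual choice for the larger cohorts this
  app targets. The default architecture is a deliberately desk-scale
  stand-in; the descriptor supports arbitrary fully connected stacks.

## Secure aggregation

Additive secret sharing over the ring Z_m with m = 2305843009213693967
(the smallest prime above 2^61). Reals are fixed-point encoded at scale
10⁶; signed values centre at m/2 on decode. Each party splits its vector
into N shares (N−1 uniform, the last the difference), sends one to every
peer through the coordinator acting as a blind relay, sums what it
receives, and submits only that partial sum; the coordinator adds partials
and decodes, learning the global sum and nothing else. Costs and limits:

* n(n−1) share messages per summation — quadratic in the party count;
* exactness to one quantisation step (1/10⁶) per summand — GLM fits with
  secure aggregation on vs off agree to ~1e-7, comfortably inside the
  1e-5 bound the scale implies;
* the scheme supports addition and multiplication by public constants
  only, and is undefined below three parties (with two, the coordinator
  could subtract its own share and recover the other party's vector) — a
  protocol error, not a degraded mode;
* the threat model is honest-but-curious; no differential privacy or
  malicious-adversary protections are claimed.

The ring comfortably holds sums of ~10⁴ parties × values up to ~10⁶ in
magnitude without wraparound. Share arithmetic uses exact integer objects;
vectors exchanged here are small (moments, Gram blocks, parameter
vectors), so the cost is negligible at simulator scale.

## Synthetic data

The generator emulates the tabular, multi-centre evaluation setting so
every app is testable without external downloads. All three tasks share a
linear signal over independent standard-Gaussian features with
alternating-sign, 1/√(1+j)-decaying coefficients scaled by a single effect
parameter: regression adds N(0, σ²) noise; classification draws Bernoulli
labels through the logistic link (an intercept steers class imbalance);
survival draws exponential event times with rate exp(xβ) and independent
Uniform(0, u) censoring, with u calibrated by bisection on
E[(1−e^{−λu})/(λu)] so the realized censoring fraction hits the requested
rate within a few percent. Default shapes follow common benchmark scales
(a 579×10 imbalanced binary cohort, a 442×10 regression cohort, a
12-feature large-n regression cohort downsized to n≈5000 for routine runs;
the full 42,894 figure appears only in the cheap split-arithmetic checks).

Partitioning defaults to the canonical uneven five-silo layout
(10/15/15/30/30 % with floored counts — the floor rule reproduces the
published per-silo counts, which sum to one less than the total, hence the
default drop-remainder policy). IID mode shuffles and cuts; label-skew
mode steers each party's class mix toward a rotating dominant class by a
strength in [0,1], drawing without replacement from the pooled class
pools. What the generator does *not* emulate: correlated or heavy-tailed
features, covariate shift between silos, missingness, or the covariance
structure of any real clinical dataset — so passing tests certify the
*federation algebra* (federated equals pooled) and qualitative non-IID
behaviour, not real-data performance levels.

## Numerical and design choices

* Convergence is judged on max|Δβ| (β-change), not log-likelihood change;
  both are exposed.
* CV folds are local, per-party, unstratified uniform shuffles (fold sizes
  differ by ≤1); a stratification flag is deliberately absent until a use
  case demands it.
* One-hot encoding shares category *names* with the coordinator — a
  documented disclosure trade-off; counts are never shared.
* Byte accounting prices numeric arrays at 8 bytes/element (little-endian
  float64 blocks) and everything else as canonical JSON.
* Determinism: one workflow seed fans out to per-party streams via
  `SeedSequence.spawn`; identical config + seed gives byte-identical
  reports and logs.
* Dropout handling is abort-and-rerun: a missing submission raises a
  timeout naming the party, and a failing app aborts the workflow with
  the failing step identified. No recovery protocol is attempted.

## Problem sizes in the shipped checks

Routine verification uses cohorts of a few hundred samples, 2–10 features,
1–8 silos, 100-trial sweeps for the GLM equivalences, and 10-fold CV for
the forest comparison; these sizes keep the full suite in the
tens-of-seconds range while exercising every code path. The exact
federation identities are scale-free (they hold to round-off at any n), so
larger cohorts would change only the stochastic comparisons, whose margins
(federated-vs-centralized forest within 0.05 median F1; skewed local
models trailing the federated model) are wide at these sizes.

## Known limitations

* No real networking, Docker isolation, TLS, or web tooling — the
  simulator's scope ends at the algorithm and protocol layer.
* No vertical FL, no cross-device scale, no Cox/Nelson–Aalen/survival-SVM
  estimators, no boosting or SVD apps.
* The secure-aggregation choreography is one standard one-round additive
  scheme; seed-expansion optimizations (per-pair PRG seeds instead of
  explicit shares) are not implemented.
* Logistic regression assumes the pooled data are non-separable for a
  meaningful ML estimate; the ridge fallback keeps the run alive but the
  coefficients are then regularized, and the converged flag reports it.
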