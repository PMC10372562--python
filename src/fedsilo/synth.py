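"""Synthetic datasets and partitions emulating multi-centre tabular
studies.

Three generators share a common linear-signal backbone over standard-
Gaussian features:

* regression:      y = Xβ + ε,  ε ~ N(0, noise_sd²)
* classification:  y ~ Bernoulli(sigmoid(Xβ + intercept))
* survival:        T ~ Exponential(rate = exp(Xβ)), censored by an
                   independent Uniform(0, u) with u calibrated so the
                   realized censoring fraction hits the requested rate.

Default shapes follow common benchmark scales for cross-silo studies: a
~579×10 binary-classification set, a ~442×10 regression set, and a large
(tens of thousands of rows) 12-feature regression set for deep-learning
experiments.

Partitioning reproduces the canonical uneven five-silo layout
(10/15/15/30/30 % of samples) either IID (shuffle, then cut) or with label
skew, where each party's class mix interpolates between the global mix and
single-class dominance — the regime in which locally trained models stop
generalizing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .preprocess import RemainderPolicy, plan_split

__all__ = [
    "DatasetSpec",
    "PartitionSpec",
    "PartyDataset",
    "generate",
    "partition",
    "DEFAULT_PROPORTIONS",
]

DEFAULT_PROPORTIONS = (0.10, 0.15, 0.15, 0.30, 0.30)


@dataclass(frozen=True)
class DatasetSpec:
    task: Literal["classification", "regression", "survival"]
    n_samples: int = 579
    n_features: int = 10
    effect: float = 1.0  # scales the coefficient vector
    noise_sd: float = 1.0
    censoring_rate: float = 0.3  # survival only
    intercept: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least two samples")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")


@dataclass(frozen=True)
class PartitionSpec:
    proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    mode: Literal["iid", "label_skew"] = "iid"
    skew_strength: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.skew_strength <= 1:
            raise ValueError("skew_strength must lie in [0, 1]")


@dataclass
class PartyDataset:
    """One silo's local table; it never leaves the party in a message."""

    party_id: int
    frame: pd.DataFrame
    feature_columns: list[str] = field(default_factory=list)
    label_column: str = "label"

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.feature_columns].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame[self.label_column].to_numpy(dtype=float)


def _coefficients(spec: DatasetSpec, rng: np.random.Generator) -> np.ndarray:
    """Alternating-sign, decaying coefficients scaled by the effect size —
    a fixed signal shape so reruns differ only through the seed."""
    j = np.arange(spec.n_features)
    beta = (-1.0) ** j / np.sqrt(1.0 + j)
    return spec.effect * beta


def generate(spec: DatasetSpec) -> pd.DataFrame:
    """Draw one pooled dataset according to the spec.

    Columns: x0..x{p-1} features, then task-specific targets
    (``label`` for classification/regression; ``time``/``event`` for
    survival).
    """
    rng = np.random.default_rng(spec.seed)
    X = rng.standard_normal((spec.n_samples, spec.n_features))
    beta = _coefficients(spec, rng)
    lin = X @ beta + spec.intercept
    cols = {f"x{j}": X[:, j] for j in range(spec.n_features)}

    if spec.task == "regression":
        cols["label"] = lin + rng.normal(0.0, spec.noise_sd, spec.n_samples)
    elif spec.task == "classification":
        p = 1.0 / (1.0 + np.exp(-lin))
        cols["label"] = (rng.random(spec.n_samples) < p).astype(int)
    else:  # survival
        rate = np.exp(np.clip(lin, -20, 20))
        t_event = rng.exponential(1.0 / rate)
        if spec.censoring_rate > 0:
            u = _calibrate_censoring(rate, spec.censoring_rate)
            t_cens = rng.uniform(0.0, u, spec.n_samples)
            observed = np.minimum(t_event, t_cens)
            event = (t_event <= t_cens).astype(int)
        else:
            observed, event = t_event, np.ones(spec.n_samples, dtype=int)
        cols["time"] = observed
        cols["event"] = event
    return pd.DataFrame(cols)


def _calibrate_censoring(rate: np.ndarray, target: float) -> float:
    """Find the Uniform(0, u) upper bound whose expected censoring
    fraction matches ``target`` for this draw of subject rates.

    A subject is censored when C < T, so averaging over C ~ U(0, u):
    P(censored | λ, u) = E[e^{−λC}] = (1 − e^{−λu})/(λu), which decreases
    monotonically in u — bisection converges.
    """

    def frac(u: float) -> float:
        lu = rate * u
        return float(np.mean((1.0 - np.exp(-lu)) / lu))

    lo, hi = 1e-9, 1.0
    while frac(hi) > target:
        hi *= 2.0
        if hi > 1e12:
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def partition(
    dataset: pd.DataFrame,
    pspec: PartitionSpec,
    label_column: str = "label",
) -> list[PartyDataset]:
    """Split the pooled table into per-party tables.

    IID mode shuffles then cuts at the planned counts (floored
    proportions; leftover rows dropped).  Label-skew mode biases each
    party's class mix toward a dominant class (assigned round-robin) by
    ``skew_strength``: 0 reproduces the global mix, 1 makes parties as
    single-class as the pooled class counts allow.
    """
    rng = np.random.default_rng(pspec.seed)
    n = len(dataset)
    plan = plan_split(n, list(pspec.proportions), RemainderPolicy.DROP)
    if any(c == 0 for c in plan.counts):
        raise ValueError(f"a party would receive 0 samples: {plan.counts}")

    feature_cols = [c for c in dataset.columns if c.startswith("x")]

    if pspec.mode == "iid":
        order = rng.permutation(n)
        assignments: list[np.ndarray] = []
        start = 0
        for c in plan.counts:
            assignments.append(order[start : start + c])
            start += c
    else:
        assignments = _label_skew_assign(
            dataset[label_column].to_numpy(), plan.counts,
            pspec.skew_strength, rng,
        )

    parties = []
    for pid, idx in enumerate(assignments):
        frame = dataset.iloc[np.sort(idx)].reset_index(drop=True)
        parties.append(
            PartyDataset(
                party_id=pid,
                frame=frame,
                feature_columns=feature_cols,
                label_column=label_column,
            )
        )
    return parties


def _label_skew_assign(
    labels: np.ndarray,
    counts: tuple[int, ...],
    strength: float,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Greedy class-targeted assignment.

    Target class mix of party i: (1−s)·global + s·one_hot(dominant class),
    dominant classes rotating over parties.  Actual draws are without
    replacement from the pooled class pools, so targets degrade gracefully
    when a class runs out.
    """
    classes = np.unique(labels)
    k = len(classes)
    global_mix = np.array([(labels == c).mean() for c in classes])
    pools = {
        c: list(rng.permutation(np.where(labels == c)[0])) for c in classes
    }
    out: list[np.ndarray] = []
    for pid, c_total in enumerate(counts):
        dominant = pid % k
        mix = (1 - strength) * global_mix
        mix[dominant] += strength
        want = np.floor(mix * c_total).astype(int)
        # distribute the rounding shortfall, dominant class first
        while want.sum() < c_total:
            want[dominant] += 1
            dominant = (dominant + 1) % k
        taken: list[int] = []
        for ci, c in enumerate(classes):
            pool = pools[c]
            take = min(want[ci], len(pool))
            taken.extend(pool[:take])
            pools[c] = pool[take:]
        # backfill from whatever classes still have samples
        short = c_total - len(taken)
        if short > 0:
            leftovers = [i for c in classes for i in pools[c]]
            rng.shuffle(leftovers)
            taken.extend(leftovers[:short])
            used = set(taken)
            for c in classes:
                pools[c] = [i for i in pools[c] if i not in used]
        out.append(np.array(taken, dtype=int))
    return out
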