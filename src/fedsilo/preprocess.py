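"""Preprocessing apps: split planning, federated standardization, local
k-fold cross-validation, and federated one-hot encoding.

Standardization federates through per-party moment triples (n, Σx, Σx²):
these are summable across silos, so the coordinator can form the pooled
mean and sample standard deviation exactly, and each party then transforms
its rows locally.  The result is identical to standardizing the pooled
data centrally.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "RemainderPolicy",
    "SplitPlan",
    "MomentStats",
    "FoldAssignment",
    "plan_split",
    "federated_standardize",
    "local_kfold",
    "federated_one_hot",
]


class RemainderPolicy(str, Enum):
    """What to do with samples left over after floor allocation."""

    DROP = "drop"
    ASSIGN_LAST = "assign_last"


@dataclass(frozen=True)
class SplitPlan:
    n_total: int
    proportions: tuple[float, ...]
    counts: tuple[int, ...]
    remainder_policy: RemainderPolicy

    @property
    def n_allocated(self) -> int:
        return sum(self.counts)


def plan_split(
    n_total: int,
    proportions: list[float],
    remainder_policy: RemainderPolicy | str = RemainderPolicy.DROP,
) -> SplitPlan:
    """Allocate ``n_total`` samples to parties by floored proportions.

    Each party receives ``floor(p_i * n_total)`` samples.  Any remainder is
    either dropped (default; a few samples go unused) or appended to the
    last party.
    """
    remainder_policy = RemainderPolicy(remainder_policy)
    props = np.asarray(proportions, dtype=float)
    if np.any(props <= 0):
        raise ValueError("proportions must be positive")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {props.sum()!r}")
    counts = [int(np.floor(p * n_total)) for p in props]
    remainder = n_total - sum(counts)
    if remainder_policy is RemainderPolicy.ASSIGN_LAST and remainder > 0:
        counts[-1] += remainder
    return SplitPlan(
        n_total=n_total,
        proportions=tuple(float(p) for p in props),
        counts=tuple(counts),
        remainder_policy=remainder_policy,
    )


@dataclass(frozen=True)
class MomentStats:
    """One party's summable first and second moments per feature."""

    n: int
    sum: np.ndarray
    sumsq: np.ndarray

    @classmethod
    def from_data(cls, X: np.ndarray) -> "MomentStats":
        X = np.asarray(X, dtype=float)
        return cls(n=X.shape[0], sum=X.sum(axis=0), sumsq=(X**2).sum(axis=0))

    def as_vector(self) -> np.ndarray:
        """Flatten to [n, Σx, Σx²] for (secure) summation."""
        return np.concatenate([[float(self.n)], self.sum, self.sumsq])

    @classmethod
    def from_vector(cls, v: np.ndarray, p: int) -> "MomentStats":
        return cls(n=int(round(v[0])), sum=v[1 : 1 + p], sumsq=v[1 + p :])


def federated_standardize(
    local_stats: list[MomentStats],
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled mean and sample std (Bessel n−1) from per-party moments.

    Zero-variance features get std 1 with a warning, so a constant column
    passes through centred (all zeros) instead of dividing by zero.
    """
    if not local_stats:
        raise ValueError("no moment statistics supplied")
    dims = {len(s.sum) for s in local_stats}
    if len(dims) != 1:
        raise ValueError(f"feature-dimension mismatch across parties: {dims}")
    n = sum(s.n for s in local_stats)
    if n < 2:
        raise ValueError("pooled sample count must be >= 2")
    total = np.sum([s.sum for s in local_stats], axis=0)
    totalsq = np.sum([s.sumsq for s in local_stats], axis=0)
    mean = total / n
    var = (totalsq - total**2 / n) / (n - 1)
    var = np.maximum(var, 0.0)  # guard tiny negative round-off
    std = np.sqrt(var)
    zero = std <= 0
    if np.any(zero):
        warnings.warn(
            f"zero-variance feature(s) at index {np.where(zero)[0].tolist()}: "
            "std set to 1, column passes through centred",
            stacklevel=2,
        )
        std = np.where(zero, 1.0, std)
    return mean, std


def apply_standardize(
    X: np.ndarray, mean: np.ndarray, std: np.ndarray
) -> np.ndarray:
    """Local transform with globally agreed parameters."""
    return (np.asarray(X, dtype=float) - mean) / std


@dataclass(frozen=True)
class FoldAssignment:
    k: int
    fold_of_sample: np.ndarray

    def train_index(self, fold: int) -> np.ndarray:
        return np.where(self.fold_of_sample != fold)[0]

    def test_index(self, fold: int) -> np.ndarray:
        return np.where(self.fold_of_sample == fold)[0]


def local_kfold(n_local: int, k: int, seed: int) -> FoldAssignment:
    """Shuffled, balanced k-fold assignment of one party's rows.

    Fold sizes differ by at most one; folds are unstratified.  Each party
    draws its own assignment — splits are local, never coordinated.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_local < k:
        raise ValueError(f"cannot split {n_local} samples into {k} folds")
    rng = np.random.default_rng(seed)
    folds = np.arange(n_local) % k
    rng.shuffle(folds)
    return FoldAssignment(k=k, fold_of_sample=folds)


def federated_one_hot(local_category_sets: list[set[str]]) -> list[str]:
    """Global category order: the sorted union of per-party label sets.

    Every party encodes against this shared list, so encoded matrices have
    identical columns everywhere; categories absent at a party encode as
    all-zero columns.  Sharing label *names* (not counts) with the
    coordinator is a deliberate, documented privacy trade-off.
    """
    union: set[str] = set()
    for s in local_category_sets:
        union |= set(s)
    if not union:
        raise ValueError("no categories found at any party")
    return sorted(union)


def one_hot_encode(values: list[str], categories: list[str]) -> np.ndarray:
    index = {c: j for j, c in enumerate(categories)}
    out = np.zeros((len(values), len(categories)))
    for i, v in enumerate(values):
        if v in index:
            out[i, index[v]] = 1.0
    return out
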