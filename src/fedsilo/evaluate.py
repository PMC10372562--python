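"""Federated evaluation: global metrics from summable local statistics.

Classification needs only each party's confusion matrix; regression needs
only (n, Σ squared error, Σ absolute error).  Both are exact under
summation — the global F1 or RMSE computed from aggregated counts equals
the metric on the pooled predictions — so no labels or predictions ever
cross a silo boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "ErrorSums",
    "aggregate_confusion",
    "f1_from_confusion",
    "rmse_from_sums",
    "cv_report",
]


@dataclass
class ConfusionCounts:
    """k×k confusion matrix (rows: true, columns: predicted)."""

    labels: list
    counts: np.ndarray

    @classmethod
    def from_predictions(
        cls, y_true: np.ndarray, y_pred: np.ndarray, labels: list
    ) -> "ConfusionCounts":
        index = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for t, p in zip(y_true, y_pred):
            counts[index[t], index[p]] += 1
        return cls(labels=list(labels), counts=counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def reindexed(self, labels: list) -> "ConfusionCounts":
        """Embed into a larger (unioned) label set."""
        out = np.zeros((len(labels), len(labels)), dtype=int)
        pos = {lab: i for i, lab in enumerate(labels)}
        for i, li in enumerate(self.labels):
            for j, lj in enumerate(self.labels):
                out[pos[li], pos[lj]] = self.counts[i, j]
        return ConfusionCounts(labels=list(labels), counts=out)


@dataclass
class ErrorSums:
    """Summable regression-error statistics."""

    n: int
    sse: float
    sae: float

    @classmethod
    def from_predictions(
        cls, y_true: np.ndarray, y_pred: np.ndarray
    ) -> "ErrorSums":
        r = np.asarray(y_true, dtype=float) - np.asarray(y_pred, dtype=float)
        return cls(n=len(r), sse=float(np.sum(r**2)),
                   sae=float(np.sum(np.abs(r))))

    def as_vector(self) -> np.ndarray:
        return np.array([float(self.n), self.sse, self.sae])

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "ErrorSums":
        return cls(n=int(round(v[0])), sse=float(v[1]), sae=float(v[2]))


def aggregate_confusion(
    parts: list[ConfusionCounts],
) -> ConfusionCounts:
    """Sum confusion matrices over the unioned, reindexed label set."""
    if not parts:
        raise ValueError("no confusion matrices supplied")
    labels = sorted({lab for p in parts for lab in p.labels})
    total = np.zeros((len(labels), len(labels)), dtype=int)
    for p in parts:
        total += p.reindexed(labels).counts
    return ConfusionCounts(labels=labels, counts=total)


def f1_from_confusion(cm: ConfusionCounts, positive_label) -> float:
    """Binary F1 for the positive class: 2TP / (2TP + FP + FN); 0 by
    convention when the denominator vanishes."""
    if positive_label not in cm.labels:
        raise ValueError(f"label {positive_label!r} not in {cm.labels}")
    i = cm.labels.index(positive_label)
    tp = cm.counts[i, i]
    fp = cm.counts[:, i].sum() - tp
    fn = cm.counts[i, :].sum() - tp
    denom = 2 * tp + fp + fn
    return 0.0 if denom == 0 else float(2 * tp / denom)


def macro_f1(cm: ConfusionCounts) -> float:
    """Unweighted mean of per-class F1 scores."""
    return float(
        np.mean([f1_from_confusion(cm, lab) for lab in cm.labels])
    )


def rmse_from_sums(es: ErrorSums) -> float:
    if es.n < 1:
        raise ValueError("need at least one prediction")
    return float(np.sqrt(es.sse / es.n))


def cv_report(per_fold_metrics: dict[int, float]) -> dict:
    """Distribution summary of a per-fold metric (median, quartiles)."""
    if not per_fold_metrics:
        raise ValueError("no folds to summarize")
    folds = sorted(per_fold_metrics)
    values = np.array([per_fold_metrics[f] for f in folds], dtype=float)
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {
        "per_fold": {int(f): float(per_fold_metrics[f]) for f in folds},
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "mean": float(values.mean()),
        "min": float(values.min()),
        "max": float(values.max()),
        "n_folds": len(folds),
    }
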