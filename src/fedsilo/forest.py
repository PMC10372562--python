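"""Federated random forest via ensemble merging.

Three-step protocol: (1) parties report local sample counts and the
coordinator apportions the fixed global tree budget proportionally;
(2) each party trains its quota of unpruned trees on bootstrap resamples of
its local data and ships them; (3) the coordinator concatenates the trees
into one global forest of constant size, which every party then evaluates
locally.  More parties means fewer trees per party, never a bigger model.

Trees are grown with scikit-learn (Gini / variance splitting, √p feature
sampling, no prepruning) and serialized to a nested-JSON node format for
transport and inspection; prediction over the merged ensemble is majority
vote (classification) or mean (regression).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

logger = logging.getLogger(__name__)

__all__ = [
    "TreeSpec",
    "TreeAllocation",
    "GlobalEnsemble",
    "allocate_trees",
    "train_local_trees",
    "merge_forests",
    "tree_to_dict",
    "predict_tree_dict",
]


@dataclass(frozen=True)
class TreeSpec:
    """Forest hyperparameters: defaults mirror a stock sklearn forest."""

    task: Literal["classification", "regression"] = "classification"
    n_trees_global: int = 100
    max_features: str = "sqrt"
    # splitting rule is implied by task: Gini / variance reduction


@dataclass(frozen=True)
class TreeAllocation:
    sample_counts: tuple[int, ...]
    trees_per_party: tuple[int, ...]

    @property
    def total_n(self) -> int:
        return sum(self.sample_counts)


def allocate_trees(
    sample_counts: list[int], n_trees_global: int = 100
) -> TreeAllocation:
    """Largest-remainder apportionment of the global tree budget.

    Each party's quota is proportional to its local sample count; floors
    are taken first and the leftover trees go to the largest fractional
    remainders (ties broken by party index), so the quotas always sum to
    exactly ``n_trees_global``.
    """
    counts = [int(c) for c in sample_counts]
    if any(c < 1 for c in counts):
        raise ValueError("every party must hold at least one sample")
    total = sum(counts)
    quotas = [n_trees_global * c / total for c in counts]
    floors = [int(np.floor(q)) for q in quotas]
    leftover = n_trees_global - sum(floors)
    # stable sort: largest remainder first, then lowest party_id
    order = sorted(
        range(len(counts)), key=lambda i: (-(quotas[i] - floors[i]), i)
    )
    for i in order[:leftover]:
        floors[i] += 1
    if 0 in floors:
        warnings.warn(
            "some parties were allocated zero trees "
            f"(counts={counts}, budget={n_trees_global})",
            stacklevel=2,
        )
    return TreeAllocation(
        sample_counts=tuple(counts), trees_per_party=tuple(floors)
    )


# ---------------------------------------------------------------------------
# Tree serialization: nested JSON of split nodes, portable across parties.
# ---------------------------------------------------------------------------

def tree_to_dict(tree, task: str, class_labels: list | None = None) -> dict:
    """Convert a fitted sklearn decision tree to a nested node dict."""
    t = tree.tree_

    def node(i: int) -> dict:
        if t.children_left[i] == -1:  # leaf
            if task == "classification":
                counts = t.value[i][0] * t.weighted_n_node_samples[i]
                best = int(np.argmax(t.value[i][0]))
                return {
                    "leaf": True,
                    "class_index": best,
                    "counts": [float(c) for c in counts],
                }
            return {"leaf": True, "value": float(t.value[i][0][0])}
        return {
            "leaf": False,
            "feature": int(t.feature[i]),
            "threshold": float(t.threshold[i]),
            "left": node(int(t.children_left[i])),
            "right": node(int(t.children_right[i])),
        }

    out = {"task": task, "root": node(0)}
    if class_labels is not None:
        out["class_labels"] = list(class_labels)
    return out


def strip_cache(tree_dict: dict) -> dict:
    """Drop the transient flattened-array cache before serialization."""
    return {k: v for k, v in tree_dict.items() if k != "_flat"}


def _flatten_tree(tree_dict: dict) -> tuple[np.ndarray, ...]:
    """Linearize the nested node dict into parallel arrays for vectorized
    traversal (leaves get feature = −1)."""
    feature, threshold, left, right, value = [], [], [], [], []
    labels = tree_dict.get("class_labels")

    def visit(node: dict) -> int:
        idx = len(feature)
        if node["leaf"]:
            feature.append(-1)
            threshold.append(0.0)
            left.append(-1)
            right.append(-1)
            if tree_dict["task"] == "classification":
                value.append(float(labels[node["class_index"]]))
            else:
                value.append(float(node["value"]))
        else:
            feature.append(node["feature"])
            threshold.append(node["threshold"])
            left.append(-2)  # patched below
            right.append(-2)
            value.append(0.0)
            left[idx] = visit(node["left"])
            right[idx] = visit(node["right"])
        return idx

    visit(tree_dict["root"])
    return (
        np.asarray(feature, dtype=np.int64),
        np.asarray(threshold, dtype=float),
        np.asarray(left, dtype=np.int64),
        np.asarray(right, dtype=np.int64),
        np.asarray(value, dtype=float),
    )


def predict_tree_dict(tree_dict: dict, X: np.ndarray) -> np.ndarray:
    """Predict from a serialized tree (label for classification, value
    for regression)."""
    X = np.asarray(X, dtype=float)
    feature, threshold, left, right, value = tree_dict.get(
        "_flat"
    ) or _flatten_tree(tree_dict)
    if "_flat" not in tree_dict:
        tree_dict["_flat"] = (feature, threshold, left, right, value)
    node = np.zeros(X.shape[0], dtype=np.int64)
    active = feature[node] >= 0
    while np.any(active):
        idx = node[active]
        go_left = (
            X[active, feature[idx]] <= threshold[idx]
        )
        node[active] = np.where(go_left, left[idx], right[idx])
        active = feature[node] >= 0
    return value[node]


def train_local_trees(
    X: np.ndarray,
    y: np.ndarray,
    spec: TreeSpec,
    n_trees: int,
    seed: int,
) -> list[dict]:
    """Train this party's quota of unpruned trees on bootstrap resamples.

    A party whose local data holds a single class still produces valid
    (constant-prediction) trees, with a logged warning — its contribution
    is diluted by the vote over the full merged ensemble.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if n_trees == 0:
        return []
    if X.shape[0] == 0:
        raise ValueError("cannot train trees on an empty local dataset")
    if spec.task == "classification" and len(np.unique(y)) == 1:
        logger.warning(
            "single-class local data: trees will predict class %r "
            "everywhere", y[0]
        )
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    trees = []
    for t in range(n_trees):
        idx = rng.integers(0, n, size=n)  # bootstrap resample
        tree_seed = int(rng.integers(0, 2**31 - 1))
        if spec.task == "classification":
            est = DecisionTreeClassifier(
                criterion="gini",
                max_features=spec.max_features,
                random_state=tree_seed,
            )
        else:
            est = DecisionTreeRegressor(
                criterion="squared_error",
                max_features=spec.max_features,
                random_state=tree_seed,
            )
        est.fit(X[idx], y[idx])
        labels = (
            [float(c) for c in est.classes_]
            if spec.task == "classification"
            else None
        )
        trees.append(tree_to_dict(est, spec.task, labels))
    return trees


@dataclass
class GlobalEnsemble:
    """The merged forest: serialized trees plus per-tree provenance."""

    trees: list[dict]
    origins: list[int]
    task: str
    class_labels: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trees)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Majority vote across trees (classification) or mean of tree
        predictions (regression)."""
        X = np.asarray(X, dtype=float)
        preds = np.stack([predict_tree_dict(t, X) for t in self.trees])
        if self.task == "classification":
            labels = np.asarray(self.class_labels, dtype=float)
            votes = np.stack([(preds == c).sum(axis=0) for c in labels])
            return labels[np.argmax(votes, axis=0)]
        return preds.mean(axis=0)

    def to_json(self) -> str:
        return json.dumps(
            {
                "task": self.task,
                "class_labels": list(self.class_labels),
                "origins": self.origins,
                "trees": [strip_cache(t) for t in self.trees],
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "GlobalEnsemble":
        d = json.loads(s)
        return cls(
            trees=d["trees"],
            origins=d["origins"],
            task=d["task"],
            class_labels=d["class_labels"],
        )


def merge_forests(
    allocation: TreeAllocation,
    local_tree_lists: list[list[dict]],
    task: str = "classification",
) -> GlobalEnsemble:
    """Concatenate per-party tree lists into the constant-size ensemble.

    Class-label sets that differ across parties are unioned; each tree
    votes only over the labels it knows.
    """
    for quota, trees in zip(allocation.trees_per_party, local_tree_lists):
        if quota != len(trees):
            raise ValueError(
                f"party shipped {len(trees)} trees, allocation says {quota}"
            )
    merged: list[dict] = []
    origins: list[int] = []
    labels: set = set()
    for pid, trees in enumerate(local_tree_lists):
        for t in trees:
            merged.append(t)
            origins.append(pid)
            labels |= set(t.get("class_labels") or [])
    return GlobalEnsemble(
        trees=merged,
        origins=origins,
        task=task,
        class_labels=sorted(labels),
    )
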