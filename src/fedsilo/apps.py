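"""Registry apps: the runnable units a workflow chains together.

Each app maps one federated algorithm onto the engine's round protocol.
The cross-validation app assigns purely local folds; every downstream app
then works fold by fold — federated standardization, model fitting and
evaluation are repeated per split, and the evaluation app finishes with a
cross-validation report.  Apps exchange only the summable or serialized
statistics their algorithm needs (moments, Gram blocks, gradient/Hessian
pairs, serialized trees, weighted parameter vectors, confusion/error
counts, event tables); party-local data and intermediate per-fold arrays
stay in the local slot store.
"""

from __future__ import annotations

from typing import Any

import numpy as np

from . import deep, evaluate, forest, glm, preprocess, survival
from .engine import (
    FederatedApp,
    Gathered,
    Opaque,
    PartyState,
    Summable,
    register_app,
)
from .synth import PartyDataset

__all__ = ["FoldedData"]


class FoldedData:
    """Per-party view of the working data: arrays plus (optional) folds.

    ``per_fold(f)`` yields the train/test row indices of fold f; with no
    fold assignment there is a single pseudo-fold covering all rows (train
    == test == everything), which lets fold-agnostic apps run unchanged.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        feature_names: list[str],
        folds: preprocess.FoldAssignment | None = None,
        extra: dict[str, np.ndarray] | None = None,
    ):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.feature_names = list(feature_names)
        self.folds = folds
        self.extra = extra or {}
        self.models: dict[int, Any] = {}

    @classmethod
    def from_dataset(cls, ds: PartyDataset) -> "FoldedData":
        extra = {}
        for col in ds.frame.columns:
            keep = col in ("time", "event", "group") or (
                ds.frame[col].dtype == object
                and col not in ds.feature_columns
                and col != ds.label_column
            )
            if keep:
                extra[col] = ds.frame[col].to_numpy()
        if ds.label_column in ds.frame.columns:
            y = ds.y
        else:
            y = np.zeros(len(ds.frame))
        return cls(
            X=ds.X, y=y, feature_names=list(ds.feature_columns),
            extra=extra,
        )

    @property
    def k(self) -> int:
        return self.folds.k if self.folds is not None else 1

    def train_index(self, fold: int) -> np.ndarray:
        if self.folds is None:
            return np.arange(len(self.y))
        return self.folds.train_index(fold)

    def test_index(self, fold: int) -> np.ndarray:
        if self.folds is None:
            return np.arange(len(self.y))
        return self.folds.test_index(fold)

    def shallow_copy(self) -> "FoldedData":
        out = FoldedData(
            self.X, self.y, self.feature_names, self.folds,
            dict(self.extra),
        )
        out.models = dict(self.models)
        return out


def _working(state: PartyState, params: dict) -> FoldedData:
    slot = params["_consumes"]
    data = state.slots[slot]
    if isinstance(data, PartyDataset):
        data = FoldedData.from_dataset(data)
        state.slots[slot] = data
    return data


@register_app
class IdentityApp(FederatedApp):
    """Pass-through app: local output equals local input."""

    name = "identity"

    def participant_phase(self, state, broadcast_in, params, round_idx):
        return {"ack": Opaque(0, "ack")}

    def coordinator_phase(self, gathered, params, n_parties):
        return None, True

    def finalize_party(self, state, final_broadcast, params):
        return state.slots[params["_consumes"]]


@register_app
class CrossValidationApp(FederatedApp):
    """Local k-fold split assignment (default k=10, unstratified)."""

    name = "cv"

    def participant_phase(self, state, broadcast_in, params, round_idx):
        data = _working(state, params)
        k = int(params.get("k", 10))
        data.folds = preprocess.local_kfold(len(data.y), k, state.seed)
        return {"ack": Opaque(len(data.y), "sample_count")}

    def coordinator_phase(self, gathered, params, n_parties):
        self._n_total = int(sum(gathered.items["ack"]))
        return None, True

    def finalize_party(self, state, final_broadcast, params):
        return state.slots[params["_consumes"]]

    def report(self):
        return {"n_total": getattr(self, "_n_total", None)}


@register_app
class NormalizationApp(FederatedApp):
    """Federated standardization, fit per fold on the training rows.

    Round f: parties submit the summable moment triple of fold f's train
    rows; the coordinator returns the pooled mean/std, which parties apply
    locally to both train and test rows of that fold.
    """

    name = "normalization"

    def __init__(self) -> None:
        self._scalers: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def participant_phase(self, state, broadcast_in, params, round_idx):
        data = _working(state, params)
        if broadcast_in is not None:
            f = broadcast_in["fold"]
            state.local.setdefault("scalers", {})[f] = (
                np.asarray(broadcast_in["mean"]),
                np.asarray(broadcast_in["std"]),
            )
        if round_idx >= data.k:
            return {"ack": Opaque(0, "ack")}
        idx = data.train_index(round_idx)
        stats = preprocess.MomentStats.from_data(data.X[idx])
        return {"moments": Summable(stats.as_vector(), "moments")}

    def coordinator_phase(self, gathered, params, n_parties):
        if "moments" not in gathered.sums:
            return None, True
        v = gathered.sums["moments"]
        p = (len(v) - 1) // 2
        pooled = preprocess.MomentStats.from_vector(v, p)
        mean, std = preprocess.federated_standardize([pooled])
        self._scalers[gathered.round] = (mean, std)
        return {
            "fold": gathered.round,
            "mean": mean.tolist(),
            "std": std.tolist(),
        }, False

    def finalize_party(self, state, final_broadcast, params):
        data = _working(state, params)
        out = data.shallow_copy()
        out.scalers = state.local.pop("scalers")
        return out

    def report(self):
        return {"folds_standardized": len(self._scalers)}


@register_app
class OneHotApp(FederatedApp):
    """Federated one-hot encoding of a categorical column.

    Parties submit their local category-label sets; the coordinator
    broadcasts the sorted union, so every party's encoded matrix gains
    identical columns in identical order (all-zero where a category is
    absent locally).  Category *names* — not counts — reach the
    coordinator: a small, documented disclosure.
    """

    name = "one_hot"

    def __init__(self) -> None:
        self._categories: list[str] = []

    def participant_phase(self, state, broadcast_in, params, round_idx):
        data = _working(state, params)
        column = params["column"]
        if broadcast_in is None:
            local = sorted(set(str(v) for v in data.extra[column]))
            return {"categories": Opaque(local, "category_set")}
        cats = broadcast_in["categories"]
        state.local["one_hot"] = (
            preprocess.one_hot_encode(
                [str(v) for v in data.extra[column]], cats
            ),
            cats,
        )
        return {"ack": Opaque(0, "ack")}

    def coordinator_phase(self, gathered, params, n_parties):
        if "categories" in gathered.items:
            self._categories = preprocess.federated_one_hot(
                [set(s) for s in gathered.items["categories"]]
            )
            return {"categories": self._categories}, False
        return None, True

    def finalize_party(self, state, final_broadcast, params):
        data = _working(state, params)
        encoded, cats = state.local.pop("one_hot")
        column = params["column"]
        out = FoldedData(
            X=np.hstack([data.X, encoded]),
            y=data.y,
            feature_names=data.feature_names
            + [f"{column}={c}" for c in cats],
            folds=data.folds,
            extra={k: v for k, v in data.extra.items() if k != column},
        )
        out.models = dict(data.models)
        return out

    def report(self):
        return {"categories": list(self._categories)}


def _fold_arrays(data: FoldedData, fold: int, train: bool):
    """Fold-f rows, standardized with fold-f parameters when available."""
    idx = data.train_index(fold) if train else data.test_index(fold)
    X = data.X[idx]
    scalers = getattr(data, "scalers", None)
    if scalers is not None:
        mean, std = scalers[fold]
        X = preprocess.apply_standardize(X, mean, std)
    return X, data.y[idx]


def _with_intercept(X: np.ndarray) -> np.ndarray:
    return np.hstack([np.ones((X.shape[0], 1)), X])


@register_app
class LinearRegressionApp(FederatedApp):
    """One-shot exact federated linear regression, per fold."""

    name = "linear_regression"

    def __init__(self) -> None:
        self._betas: dict[int, np.ndarray] = {}

    def participant_phase(self, state, broadcast_in, params, round_idx):
        data = _working(state, params)
        if broadcast_in is not None:
            state.local.setdefault("linear_models", {})[
                broadcast_in["fold"]
            ] = np.asarray(broadcast_in["beta"])
        if round_idx >= data.k:
            return {"ack": Opaque(0, "ack")}
        X, y = _fold_arrays(data, round_idx, train=True)
        if params.get("intercept", True):
            X = _with_intercept(X)
        g = glm.local_gram(glm.DesignMatrix(X=X, y=y))
        return {"gram": Summable(g.as_vector(), "gram")}

    def coordinator_phase(self, gathered, params, n_parties):
        if "gram" not in gathered.sums:
            return None, True
        v = gathered.sums["gram"]
        p = int(round((-1 + np.sqrt(1 + 4 * (len(v) - 1))) / 2))
        pooled = glm.GramStats.from_vector(v, p)
        beta = glm.fit_linear([pooled]).beta
        self._betas[gathered.round] = beta
        return {"fold": gathered.round, "beta": beta.tolist()}, False

    def finalize_party(self, state, final_broadcast, params):
        data = _working(state, params)
        out = data.shallow_copy()
        if hasattr(data, "scalers"):
            out.scalers = data.scalers
        out.models = {
            f: {"kind": "linear", "beta": b,
                "intercept": params.get("intercept", True)}
            for f, b in state.local.pop("linear_models").items()
        }
        return out

    def report(self):
        return {
            "folds_fitted": len(self._betas),
            "beta": {f: b.tolist() for f, b in self._betas.items()},
        }


@register_app
class LogisticRegressionApp(FederatedApp):
    """Iterative federated logistic regression (Newton–Raphson).

    Inner loop per fold: parties submit (gradient, Hessian) at the
    broadcast coefficients; the coordinator sums, steps, and either
    broadcasts the next iterate or advances to the next fold once the
    step size drops below tolerance.
    """

    name = "logistic_regression"

    def __init__(self) -> None:
        self._betas: dict[int, np.ndarray] = {}
        self._iters: dict[int, int] = {}
        self._fold = 0
        self._iteration = 0
        self._beta: np.ndarray | None = None

    def participant_phase(self, state, broadcast_in, params, round_idx):
        data = _working(state, params)
        if broadcast_in is not None and "model_fold" in broadcast_in:
            state.local.setdefault("logistic_models", {})[
                broadcast_in["model_fold"]
            ] = np.asarray(broadcast_in["model_beta"])
        fold = broadcast_in["fold"] if broadcast_in else 0
        if fold >= data.k:
            return {"ack": Opaque(0, "ack")}
        X, y = _fold_arrays(data, fold, train=True)
        if params.get("intercept", True):
            X = _with_intercept(X)
        b_in = broadcast_in["beta"] if broadcast_in else []
        beta = (
            np.asarray(b_in, dtype=float)
            if len(b_in)
            else np.zeros(X.shape[1])
        )
        r = glm.local_logistic_round(glm.DesignMatrix(X=X, y=y), beta)
        return {
            "newton": Summable(r.as_vector(), "newton_stats"),
        }

    def coordinator_phase(self, gathered, params, n_parties):
        if "newton" not in gathered.sums:
            return None, True
        tol = float(params.get("tol", 1e-8))
        max_iter = int(params.get("max_iter", 25))
        v = gathered.sums["newton"]
        p = int(round((-1 + np.sqrt(1 + 4 * len(v))) / 2))
        grad, hess = glm.NewtonRound.split_vector(v, p)
        beta = self._beta if self._beta is not None else np.zeros(p)
        try:
            step = np.linalg.solve(hess, grad)
            if not np.all(np.isfinite(step)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            step = np.linalg.solve(
                hess + glm.HESSIAN_RIDGE * np.eye(p), grad
            )
        beta = beta + step
        self._iteration += 1
        out: dict[str, Any] = {}
        if np.max(np.abs(step)) < tol or self._iteration >= max_iter:
            self._betas[self._fold] = beta
            self._iters[self._fold] = self._iteration
            out["model_fold"] = self._fold
            out["model_beta"] = beta.tolist()
            self._fold += 1
            self._iteration = 0
            self._beta = None
            out["fold"] = self._fold
            out["beta"] = []  # reset; participants rebuild zeros next fold
            return out, False
        self._beta = beta
        return {"fold": self._fold, "beta": beta.tolist()}, False

    def finalize_party(self, state, final_broadcast, params):
        data = _working(state, params)
        out = data.shallow_copy()
        if hasattr(data, "scalers"):
            out.scalers = data.scalers
        out.models = {
            f: {"kind": "logistic", "beta": b,
                "intercept": params.get("intercept", True)}
            for f, b in state.local.pop("logistic_models").items()
        }
        return out

    def report(self):
        return {
            "folds_fitted": len(self._betas),
            "iterations": dict(self._iters),
        }


@register_app
class RandomForestApp(FederatedApp):
    """Three-step federated random forest, per fold.

    Step 1: parties report local training-sample counts and receive the
    proportional tree allocation.  Step 2: parties train their quota of
    unpruned trees on bootstrap resamples and ship the serialized trees;
    the coordinator concatenates them into the constant-size global
    forest and broadcasts it.  (Step 3, evaluation, is the evaluation
    app's job.)
    """

    name = "random_forest"

    def __init__(self) -> None:
        self._fold = 0
        self._phase = "counts"
        self._allocation = None
        self._sizes: dict[int, int] = {}

    def participant_phase(self, state, broadcast_in, params, round_idx):
        data = _working(state, params)
        spec = forest.TreeSpec(
            task=params.get("task", "classification"),
            n_trees_global=int(params.get("n_trees", 100)),
        )
        if broadcast_in is not None and "forest" in broadcast_in:
            state.local.setdefault("forest_models", {})[
                broadcast_in["fold"]
            ] = forest.GlobalEnsemble.from_json(broadcast_in["forest"])
        fold = broadcast_in["next_fold"] if broadcast_in else 0
        phase = broadcast_in["phase"] if broadcast_in else "counts"
        if fold >= data.k:
            return {"ack": Opaque(0, "ack")}
        if phase == "counts":
            n_train = len(data.train_index(fold))
            return {"count": Opaque(n_train, "sample_count")}
        # training phase: quota received in the allocation broadcast
        quota = broadcast_in["allocation"][state.party_id]
        X, y = _fold_arrays(data, fold, train=True)
        trees = forest.train_local_trees(
            X, y, spec, quota, seed=state.seed + 7919 * fold
        )
        return {
            "trees": Opaque([forest.strip_cache(t) for t in trees], "trees")
        }

    def coordinator_phase(self, gathered, params, n_parties):
        task = params.get("task", "classification")
        n_trees = int(params.get("n_trees", 100))
        if "count" in gathered.items:
            counts = [int(c) for c in gathered.items["count"]]
            self._allocation = forest.allocate_trees(counts, n_trees)
            return {
                "phase": "train",
                "next_fold": self._fold,
                "allocation": list(self._allocation.trees_per_party),
                "n_total": self._allocation.total_n,
            }, False
        if "trees" in gathered.items:
            ensemble = forest.merge_forests(
                self._allocation, gathered.items["trees"], task
            )
            self._sizes[self._fold] = len(ensemble)
            out = {
                "phase": "counts",
                "fold": self._fold,
                "forest": ensemble.to_json(),
            }
            self._fold += 1
            out["next_fold"] = self._fold
            return out, False
        return None, True

    def finalize_party(self, state, final_broadcast, params):
        data = _working(state, params)
        out = data.shallow_copy()
        if hasattr(data, "scalers"):
            out.scalers = data.scalers
        out.models = {
            f: {"kind": "forest", "ensemble": ens}
            for f, ens in state.local.pop("forest_models").items()
        }
        return out

    def report(self):
        return {"forest_sizes": dict(self._sizes)}


@register_app
class DeepLearningApp(FederatedApp):
    """FedAvg training of the numpy MLP with a local 20% holdout.

    Per round: parties run local mini-batch epochs from the broadcast
    parameters and submit the summable pair (n_i · params, n_i); the
    coordinator divides the sums to get the count-weighted average and
    broadcasts it.
    """

    name = "deep_learning"

    def __init__(self) -> None:
        self._round = 0
        self._arch = None
        self._history: list[float] = []

    def _config(self, params: dict) -> deep.TrainConfig:
        return deep.TrainConfig(
            rounds=int(params.get("rounds", 50)),
            local_epochs=int(params.get("local_epochs", 1)),
            batch_size=int(params.get("batch_size", 32)),
            learning_rate=float(params.get("learning_rate", 0.05)),
            loss=params.get("loss", "mse"),
            seed=int(params.get("seed", 0)),
        )

    def initial_broadcast(self, params, n_parties):
        hidden = params.get("hidden", [32])
        n_features = int(params["n_features"])
        self._arch = deep.Architecture(
            layer_sizes=(n_features, *hidden, 1),
            activation=params.get("activation", "tanh"),
        )
        params0 = deep.init_params(
            self._arch, int(params.get("seed", 0))
        )
        return {"round": 0, "params": params0.as_vector()}

    def participant_phase(self, state, broadcast_in, params, round_idx):
        data = _working(state, params)
        cfg = self._config(params)
        if "holdout" not in state.local:
            rng = np.random.default_rng(state.seed)
            n = len(data.y)
            order = rng.permutation(n)
            n_test = max(1, int(round(params.get("test_fraction", 0.2) * n)))
            state.local["holdout"] = (order[n_test:], order[:n_test])
            state.local["dl_rng"] = np.random.default_rng(
                state.seed + 104729
            )
        if broadcast_in.get("done"):
            state.local["dl_model"] = np.asarray(broadcast_in["params"])
            return {"ack": Opaque(0, "ack")}
        arch = deep.Architecture(
            layer_sizes=tuple(broadcast_in.get("layer_sizes", ()))
            or self._arch.layer_sizes,
            activation=params.get("activation", "tanh"),
        )
        model = deep.ModelParams.from_vector(
            np.asarray(broadcast_in["params"]), arch
        )
        train_idx, _ = state.local["holdout"]
        updated = deep.local_update(
            model,
            data.X[train_idx],
            data.y[train_idx],
            arch,
            cfg,
            state.local["dl_rng"],
        )
        n_i = float(len(train_idx))
        return {
            "wparams": Summable(n_i * updated.as_vector(), "weighted_params"),
            "wcount": Summable(np.array([n_i]), "weighted_params"),
        }

    def coordinator_phase(self, gathered, params, n_parties):
        if "wparams" not in gathered.sums:
            return None, True
        cfg = self._config(params)
        total = gathered.sums["wcount"][0]
        avg = gathered.sums["wparams"] / total
        self._round += 1
        done = self._round >= cfg.rounds
        return {
            "round": self._round,
            "params": avg,
            "layer_sizes": list(self._arch.layer_sizes),
            "done": done,
        }, False

    def finalize_party(self, state, final_broadcast, params):
        data = _working(state, params)
        out = data.shallow_copy()
        train_idx, test_idx = state.local.pop("holdout")
        out.models = {
            0: {
                "kind": "mlp",
                "params": state.local.pop("dl_model"),
                "layer_sizes": list(self._arch.layer_sizes),
                "activation": params.get("activation", "tanh"),
            }
        }
        out.holdout = (train_idx, test_idx)
        state.local.pop("dl_rng", None)
        return out

    def report(self):
        return {"rounds": self._round}


def _predict(model: dict, X: np.ndarray) -> np.ndarray:
    kind = model["kind"]
    if kind in ("linear", "logistic"):
        Xd = _with_intercept(X) if model.get("intercept", True) else X
        z = Xd @ np.asarray(model["beta"], dtype=float)
        if kind == "logistic":
            return (z > 0).astype(float)  # threshold at p = 0.5
        return z
    if kind == "forest":
        return model["ensemble"].predict(X)
    if kind == "mlp":
        arch = deep.Architecture(
            layer_sizes=tuple(model["layer_sizes"]),
            activation=model.get("activation", "tanh"),
        )
        mp = deep.ModelParams.from_vector(
            np.asarray(model["params"]), arch
        )
        return deep.forward(mp, X, arch).ravel()
    raise ValueError(f"unknown model kind {kind!r}")


class _EvalBase(FederatedApp):
    """Shared fold loop for the two evaluation apps."""

    def _test_arrays(self, state, data, fold):
        if hasattr(data, "holdout"):  # deep-learning 20% holdout
            _, test_idx = data.holdout
            X = data.X[test_idx]
            y = data.y[test_idx]
            scalers = getattr(data, "scalers", None)
            if scalers is not None:
                mean, std = scalers[fold]
                X = preprocess.apply_standardize(X, mean, std)
            return X, y
        return _fold_arrays(data, fold, train=False)

    def _n_folds(self, data) -> int:
        return len(data.models) if data.models else data.k


@register_app
class EvalClassificationApp(_EvalBase):
    """Global F1 per fold from summed confusion matrices."""

    name = "eval_classification"

    def __init__(self) -> None:
        self._metrics: dict[int, float] = {}
        self._local: dict[int, list[float]] = {}

    def participant_phase(self, state, broadcast_in, params, round_idx):
        data = _working(state, params)
        if round_idx >= self._n_folds(data):
            return {"ack": Opaque(0, "ack")}
        fold = round_idx
        X, y = self._test_arrays(state, data, fold)
        y_pred = _predict(data.models[fold], X)
        labels = params.get("labels", [0.0, 1.0])
        cm = evaluate.ConfusionCounts.from_predictions(
            y.astype(float), y_pred.astype(float), labels
        )
        out = {
            "confusion": Summable(
                cm.counts.ravel().astype(float), "confusion"
            )
        }
        if params.get("local_metrics", False):
            out["local_f1"] = Opaque(
                evaluate.f1_from_confusion(
                    cm, params.get("positive_label", 1.0)
                ),
                "local_metric",
            )
        return out

    def coordinator_phase(self, gathered, params, n_parties):
        if "confusion" not in gathered.sums:
            return None, True
        labels = params.get("labels", [0.0, 1.0])
        k = len(labels)
        cm = evaluate.ConfusionCounts(
            labels=list(labels),
            counts=np.rint(gathered.sums["confusion"]).astype(int).reshape(k, k),
        )
        if params.get("macro", False):
            f1 = evaluate.macro_f1(cm)
        else:
            f1 = evaluate.f1_from_confusion(
                cm, params.get("positive_label", 1.0)
            )
        self._metrics[gathered.round] = f1
        if "local_f1" in gathered.items:
            self._local[gathered.round] = list(gathered.items["local_f1"])
        return {"fold": gathered.round, "f1": f1}, False

    def finalize_party(self, state, final_broadcast, params):
        return {"metric": "f1", "per_fold": dict(self._metrics)}

    def report(self):
        rep = {
            "metric": "f1",
            "summary": evaluate.cv_report(self._metrics),
        }
        if self._local:
            rep["local_per_party"] = self._local
        return rep


@register_app
class EvalRegressionApp(_EvalBase):
    """Global RMSE per fold from summed squared-error statistics."""

    name = "eval_regression"

    def __init__(self) -> None:
        self._metrics: dict[int, float] = {}

    def participant_phase(self, state, broadcast_in, params, round_idx):
        data = _working(state, params)
        if round_idx >= self._n_folds(data):
            return {"ack": Opaque(0, "ack")}
        fold = round_idx
        X, y = self._test_arrays(state, data, fold)
        y_pred = _predict(data.models[fold], X)
        es = evaluate.ErrorSums.from_predictions(y, y_pred)
        return {"errors": Summable(es.as_vector(), "error_sums")}

    def coordinator_phase(self, gathered, params, n_parties):
        if "errors" not in gathered.sums:
            return None, True
        es = evaluate.ErrorSums.from_vector(gathered.sums["errors"])
        rmse = evaluate.rmse_from_sums(es)
        self._metrics[gathered.round] = rmse
        return {"fold": gathered.round, "rmse": rmse}, False

    def finalize_party(self, state, final_broadcast, params):
        return {"metric": "rmse", "per_fold": dict(self._metrics)}

    def report(self):
        return {
            "metric": "rmse",
            "summary": evaluate.cv_report(self._metrics),
        }


@register_app
class KaplanMeierApp(FederatedApp):
    """Federated survival curves and (optional) log-rank test.

    Parties submit per-group event tables; the coordinator aggregates
    them over the union of time points — exactly reproducing the pooled
    analysis — and broadcasts the survival curve(s) plus the test report.
    """

    name = "kaplan_meier"

    def __init__(self) -> None:
        self._result: dict = {}

    def participant_phase(self, state, broadcast_in, params, round_idx):
        if round_idx > 0:
            return {"ack": Opaque(0, "ack")}
        data = _working(state, params)
        time = data.extra["time"]
        event = data.extra["event"]
        group = data.extra.get("group")
        tables: dict[str, dict] = {}
        groups = (
            np.unique(group) if group is not None else np.array(["all"])
        )
        for g in groups:
            mask = (
                np.ones(len(time), dtype=bool)
                if group is None
                else group == g
            )
            records = [
                survival.SurvivalRecord(float(t), int(e))
                for t, e in zip(time[mask], event[mask])
            ]
            t = survival.local_event_table(records)
            tables[str(g)] = {
                "times": t.times.tolist(),
                "d": t.d.tolist(),
                "n_total": t.n_total,
                "censor_times": t.censor_times.tolist(),
                "censor_counts": t.censor_counts.tolist(),
            }
        return {"tables": Opaque(tables, "event_table")}

    def coordinator_phase(self, gathered, params, n_parties):
        if "tables" not in gathered.items:
            return None, True
        merged: dict[str, list[survival.EventTable]] = {}
        for party_tables in gathered.items["tables"]:
            for g, t in party_tables.items():
                merged.setdefault(g, []).append(
                    survival.EventTable(
                        times=np.asarray(t["times"], dtype=float),
                        d=np.asarray(t["d"], dtype=int),
                        n_total=int(t["n_total"]),
                        censor_times=np.asarray(
                            t["censor_times"], dtype=float
                        ),
                        censor_counts=np.asarray(
                            t["censor_counts"], dtype=int
                        ),
                    )
                )
        group_tables = {
            g: survival.aggregate_tables(ts) for g, ts in merged.items()
        }
        curves = {}
        for g, table in group_tables.items():
            times, s = survival.km_curve(table)
            curves[g] = {
                "time": times.tolist(),
                "n_at_risk": table.n_at_risk.tolist(),
                "d": table.d.tolist(),
                "S": s.tolist(),
            }
        result: dict[str, Any] = {"curves": curves}
        if len(group_tables) >= 2:
            chi2, p = survival.logrank_test(group_tables)
            result["logrank"] = {"chi2": chi2, "p_value": p}
        self._result = result
        return result, False

    def finalize_party(self, state, final_broadcast, params):
        return self._result

    def report(self):
        return dict(self._result)
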