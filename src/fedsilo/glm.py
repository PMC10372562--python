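"""Federated generalized linear models.

Linear regression is one-shot and exact: each party computes its Gram
statistics (XᵀX, Xᵀy, n), the coordinator adds them and solves the pooled
normal equations.  Because XᵀX and Xᵀy are sums over rows, the federated
solution is *identical* to ordinary least squares on the pooled data — the
partition of rows across silos is algebraically invisible.

Logistic regression iterates Newton–Raphson (IRLS): per round each party
evaluates the local log-likelihood gradient Xᵀ(y − p) and Hessian
Xᵀ diag(p(1−p)) X at the current coefficients, the coordinator sums them,
takes a Newton step, and broadcasts the new coefficients.  The summed
gradient/Hessian again equal the pooled quantities exactly, so the iterate
trajectory matches a centralized Newton fit round for round.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DesignMatrix",
    "GramStats",
    "BetaVector",
    "NewtonRound",
    "local_gram",
    "fit_linear",
    "local_logistic_round",
    "fit_logistic",
]

#: Ridge added to an ill-conditioned aggregate Hessian (separable data).
HESSIAN_RIDGE = 1e-8


@dataclass
class DesignMatrix:
    """One party's design: features X (n×p), response y, feature names.

    ``with_intercept`` prepends an explicit ones column — the shared
    convention across parties, so intercepts federate like any coefficient.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.y))):
            raise ValueError("missing or non-finite values in design matrix")
        if not self.feature_names:
            self.feature_names = [f"x{j}" for j in range(self.X.shape[1])]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def with_intercept(self) -> "DesignMatrix":
        ones = np.ones((self.n, 1))
        return DesignMatrix(
            X=np.hstack([ones, self.X]),
            y=self.y,
            feature_names=["intercept"] + list(self.feature_names),
        )

    def require_binary(self) -> None:
        if not np.all(np.isin(self.y, (0.0, 1.0))):
            raise ValueError("logistic response must be coded {0, 1}")


@dataclass
class GramStats:
    """Sufficient statistics for least squares, summable across parties."""

    XtX: np.ndarray
    Xty: np.ndarray
    n: int

    def as_vector(self) -> np.ndarray:
        return np.concatenate(
            [self.XtX.ravel(), self.Xty, [float(self.n)]]
        )

    @classmethod
    def from_vector(cls, v: np.ndarray, p: int) -> "GramStats":
        return cls(
            XtX=v[: p * p].reshape(p, p),
            Xty=v[p * p : p * p + p],
            n=int(round(v[-1])),
        )


@dataclass
class BetaVector:
    beta: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    has_intercept: bool = False
    iterations: int = 0
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "beta": np.asarray(self.beta, dtype=float).tolist(),
            "has_intercept": self.has_intercept,
            "iterations": self.iterations,
            "converged": self.converged,
        }


@dataclass
class NewtonRound:
    """One party's contribution to one Newton iteration."""

    beta: np.ndarray
    local_gradient: np.ndarray
    local_hessian: np.ndarray
    iteration: int = 0
    converged: bool = False

    def as_vector(self) -> np.ndarray:
        return np.concatenate(
            [self.local_gradient, self.local_hessian.ravel()]
        )

    @staticmethod
    def split_vector(v: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
        return v[:p], v[p:].reshape(p, p)


def local_gram(data: DesignMatrix) -> GramStats:
    """XᵀX, Xᵀy and the row count — computed entirely at the party."""
    return GramStats(XtX=data.X.T @ data.X, Xty=data.X.T @ data.y, n=data.n)


def fit_linear(gram_list: list[GramStats]) -> BetaVector:
    """Solve the pooled normal equations from summed Gram statistics.

    Falls back to the pseudoinverse with a warning when the aggregate
    XᵀX is singular (collinear pooled features).
    """
    if not gram_list:
        raise ValueError("no Gram statistics supplied")
    XtX = np.sum([g.XtX for g in gram_list], axis=0)
    Xty = np.sum([g.Xty for g in gram_list], axis=0)
    try:
        beta = np.linalg.solve(XtX, Xty)
        # reject solutions from numerically singular systems
        if not np.all(np.isfinite(beta)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn(
            "aggregate X^T X is singular; using pseudoinverse",
            stacklevel=2,
        )
        beta = np.linalg.pinv(XtX) @ Xty
    return BetaVector(beta=beta)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def local_logistic_round(
    data: DesignMatrix, beta: np.ndarray, iteration: int = 0
) -> NewtonRound:
    """Local gradient and Hessian of the log-likelihood at ``beta``.

    Ascent convention: gradient = Xᵀ(y − p), Hessian = Xᵀ diag(p(1−p)) X
    (the negative of the log-likelihood's second derivative), so the Newton
    update is beta + H⁻¹g.
    """
    data.require_binary()
    beta = np.asarray(beta, dtype=float)
    p_hat = _sigmoid(data.X @ beta)
    grad = data.X.T @ (data.y - p_hat)
    w = p_hat * (1.0 - p_hat)
    hess = (data.X * w[:, None]).T @ data.X
    return NewtonRound(
        beta=beta, local_gradient=grad, local_hessian=hess,
        iteration=iteration,
    )


def fit_logistic(
    parties: list[DesignMatrix],
    max_iter: int = 25,
    tol: float = 1e-8,
    beta0: np.ndarray | None = None,
) -> BetaVector:
    """Federated Newton–Raphson for unpenalized logistic regression.

    Per round: every party reports (gradient, Hessian) at the broadcast
    coefficients; the coordinator sums and updates
    ``beta ← beta + (ΣH)⁻¹ Σg`` until ``max|Δbeta| < tol`` or ``max_iter``.
    Near-singular aggregate Hessians (separable data) are ridge-damped with
    a warning rather than aborting.
    """
    if not parties:
        raise ValueError("no parties supplied")
    p = parties[0].p
    for d in parties:
        if d.p != p:
            raise ValueError("feature-dimension mismatch across parties")
        d.require_binary()
    pooled_y = np.concatenate([d.y for d in parties])
    if pooled_y.min() == pooled_y.max():
        raise ValueError("pooled response contains a single class")

    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, float).copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        rounds = [local_logistic_round(d, beta, it) for d in parties]
        grad = np.sum([r.local_gradient for r in rounds], axis=0)
        hess = np.sum([r.local_hessian for r in rounds], axis=0)
        try:
            step = np.linalg.solve(hess, grad)
            if not np.all(np.isfinite(step)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            warnings.warn(
                "ill-conditioned aggregate Hessian; applying ridge damping",
                stacklevel=2,
            )
            step = np.linalg.solve(
                hess + HESSIAN_RIDGE * np.eye(p), grad
            )
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    if not converged:
        logger.warning("logistic Newton did not converge in %d rounds", it)
    return BetaVector(beta=beta, iterations=it, converged=converged)


def logistic_deviance(parties: list[DesignMatrix], beta: np.ndarray) -> float:
    """Pooled deviance −2·loglik, for convergence diagnostics."""
    total = 0.0
    for d in parties:
        z = d.X @ np.asarray(beta, dtype=float)
        # log(1+e^z) computed stably
        log1pez = np.logaddexp(0.0, z)
        total += float(np.sum(d.y * z - log1pez))
    return -2.0 * total
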