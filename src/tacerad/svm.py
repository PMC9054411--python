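"""Soft-margin kernel SVM trained by SMO with max-violating-pair selection.

The classifier solves the dual of the soft-margin problem

    min_{N,a,theta}  1/2 ||N||^2 + C sum_r theta_r
    s.t.             y_r (N^T phi(x_r) + a) >= 1 - theta_r,  theta_r >= 0

i.e. maximize  sum_r beta_r - 1/2 sum_{i,l} beta_i beta_l y_i y_l W(x_i, x_l)
subject to     0 <= beta_r <= C,  sum_r beta_r y_r = 0,

where W(u, v) = <phi(u), phi(v)> is the kernel. The decision function is
f(x) = sum_r beta_r y_r W(x_r, x) + a; prediction is sign(f), with an
exact zero resolved to +1.

The solver is sequential minimal optimization: at each step the pair of
coefficients most violating the KKT conditions is updated analytically,
until the duality-gap measure m(beta) - M(beta) falls below ``tol``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np


@dataclasses.dataclass(frozen=True)
class KernelSpec:
    """Kernel family and hyperparameters.

    linear:      W(u,v) = u.v
    polynomial:  W(u,v) = (u.v + coef0)^degree
    rbf:         W(u,v) = exp(-gamma ||u - v||^2)
    """

    family: str = "rbf"
    degree: int = 3
    gamma: float | None = None  # None -> 1/(n_features * var(X)) at fit time
    coef0: float = 1.0

    def __post_init__(self):
        if self.family not in ("linear", "polynomial", "rbf"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.family == "polynomial" and (int(self.degree) != self.degree or self.degree < 1):
            raise ValueError("polynomial degree must be an integer >= 1")
        if self.family == "rbf" and self.gamma is not None and self.gamma <= 0:
            raise ValueError("rbf gamma must be > 0")


def _resolve_gamma(spec: KernelSpec, X: np.ndarray) -> float:
    if spec.gamma is not None:
        return float(spec.gamma)
    var = float(X.var())
    return 1.0 / (X.shape[1] * var) if var > 0 else 1.0 / X.shape[1]


def kernel_eval(u: np.ndarray, v: np.ndarray, spec: KernelSpec) -> float:
    """Evaluate the kernel on a single pair of equal-dimension vectors."""
    u, v = np.asarray(u, dtype=float), np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    if spec.family == "linear":
        return float(u @ v)
    if spec.family == "polynomial":
        return float((u @ v + spec.coef0) ** spec.degree)
    gamma = spec.gamma if spec.gamma is not None else 1.0
    return float(np.exp(-gamma * np.sum((u - v) ** 2)))


def kernel_matrix(X1: np.ndarray, X2: np.ndarray, spec: KernelSpec, gamma: float | None = None) -> np.ndarray:
    """Dense kernel Gram matrix between two sample sets."""
    X1, X2 = np.atleast_2d(X1), np.atleast_2d(X2)
    if X1.shape[1] != X2.shape[1]:
        raise ValueError(f"dimension mismatch: {X1.shape[1]} vs {X2.shape[1]}")
    if spec.family == "linear":
        return X1 @ X2.T
    if spec.family == "polynomial":
        return (X1 @ X2.T + spec.coef0) ** spec.degree
    g = gamma if gamma is not None else (spec.gamma if spec.gamma is not None else 1.0)
    sq = (X1 ** 2).sum(axis=1)[:, None] + (X2 ** 2).sum(axis=1)[None, :] - 2 * X1 @ X2.T
    return np.exp(-g * np.maximum(sq, 0.0))


@dataclasses.dataclass
class SVMModel:
    """Trained soft-margin kernel classifier (dual form)."""

    beta: np.ndarray  # dual coefficients, 0 <= beta_r <= C
    a: float  # bias
    C: float
    kernel: KernelSpec
    gamma: float  # resolved rbf width (ignored for other kernels)
    X: np.ndarray  # training samples (support expansion needs them)
    y: np.ndarray  # labels in {-1, +1}
    theta: np.ndarray  # slack values max(0, 1 - y f(x)) at the solution
    n_iter: int
    converged: bool

    @property
    def support(self) -> np.ndarray:
        """Indices of support vectors (beta > 0)."""
        return np.nonzero(self.beta > 1e-10)[0]

    @property
    def N(self) -> np.ndarray:
        """Primal weight vector sum beta_r y_r x_r (linear kernel only)."""
        if self.kernel.family != "linear":
            raise ValueError("primal weights are only defined for the linear kernel")
        return (self.beta * self.y) @ self.X

    def to_json(self, path: str | Path) -> None:
        payload = {
            "beta": self.beta.tolist(), "a": self.a, "C": self.C,
            "kernel": dataclasses.asdict(self.kernel), "gamma": self.gamma,
            "X": self.X.tolist(), "y": self.y.tolist(),
            "theta": self.theta.tolist(),
            "n_iter": self.n_iter, "converged": self.converged,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SVMModel":
        d = json.loads(Path(path).read_text())
        return cls(
            beta=np.asarray(d["beta"]), a=float(d["a"]), C=float(d["C"]),
            kernel=KernelSpec(**d["kernel"]), gamma=float(d["gamma"]),
            X=np.asarray(d["X"]), y=np.asarray(d["y"]),
            theta=np.asarray(d["theta"]),
            n_iter=int(d["n_iter"]), converged=bool(d["converged"]),
        )


def dual_objective(beta: np.ndarray, y: np.ndarray, K: np.ndarray) -> float:
    """Value of the dual objective sum(beta) - 1/2 beta^T (yy' * K) beta."""
    by = beta * y
    return float(beta.sum() - 0.5 * by @ K @ by)


def train(
    X: np.ndarray,
    y: np.ndarray,
    kernel: KernelSpec | None = None,
    C: float = 1.0,
    tol: float = 1e-3,
    max_iter: int | None = None,
    seed: int | None = None,
) -> SVMModel:
    """Fit the soft-margin dual by SMO.

    The working pair is the maximal violating pair: i maximizing and j
    minimizing ``-y_t F_t`` over the index sets allowed to move up/down,
    where ``F_t = sum_l beta_l y_l K(t,l) - y_t``. Convergence is declared
    when the violation gap drops below ``tol``. The bias is the average of
    ``y_r - sum_l beta_l y_l K(r,l)`` over margin support vectors
    (0 < beta_r < C), or the violation-gap midpoint when none are free.
    The solution is deterministic; ``seed`` is accepted for interface
    uniformity only.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y lengths differ")
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ValueError("non-finite values in training data")
    if set(np.unique(y)) != {-1.0, 1.0}:
        raise ValueError("labels must be exactly {-1, +1} with both classes present")
    if C <= 0:
        raise ValueError("C must be > 0")
    m = len(y)
    kernel = kernel or KernelSpec()
    gamma = _resolve_gamma(kernel, X) if kernel.family == "rbf" else 1.0
    K = kernel_matrix(X, X, kernel, gamma=gamma)
    if max_iter is None:
        max_iter = max(20000, 200 * m)

    beta = np.zeros(m)
    F = -y.copy()  # F_t = sum beta y K - y_t; starts at -y with beta = 0
    it = 0
    converged = False
    while it < max_iter:
        up = ((y > 0) & (beta < C - 1e-12)) | ((y < 0) & (beta > 1e-12))
        lo = ((y < 0) & (beta < C - 1e-12)) | ((y > 0) & (beta > 1e-12))
        if not up.any() or not lo.any():
            converged = True
            break
        # -y_t * grad_t of the dual in minimization form equals -F_t
        neg_yF = -F
        i = int(np.flatnonzero(up)[np.argmax(neg_yF[up])])
        j = int(np.flatnonzero(lo)[np.argmin(neg_yF[lo])])
        gap = neg_yF[i] - neg_yF[j]
        if gap <= tol:
            converged = True
            break
        eta = K[i, i] + K[j, j] - 2 * K[i, j]
        eta = max(eta, 1e-12)
        if y[i] != y[j]:
            L = max(0.0, beta[j] - beta[i])
            H = min(C, C + beta[j] - beta[i])
        else:
            L = max(0.0, beta[i] + beta[j] - C)
            H = min(C, beta[i] + beta[j])
        bj_new = np.clip(beta[j] + y[j] * (F[i] - F[j]) / eta, L, H)
        dj = bj_new - beta[j]
        di = -y[i] * y[j] * dj
        beta[i] += di
        beta[j] = bj_new
        F += y[i] * di * K[:, i] + y[j] * dj * K[:, j]
        it += 1

    fx_no_bias = (beta * y) @ K
    free = (beta > 1e-8 * C) & (beta < C * (1 - 1e-8))
    if free.any():
        a = float(np.mean(y[free] - fx_no_bias[free]))
    else:
        up = ((y > 0) & (beta < C - 1e-12)) | ((y < 0) & (beta > 1e-12))
        lo = ((y < 0) & (beta < C - 1e-12)) | ((y > 0) & (beta > 1e-12))
        neg_yF = -F
        hi = neg_yF[up].max() if up.any() else 0.0
        lo_v = neg_yF[lo].min() if lo.any() else 0.0
        a = float((hi + lo_v) / 2.0)
    fx = fx_no_bias + a
    theta = np.maximum(0.0, 1.0 - y * fx)
    return SVMModel(
        beta=beta, a=a, C=float(C), kernel=kernel, gamma=gamma,
        X=X, y=y, theta=theta, n_iter=it, converged=converged,
    )


def decision(model: SVMModel, x: np.ndarray) -> np.ndarray:
    """Decision values f(x) = sum beta_r y_r W(x_r, x) + a."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != model.X.shape[1]:
        raise ValueError(f"dimension mismatch: {x.shape[1]} vs {model.X.shape[1]}")
    Kx = kernel_matrix(x, model.X, model.kernel, gamma=model.gamma)
    return Kx @ (model.beta * model.y) + model.a


def predict(model: SVMModel, x: np.ndarray) -> np.ndarray:
    """Hard labels in {-1, +1}; a decision value of exactly 0 maps to +1."""
    f = decision(model, x)
    return np.where(f >= 0, 1, -1)
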