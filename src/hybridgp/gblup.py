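"""Multi-kernel linear mixed model: kernel construction, REML variance
components, and block-partitioned BLUP prediction.

The model is y = X beta + sum_k u_k + e with u_k ~ N(0, phi_k^2 K_k) and
e ~ N(0, sigma_e^2 I), so var(y) = V = sum_k phi_k^2 K_k + sigma_e^2 I.
Kernels are scaled cross-products K = W W' / q of a feature matrix W with q
columns (no trace normalization). Variance components maximize the
restricted log-likelihood

    l_R = -1/2 [ log|V| + log|X' V^-1 X| + (y - X b)' V^-1 (y - X b) ]

over non-negative components, optimized on the log-variance scale with
analytic gradients. Prediction of a held-out block uses the conditional
mean of the joint Gaussian:

    yhat_2 = X_2 b + (sum_k phi_k^2 K_k,21) V_11^-1 (y_1 - X_1 b).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

logger = logging.getLogger(__name__)

__all__ = ["KernelSet", "MixedModelFit", "TrainTestSplit", "build_kernel", "reml_fit", "predict_blup"]

_LOG2PI = float(np.log(2.0 * np.pi))


def build_kernel(W: np.ndarray, divisor: int) -> np.ndarray:
    """K = W W' / divisor; the divisor is the feature count (columns of W)."""
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[1] == 0:
        raise ValueError("design matrix must have at least one column")
    if divisor <= 0:
        raise ValueError("divisor must be positive")
    K = (W @ W.T) / float(divisor)
    return (K + K.T) / 2.0


@dataclass
class KernelSet:
    """Labelled n x n kernels entering the variance model."""

    labels: list[str]
    matrices: list[np.ndarray]
    scale_divisors: list[int] | None = None

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.matrices):
            raise ValueError("labels / matrices length mismatch")
        if len(set(self.labels)) != len(self.labels) or "residual" in self.labels:
            raise ValueError("kernel labels must be unique and not 'residual'")
        ns = {K.shape for K in self.matrices}
        if len(ns) > 1 or any(K.shape[0] != K.shape[1] for K in self.matrices):
            raise ValueError("kernels must be square with a common dimension")

    @property
    def n(self) -> int:
        return self.matrices[0].shape[0]

    def validate(self, sym_tol: float = 1e-8) -> None:
        """Check symmetry and positive semidefiniteness of every kernel."""
        for lbl, K in zip(self.labels, self.matrices):
            if not np.allclose(K, K.T, atol=sym_tol * max(1.0, np.abs(K).max())):
                raise ValueError(f"kernel {lbl} is not symmetric")
            evals = linalg.eigvalsh(K)
            floor = -1e-8 * max(np.trace(K), 1.0) / K.shape[0]
            if evals.min() < floor:
                raise ValueError(f"kernel {lbl} is not PSD (min eigenvalue {evals.min():.3e})")

    def subset(self, idx: np.ndarray) -> "KernelSet":
        return KernelSet(
            list(self.labels), [K[np.ix_(idx, idx)] for K in self.matrices], self.scale_divisors
        )


@dataclass
class MixedModelFit:
    beta: np.ndarray
    variance_components: dict[str, float]
    restricted_loglik: float
    converged: bool
    n_iter: int
    grad_norm: float
    kernel_labels: list[str]
    boundary: dict[str, bool] = field(default_factory=dict)
    training_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.variance_components.values()):
            raise ValueError("variance components must be non-negative")

    def to_json(self) -> str:
        return json.dumps(
            {
                "beta": np.asarray(self.beta).tolist(),
                "variance_components": self.variance_components,
                "restricted_loglik": self.restricted_loglik,
                "converged": self.converged,
                "n_iter": self.n_iter,
                "grad_norm": self.grad_norm,
                "kernel_labels": self.kernel_labels,
                "boundary": self.boundary,
            },
            indent=2,
        )


@dataclass
class TrainTestSplit:
    """Index partition plus per-kernel 2x2 blocks (K11 train, K21 test-train)."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    labels: list[str]
    K11: list[np.ndarray]
    K21: list[np.ndarray]
    K22: list[np.ndarray]

    @classmethod
    def from_kernels(
        cls, kernels: KernelSet, train_idx: np.ndarray, test_idx: np.ndarray
    ) -> "TrainTestSplit":
        train_idx = np.asarray(train_idx)
        test_idx = np.asarray(test_idx)
        if np.intersect1d(train_idx, test_idx).size:
            raise ValueError("train and test indices overlap")
        return cls(
            train_idx=train_idx,
            test_idx=test_idx,
            labels=list(kernels.labels),
            K11=[K[np.ix_(train_idx, train_idx)] for K in kernels.matrices],
            K21=[K[np.ix_(test_idx, train_idx)] for K in kernels.matrices],
            K22=[K[np.ix_(test_idx, test_idx)] for K in kernels.matrices],
        )


def _restricted_loglik_parts(
    v: np.ndarray, y: np.ndarray, X: np.ndarray, Ks: list[np.ndarray]
) -> tuple[float, np.ndarray, np.ndarray]:
    """(restricted loglik, gradient wrt variances, beta) at variances v.

    v holds one variance per kernel followed by the residual variance.
    """
    n, p = X.shape
    V = v[-1] * np.eye(n)
    for vk, K in zip(v[:-1], Ks):
        V += vk * K
    try:
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError:
        jitter = 1e-8 * np.mean(np.diag(V))
        logger.warning("singular V: adding jitter %.3e", jitter)
        V = V + jitter * np.eye(n)
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    logdetV = 2.0 * np.sum(np.log(np.diag(c)))
    Vi = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
    ViX = Vi @ X
    XtViX = X.T @ ViX
    cx, lowx = linalg.cho_factor(XtViX, lower=True, check_finite=False)
    logdetXtViX = 2.0 * np.sum(np.log(np.diag(cx)))
    beta = linalg.cho_solve((cx, lowx), X.T @ (Vi @ y), check_finite=False)
    r = y - X @ beta
    Vir = Vi @ r
    quad = float(r @ Vir)
    ll = -0.5 * ((n - p) * _LOG2PI + logdetV + logdetXtViX + quad)
    # P = Vi - ViX (X'ViX)^-1 X'Vi ; dl/dv_k = -1/2 [tr(P K_k) - r'Vi K_k Vi r]
    P = Vi - ViX @ linalg.cho_solve((cx, lowx), ViX.T, check_finite=False)
    grad = np.empty_like(v)
    for k, K in enumerate(Ks):
        grad[k] = -0.5 * (np.sum(P * K) - Vir @ (K @ Vir))
    grad[-1] = -0.5 * (np.trace(P) - Vir @ Vir)
    return ll, grad, beta


def reml_fit(
    y: np.ndarray,
    X: np.ndarray | None,
    kernels: KernelSet,
    max_iter: int = 500,
    rel_tol: float = 1e-8,
    training_ids: list[str] | None = None,
    n_starts: int = 3,
) -> MixedModelFit:
    """Estimate variance components by REML.

    Bounded quasi-Newton (L-BFGS-B) on log-variances from several starting
    partitions of the phenotypic variance; the best restricted log-likelihood
    wins. Components pinned at the lower bound (1e-10 x phenotypic variance)
    are reported as 0 with a boundary flag.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 10:
        raise ValueError(f"need at least 10 observations (got {n})")
    if not np.isfinite(y).all():
        raise ValueError("y contains missing or non-finite values")
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")
    Ks = kernels.matrices
    nk = len(Ks)
    vy = float(np.var(y))
    if vy == 0:
        vy = 1.0
    lb, ub = 1e-10 * vy, 1e6 * vy
    bounds = [(np.log(lb), np.log(ub))] * (nk + 1)

    def negloglik(theta: np.ndarray) -> tuple[float, np.ndarray]:
        v = np.exp(theta)
        ll, grad, _ = _restricted_loglik_parts(v, y, X, Ks)
        return -ll, -grad * v  # chain rule to log scale

    # kernel scales differ; normalize starts by mean diagonal
    kdiag = np.array([max(np.mean(np.diag(K)), 1e-12) for K in Ks])
    starts = []
    equal = np.concatenate([vy / (nk + 1) / kdiag, [vy / (nk + 1)]])
    starts.append(equal)
    if n_starts > 1:
        starts.append(np.concatenate([0.05 * vy / kdiag, [0.95 * vy]]))
    if n_starts > 2:
        starts.append(np.concatenate([0.9 * vy / nk / kdiag, [0.1 * vy]]))

    best = None
    for v0 in starts[:n_starts]:
        res = optimize.minimize(
            negloglik,
            np.log(np.clip(v0, lb * 10, ub / 10)),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": rel_tol, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    v_hat = np.exp(best.x)
    ll, grad, beta = _restricted_loglik_parts(v_hat, y, X, Ks)
    converged = bool(best.success or np.linalg.norm(best.jac, ord=np.inf) < 1e-4)
    if not converged:
        logger.warning("REML did not converge: %s", best.message)
    labels = list(kernels.labels) + ["residual"]
    boundary = {lbl: bool(v <= lb * 1.01) for lbl, v in zip(labels, v_hat)}
    components = {
        lbl: (0.0 if boundary[lbl] else float(v)) for lbl, v in zip(labels, v_hat)
    }
    return MixedModelFit(
        beta=beta,
        variance_components=components,
        restricted_loglik=float(ll),
        converged=converged,
        n_iter=int(best.nit),
        grad_norm=float(np.linalg.norm(best.jac, ord=np.inf)),
        kernel_labels=list(kernels.labels),
        boundary=boundary,
        training_ids=training_ids,
    )


def predict_blup(
    fit: MixedModelFit,
    split: TrainTestSplit,
    y1: np.ndarray,
    X1: np.ndarray | None = None,
    X2: np.ndarray | None = None,
) -> np.ndarray:
    """Conditional-mean prediction of the test block given the training block."""
    y1 = np.asarray(y1, dtype=float).ravel()
    n1 = y1.size
    n2 = len(split.test_idx)
    if X1 is None:
        X1 = np.ones((n1, 1))
    if X2 is None:
        X2 = np.ones((n2, 1))
    if list(split.labels) != list(fit.kernel_labels):
        raise ValueError("split kernels do not match the fitted model")
    sig = fit.variance_components["residual"]
    V11 = sig * np.eye(n1)
    C21 = np.zeros((n2, n1))
    for lbl, K11, K21 in zip(split.labels, split.K11, split.K21):
        phi = fit.variance_components[lbl]
        V11 += phi * K11
        C21 += phi * K21
    try:
        c, low = linalg.cho_factor(V11, lower=True, check_finite=False)
    except linalg.LinAlgError:
        jitter = 1e-8 * np.mean(np.diag(V11))
        logger.warning("singular V11: adding jitter %.3e", jitter)
        c, low = linalg.cho_factor(V11 + jitter * np.eye(n1), lower=True, check_finite=False)
    resid = y1 - X1 @ fit.beta
    return X2 @ fit.beta + C21 @ linalg.cho_solve((c, low), resid, check_finite=False)
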