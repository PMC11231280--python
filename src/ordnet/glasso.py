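"""L1-penalized Gaussian graphical model estimation with EBIC selection.

The graphical lasso maximizes ``log det K - tr(S K) - lambda * sum_{i!=j}
|K_ij|`` over positive-definite precision matrices K (diagonal
unpenalized), by block coordinate descent: each row/column is updated by
solving a lasso subproblem on the working covariance. The penalty is chosen
by minimizing the Extended Bayesian Information Criterion over a
log-spaced lambda path, and the selected precision matrix is reported as a
partial-correlation weight matrix ``W_ij = -K_ij / sqrt(K_ii K_jj)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .polychoric import CorrelationMatrix

__all__ = [
    "GlassoSolution",
    "NetworkModel",
    "glasso",
    "glasso_objective",
    "ebic",
    "select_network",
    "to_partial_correlations",
]

EDGE_EPS = 1e-10  # coordinate descent yields exact zeros; this guards float noise


@njit(cache=True)
def _bcd(S, lam, tol, max_iter, W, B, K):  # pragma: no cover - jitted
    p = S.shape[0]
    gap = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        for j in range(p):
            beta = B[j]
            # lasso subproblem on column j by coordinate descent
            for _ in range(200):
                delta = 0.0
                for k in range(p):
                    if k == j:
                        continue
                    r = S[k, j] - (np.dot(W[k], beta) - W[k, k] * beta[k])
                    if r > lam:
                        new = (r - lam) / W[k, k]
                    elif r < -lam:
                        new = (r + lam) / W[k, k]
                    else:
                        new = 0.0
                    d = abs(new - beta[k])
                    if d > delta:
                        delta = d
                    beta[k] = new
                if delta < 0.1 * tol:
                    break
            w_new = np.dot(W, beta)
            for k in range(p):
                if k != j:
                    W[k, j] = w_new[k]
                    W[j, k] = w_new[k]
        # recover precision and evaluate the duality gap
        for j in range(p):
            denom = W[j, j]
            for k in range(p):
                denom -= W[k, j] * B[j][k]
            kjj = 1.0 / denom
            K[j, j] = kjj
            for k in range(p):
                if k != j:
                    K[k, j] = -B[j][k] * kjj
        for j in range(p):
            for k in range(j + 1, p):
                avg = 0.5 * (K[j, k] + K[k, j])
                K[j, k] = avg
                K[k, j] = avg
        # true duality gap: primal objective minus the dual objective at the
        # feasible point obtained by clipping W - S into the lam-box
        M = S.copy()
        for j in range(p):
            for k in range(p):
                if j != k:
                    u = W[j, k] - S[j, k]
                    if u > lam:
                        u = lam
                    elif u < -lam:
                        u = -lam
                    M[j, k] = S[j, k] + u
        ek = np.linalg.eigvalsh(K)
        em = np.linalg.eigvalsh(M)
        if ek[0] > 0.0 and em[0] > 0.0:
            primal = np.sum(S * K)
            for j in range(p):
                for k in range(p):
                    if j != k:
                        primal += lam * abs(K[j, k])
            primal -= np.sum(np.log(ek))
            dual = np.sum(np.log(em)) + p
            gap = primal - dual
            if abs(gap) < tol:
                return it, gap
    return it, gap


@dataclass
class GlassoSolution:
    """One graphical-lasso fit at a fixed penalty."""

    K: np.ndarray
    Theta_cov: np.ndarray
    lam: float
    iterations: int
    dual_gap: float
    converged: bool = True

    @property
    def edge_count(self) -> int:
        p = self.K.shape[0]
        iu = np.triu_indices(p, k=1)
        return int(np.sum(np.abs(self.K[iu]) > EDGE_EPS))


@dataclass
class NetworkModel:
    """An EBIC-selected partial-correlation network."""

    W: np.ndarray
    K: np.ndarray
    lambda_selected: float
    gamma: float
    n: int
    p: int
    lambda_path: np.ndarray
    ebic_trace: np.ndarray
    edge_count: int
    node_names: list[str] = field(default_factory=list)

    def edges(self) -> pd.DataFrame:
        """Tidy edge list of the nonzero upper-triangle weights."""
        names = self.node_names or [f"node_{i + 1}" for i in range(self.p)]
        rows = []
        for i in range(self.p):
            for j in range(i + 1, self.p):
                if abs(self.W[i, j]) > 0:
                    rows.append((names[i], names[j], self.W[i, j]))
        return pd.DataFrame(rows, columns=["node_i", "node_j", "weight"])

    @property
    def possible_edges(self) -> int:
        return self.p * (self.p - 1) // 2


def _as_matrix(S) -> tuple[np.ndarray, list[str]]:
    if isinstance(S, CorrelationMatrix):
        return np.asarray(S.S, dtype=float), list(S.item_names)
    S = np.asarray(S, dtype=float)
    return S, [f"node_{i + 1}" for i in range(S.shape[0])]


def _check_input(S: np.ndarray) -> None:
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be square")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S must be symmetric")
    if np.linalg.eigvalsh(S)[0] <= 0:
        raise ValueError("S must be positive definite (run PSD repair first)")


def glasso(
    S,
    lam: float,
    tol: float = 1e-6,
    max_iter: int = 500,
    warm: tuple[np.ndarray, np.ndarray] | None = None,
) -> GlassoSolution:
    """Graphical lasso at a single penalty ``lam``.

    Block coordinate descent on the working covariance; the diagonal is
    unpenalized. Returns when the primal-dual gap drops below ``tol``. At
    ``lam = 0`` the exact unpenalized MLE ``inv(S)`` is returned directly.
    """
    S, _ = _as_matrix(S)
    _check_input(S)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    p = S.shape[0]
    if lam == 0.0 or p == 1:
        K = np.linalg.inv(S)
        return GlassoSolution(K=K, Theta_cov=S.copy(), lam=lam, iterations=0, dual_gap=0.0)
    if warm is not None:
        W, B = warm
    else:
        W, B = S.copy(), np.zeros((p, p))
    K = np.empty((p, p))
    it, gap = _bcd(S, lam, tol, max_iter, W, B, K)
    converged = abs(gap) < tol
    sol = GlassoSolution(
        K=K.copy(), Theta_cov=W.copy(), lam=lam, iterations=it,
        dual_gap=float(gap), converged=converged,
    )
    sol._warm = (W, B)  # reused along a descending lambda path
    return sol


def glasso_objective(K: np.ndarray, S: np.ndarray, lam: float) -> float:
    """Penalized log-likelihood the estimator maximizes (up to constants)."""
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        return -np.inf
    off = np.abs(K).sum() - np.abs(np.diag(K)).sum()
    return float(logdet - np.sum(S * K) - lam * off)


def ebic(sol: GlassoSolution, S, n: int, gamma: float = 0.5) -> float:
    """Extended BIC: ``-2 L + E log(n) + 4 gamma E log(p)``.

    ``L = (n/2)(log det K - tr(S K))`` with the input correlation matrix
    standing in as the sample covariance, and ``E`` the number of nonzero
    off-diagonal *pairs* of K. Additive constants are dropped consistently
    across a lambda path, so only differences matter for selection.
    """
    S, _ = _as_matrix(S)
    if n < 2:
        raise ValueError("n must be >= 2")
    K = sol.K
    p = K.shape[0]
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        raise ValueError("precision estimate is not positive definite")
    L = 0.5 * n * (logdet - float(np.sum(S * K)))
    E = sol.edge_count
    return -2.0 * L + E * np.log(n) + 4.0 * gamma * E * np.log(p)


def to_partial_correlations(K: np.ndarray) -> np.ndarray:
    """Partial correlations ``W_ij = -K_ij / sqrt(K_ii K_jj)``, zero diagonal."""
    K = np.asarray(K, dtype=float)
    d = np.diag(K)
    if np.any(d <= 0):
        raise ValueError("precision matrix must have positive diagonal")
    W = -K / np.sqrt(np.outer(d, d))
    np.fill_diagonal(W, 0.0)
    return (W + W.T) / 2.0


def select_network(
    S,
    n: int,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> NetworkModel:
    """EBIC-selected graphical-lasso network over a log-spaced lambda path.

    The path runs from ``lambda_max`` (the largest off-diagonal |S|, at
    which the solution is empty) down to ``lambda_max * lambda_min_ratio``;
    fits reuse warm starts descending. Ties in EBIC resolve to the sparser
    (larger-lambda) model.
    """
    Smat, names = _as_matrix(S)
    _check_input(Smat)
    p = Smat.shape[0]
    iu = np.triu_indices(p, k=1)
    lam_max = float(np.max(np.abs(Smat[iu]))) if p > 1 else 0.0
    if lam_max <= 0.0:
        path = np.array([0.0])
    else:
        path = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)
    trace = np.empty(len(path))
    sols: list[GlassoSolution] = []
    warm = None
    failures = []
    for i, lam in enumerate(path):
        try:
            sol = glasso(Smat, float(lam), tol=tol, max_iter=max_iter, warm=warm)
            warm = getattr(sol, "_warm", None)
            if warm is not None:
                warm = (warm[0].copy(), warm[1].copy())
            trace[i] = ebic(sol, Smat, n, gamma)
        except Exception as exc:  # noqa: BLE001 - collected for diagnostics
            failures.append((float(lam), str(exc)))
            trace[i] = np.inf
            sol = None
        sols.append(sol)
    if all(s is None for s in sols):
        raise RuntimeError(f"all glasso fits failed along the path: {failures}")
    best = int(np.argmin(trace))  # first occurrence = largest lambda on ties
    sol = sols[best]
    W = to_partial_correlations(sol.K)
    W[np.abs(W) <= EDGE_EPS] = 0.0
    return NetworkModel(
        W=W,
        K=sol.K,
        lambda_selected=float(path[best]),
        gamma=gamma,
        n=n,
        p=p,
        lambda_path=path,
        ebic_trace=trace,
        edge_count=sol.edge_count,
        node_names=names,
    )
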