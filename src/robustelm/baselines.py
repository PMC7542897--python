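"""Closed-form and iteratively-reweighted ELM read-out solvers.

Three reference solvers for the output weights ``beta`` of an extreme
learning machine, each minimizing a different trade-off between fit and
regularization over the fixed hidden features ``H``:

* RELM — ridge read-out, min (1/2)||beta||_F^2 + (gamma/2)||T - H beta||_F^2,
  solved in one linear solve (two algebraically equivalent forms are used
  depending on whether samples or hidden nodes are more numerous).
* L2,1-RFELM — min (1/2)||beta||_{2,1} + (C/2)||T - H beta||_F^2: the row-wise
  L2,1 penalty prunes whole hidden nodes; solved by iterative reweighting.
* LR21ELM — min ||beta||_{2,1} + C ||T - H beta||_{2,1}: additionally replaces
  the squared loss by a row-wise L2,1 loss, down-weighting whole outlier
  samples; solved by alternating two reweighting diagonals.

All row-norm reciprocals are smoothed as 1 / (2 sqrt(||r||^2 + kappa)) with
a tiny kappa so that zero rows stay differentiable; with that smoothing each
reweighting step is a majorize-minimize step and the (smoothed) objective
decreases monotonically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "OutputWeights",
    "row_norm_weights",
    "smoothed_l21",
    "fit_relm",
    "fit_l21rfelm",
    "fit_lr21elm",
]

DEFAULT_KAPPA = 1e-6
DEFAULT_TOL = 1e-5
DEFAULT_MAX_ITER = 40


@dataclass
class OutputWeights:
    """Fitted output weight matrix plus solver bookkeeping."""

    beta: np.ndarray
    method: str
    n_iterations: int = 1
    converged: bool = True
    objective_trace: list = field(default_factory=list)


def row_norm_weights(B: np.ndarray, kappa: float = DEFAULT_KAPPA) -> np.ndarray:
    """Diagonal of the L2,1 reweighting matrix: 1 / (2 sqrt(||b_i||^2 + kappa))."""
    sq = np.einsum("ij,ij->i", B, B)
    return 1.0 / (2.0 * np.sqrt(sq + kappa))


def smoothed_l21(B: np.ndarray, kappa: float = DEFAULT_KAPPA) -> float:
    """Smoothed L2,1 norm: sum_i sqrt(||b_i||^2 + kappa)."""
    sq = np.einsum("ij,ij->i", B, B)
    return float(np.sum(np.sqrt(sq + kappa)))


def _spd_solve(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve A X = B for symmetric positive-definite A."""
    try:
        return scipy.linalg.solve(A, B, assume_a="pos")
    except np.linalg.LinAlgError as exc:  # pragma: no cover - numerical guard
        raise np.linalg.LinAlgError(
            f"linear solve failed (cond ~ {np.linalg.cond(A):.3e})"
        ) from exc


def fit_relm(H: np.ndarray, T: np.ndarray, gamma: float) -> OutputWeights:
    """Ridge-regularized ELM read-out (non-iterative).

    beta = (gamma H^T H + I_L)^{-1} gamma H^T T when N >= L, and the
    algebraically equivalent beta = H^T (gamma H H^T + I_N)^{-1} gamma T
    when N < L (cheaper: the solve is N x N).
    """
    H = np.asarray(H, dtype=float)
    T = np.asarray(T, dtype=float)
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if H.shape[0] != T.shape[0]:
        raise ValueError("H and T must have the same number of rows")
    N, L = H.shape
    if N >= L:
        beta = _spd_solve(gamma * H.T @ H + np.eye(L), gamma * H.T @ T)
    else:
        beta = H.T @ _spd_solve(gamma * H @ H.T + np.eye(N), gamma * T)
    return OutputWeights(beta=beta, method="relm", n_iterations=1, converged=True)


def _l21rfelm_beta(H, T, C, d):
    """One reweighted solve of the node-sparse read-out, branching on N vs L."""
    N, L = H.shape
    if N >= L:
        return _spd_solve(np.diag(d) + C * H.T @ H, C * H.T @ T)
    Dinv_Ht = H.T / d[:, None]
    return C * Dinv_Ht @ _spd_solve(np.eye(N) + C * H @ Dinv_Ht, T)


def fit_l21rfelm(
    H: np.ndarray,
    T: np.ndarray,
    C: float,
    kappa: float = DEFAULT_KAPPA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> OutputWeights:
    """Node-sparse ELM read-out via iteratively reweighted least squares.

    Alternates the reweighting diagonal D (from the current beta rows) with
    the closed-form beta that solves the weighted normal equations
    D beta = C H^T (T - H beta), starting from D = I.  Stops when the
    relative Frobenius change of beta drops below ``tol``.
    """
    H = np.asarray(H, dtype=float)
    T = np.asarray(T, dtype=float)
    if C <= 0:
        raise ValueError("C must be positive")
    N, L = H.shape
    d = np.ones(L)
    beta = _l21rfelm_beta(H, T, C, d)
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d = row_norm_weights(beta, kappa)
        beta_new = _l21rfelm_beta(H, T, C, d)
        trace.append(
            0.5 * smoothed_l21(beta_new, kappa)
            + 0.5 * C * float(np.sum((T - H @ beta_new) ** 2))
        )
        delta = np.linalg.norm(beta_new - beta) / max(np.linalg.norm(beta), 1e-30)
        beta = beta_new
        if delta < tol:
            converged = True
            break
    return OutputWeights(
        beta=beta,
        method="l21rfelm",
        n_iterations=it,
        converged=converged,
        objective_trace=trace,
    )


def _lr21elm_beta(H, T, C, d, d1):
    """One reweighted solve of the doubly row-sparse problem."""
    N, L = H.shape
    if N >= L:
        Ht_D1 = H.T * d1[None, :]
        return _spd_solve(Ht_D1 @ H + np.diag(d) / C, Ht_D1 @ T)
    Dinv_Ht = H.T / d[:, None]
    return Dinv_Ht @ _spd_solve(H @ Dinv_Ht + np.diag(1.0 / d1) / C, T)


def fit_lr21elm(
    H: np.ndarray,
    T: np.ndarray,
    C: float,
    kappa: float = DEFAULT_KAPPA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> OutputWeights:
    """Doubly row-sparse ELM read-out: L2,1 loss and L2,1 weight penalty.

    Alternates two reweighting diagonals — D from the rows of beta and D1
    from the rows of the residual xi = T - H beta (a sample with a huge
    residual gets a tiny D1 weight, i.e. is treated as an outlier) — with
    the closed-form beta of the doubly weighted quadratic.
    """
    H = np.asarray(H, dtype=float)
    T = np.asarray(T, dtype=float)
    if C <= 0:
        raise ValueError("C must be positive")
    N, L = H.shape
    beta = _lr21elm_beta(H, T, C, np.ones(L), np.ones(N))
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d = row_norm_weights(beta, kappa)
        d1 = row_norm_weights(T - H @ beta, kappa)
        beta_new = _lr21elm_beta(H, T, C, d, d1)
        trace.append(
            smoothed_l21(beta_new, kappa) + C * smoothed_l21(T - H @ beta_new, kappa)
        )
        delta = np.linalg.norm(beta_new - beta) / max(np.linalg.norm(beta), 1e-30)
        beta = beta_new
        if delta < tol:
            converged = True
            break
    return OutputWeights(
        beta=beta,
        method="lr21elm",
        n_iterations=it,
        converged=converged,
        objective_trace=trace,
    )
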