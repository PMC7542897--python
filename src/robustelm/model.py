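"""Correntropy-loss sparse graph-regularized ELM (CSRGELM).

The model replaces the squared loss of a ridge ELM read-out with the
correntropy induced loss

    c(xi_i) = 1 - exp(-||xi_i||^2 / (2 sigma^2)),      xi_i = t_i - h(x_i) beta,

which is bounded by 1, so a grossly mislabelled sample can contribute at
most a constant to the objective instead of a squared residual.  The full
training objective is

    F(beta) = sum_i c(xi_i)
              + (lambda/2) ||beta||_{2,1}
              + (C/2) Tr((H beta)^T Z (H beta)),

with Z the same-label graph Laplacian of the training set: the L2,1 penalty
prunes whole hidden nodes, the graph term asks same-class samples for
similar outputs.

F is non-convex, but the correntropy term admits a half-quadratic rewrite:
introducing per-sample auxiliaries tau_i < 0 (via the convex conjugate of
f(tau) = -tau log(-tau) + tau) turns each loss term into
inf_tau (1 - v_i tau_i + f(tau_i)) with v_i = ||xi_i||^2 / 2 sigma^2.  The
infimum is attained at tau_i = -exp(-v_i).  Each outer iteration therefore

  1. updates tau_i <- -exp(-||xi_i||^2 / 2 sigma^2) exactly, and
  2. solves the now *convex* fixed-tau subproblem in beta by alternating
     the L2,1 reweighting diagonal D <- diag(1 / (2 sqrt(||beta_i||^2 + kappa)))
     with the closed-form solve of the weighted quadratic until beta is
     stationary,

and neither step can increase the (kappa-smoothed) objective.  With omega = diag(-tau),
eta = lambda sigma^2 and rho = C sigma^2 the beta-update is

    beta = (eta D + H^T omega H + rho H^T Z H)^{-1} H^T omega T      (N >= L)

or the algebraically equivalent N x N form when hidden nodes outnumber
samples.  Small omega_i marks sample i as an outlier: it is soft-removed
from the normal equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .baselines import OutputWeights, fit_relm, row_norm_weights, smoothed_l21
from .data import Dataset, one_hot
from .graph import GraphLaplacian, label_similarity, laplacian
from .hidden import HiddenLayerMap, hidden_output, init_hidden_map

__all__ = [
    "CSRGELMParams",
    "HQState",
    "TrainedELM",
    "correntropy_loss",
    "objective",
    "update_tau",
    "solve_beta",
    "fit_csrgelm",
    "fit",
    "predict",
]


@dataclass(frozen=True)
class CSRGELMParams:
    """Hyperparameters of the correntropy-loss graph-regularized read-out.

    sigma : kernel bandwidth of the correntropy loss; residual norms beyond
        a few sigma saturate the loss and are effectively ignored.
    lam : weight of the L2,1 row-sparsity penalty on beta.
    C : weight of the graph-Laplacian smoothness penalty.
    n_hidden : number of random hidden nodes L.
    kappa : smoothing constant inside the row-norm reciprocals (default
        1e-6) keeping the reweighting finite at zero rows.
    max_iter : cap on (outer) half-quadratic iterations (default 40).
    tol : relative-objective-change stopping threshold (default 1e-4).
    inner_max_iter : cap on the D <-> beta reweighting sweeps used to solve
        the convex fixed-omega subproblem inside each outer iteration;
        1 recovers a single reweighting step per outer iteration.
    inner_tol : relative beta-change threshold ending the inner sweeps.
    """

    sigma: float = 1.0
    lam: float = 1.0
    C: float = 0.01
    n_hidden: int = 100
    kappa: float = 1e-6
    max_iter: int = 40
    tol: float = 1e-4
    inner_max_iter: int = 30
    inner_tol: float = 1e-8
    seed: int = 0
    init: str = "relm"  # or "zeros"
    coding: str = "zero_one"

    def __post_init__(self) -> None:
        if min(self.sigma, self.lam, self.C, self.kappa, self.tol) <= 0:
            raise ValueError("sigma, lam, C, kappa and tol must be positive")
        if min(self.n_hidden, self.max_iter, self.inner_max_iter) < 1:
            raise ValueError("n_hidden, max_iter and inner_max_iter must be >= 1")


@dataclass
class HQState:
    """Half-quadratic auxiliaries of the final accepted iteration."""

    tau: np.ndarray
    omega: np.ndarray
    row_weights: np.ndarray
    objective_trace: list
    iteration: int


@dataclass
class TrainedELM:
    """Frozen hidden map + fitted output weights + class codebook."""

    hidden: HiddenLayerMap
    weights: OutputWeights
    classes: tuple
    params: object = None
    hq_state: HQState | None = None


def correntropy_loss(residual_sq: np.ndarray, sigma: float) -> np.ndarray:
    """Per-sample correntropy induced loss 1 - exp(-r^2 / 2 sigma^2).

    Takes *squared* residual norms; each loss value lies in [0, 1), rising
    from 0 at a perfect fit and saturating at 1 for arbitrarily large
    residuals — the boundedness that makes the loss robust.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    residual_sq = np.asarray(residual_sq, dtype=float)
    if np.any(residual_sq < 0):
        raise ValueError("squared residuals must be nonnegative")
    return 1.0 - np.exp(-residual_sq / (2.0 * sigma**2))


def _residual_sq_rows(H: np.ndarray, T: np.ndarray, beta: np.ndarray) -> np.ndarray:
    R = T - H @ beta
    return np.einsum("ij,ij->i", R, R)


def objective(
    beta: np.ndarray,
    H: np.ndarray,
    T: np.ndarray,
    Z: np.ndarray,
    params: CSRGELMParams,
    kappa: float = 0.0,
) -> float:
    """Training objective F(beta); ``kappa > 0`` smooths the L2,1 term.

    The solver monitors the smoothed variant (kappa = params.kappa), which
    is the quantity its majorize-minimize steps provably decrease.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (H.shape[1], T.shape[1]):
        raise ValueError("beta shape inconsistent with H and T")
    loss = float(np.sum(correntropy_loss(_residual_sq_rows(H, T, beta), params.sigma)))
    if kappa > 0:
        l21 = smoothed_l21(beta, kappa)
    else:
        l21 = float(np.sum(np.linalg.norm(beta, axis=1)))
    HB = H @ beta
    graph = float(np.trace(HB.T @ Z @ HB))
    return loss + 0.5 * params.lam * l21 + 0.5 * params.C * graph


def update_tau(
    H: np.ndarray, T: np.ndarray, beta: np.ndarray, sigma: float
) -> np.ndarray:
    """Exact half-quadratic auxiliary update.

    tau_i = -exp(-||t_i - h(x_i) beta||^2 / 2 sigma^2), always in [-1, 0);
    omega_i = -tau_i is the effective weight of sample i in the next
    quadratic subproblem (1 for a perfectly fitted sample, -> 0 for an
    outlier).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return -np.exp(-_residual_sq_rows(H, T, beta) / (2.0 * sigma**2))


def solve_beta(
    H: np.ndarray,
    T: np.ndarray,
    Z: np.ndarray,
    omega: np.ndarray,
    row_weights: np.ndarray,
    params: CSRGELMParams,
    HtZH: np.ndarray | None = None,
) -> np.ndarray:
    """Closed-form minimizer of the fixed-(omega, D) quadratic surrogate.

    Solves the stationarity condition

        -(1/sigma^2) H^T omega (T - H beta) + lambda D beta + C H^T Z H beta = 0

    using the L x L system when samples are at least as numerous as hidden
    nodes, and the equivalent N x N system otherwise.  ``HtZH`` may carry a
    precomputed H^T Z H (it is constant across iterations).
    """
    H = np.asarray(H, dtype=float)
    T = np.asarray(T, dtype=float)
    omega = np.asarray(omega, dtype=float)
    d = np.asarray(row_weights, dtype=float)
    N, L = H.shape
    eta = params.lam * params.sigma**2
    rho = params.C * params.sigma**2
    Ht_omega_T = H.T @ (omega[:, None] * T)
    try:
        if N >= L:
            if HtZH is None:
                HtZH = H.T @ Z @ H
            A = eta * np.diag(d) + H.T @ (omega[:, None] * H) + rho * HtZH
            return scipy.linalg.solve(A, Ht_omega_T, assume_a="pos")
        Dinv_Ht = H.T / d[:, None]
        HDinvHt = H @ Dinv_Ht
        A = (
            np.eye(N)
            + (1.0 / eta) * (omega[:, None] * HDinvHt)
            + (params.C / params.lam) * (Z @ HDinvHt)
        )
        return (1.0 / eta) * Dinv_Ht @ scipy.linalg.solve(
            A, omega[:, None] * T, assume_a="gen"
        )
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError) as exc:
        raise np.linalg.LinAlgError(
            f"beta solve failed (system size {min(N, L)})"
        ) from exc


def fit_csrgelm(
    X: np.ndarray,
    y: np.ndarray,
    params: CSRGELMParams,
    graph: GraphLaplacian | None = None,
    classes: tuple | None = None,
) -> TrainedELM:
    """Fit the correntropy-loss sparse graph-regularized ELM.

    Builds the seeded random hidden layer, 0/1 one-hot targets and (unless
    supplied) the same-label graph Laplacian, and initializes beta with the
    ridge (RELM) solution at gamma = C.  Each outer iteration performs the
    exact tau-update and then solves the resulting convex fixed-omega
    subproblem by D <-> beta reweighting sweeps (at most
    ``params.inner_max_iter`` of them); the loop stops when the relative
    change of the smoothed objective falls below ``params.tol`` or after
    ``params.max_iter`` outer iterations.  The per-outer-iteration
    objective trace, final tau/omega and row weights are kept on the
    returned model.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y must have the same number of rows")
    if classes is None:
        classes = tuple(np.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    codes = {c: k for k, c in enumerate(classes)}
    y_codes = np.asarray([codes[v] for v in y.tolist()], dtype=int)
    T = one_hot(y_codes, len(classes), coding=params.coding)

    hidden = init_hidden_map(X.shape[1], params.n_hidden, seed=params.seed)
    H = hidden_output(hidden, X)
    if graph is None:
        graph = laplacian(label_similarity(y_codes))
    Z = graph.Z
    HtZH = H.T @ Z @ H if X.shape[0] >= params.n_hidden else None

    if params.init == "relm":
        beta = fit_relm(H, T, gamma=params.C).beta
    elif params.init == "zeros":
        beta = np.zeros((params.n_hidden, len(classes)))
    else:
        raise ValueError(f"unknown init {params.init!r}")

    trace = [objective(beta, H, T, Z, params, kappa=params.kappa)]
    tau = update_tau(H, T, beta, params.sigma)
    d = row_norm_weights(beta, params.kappa)
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        tau = update_tau(H, T, beta, params.sigma)
        for _ in range(params.inner_max_iter):
            d = row_norm_weights(beta, params.kappa)
            beta_new = solve_beta(H, T, Z, -tau, d, params, HtZH=HtZH)
            step = np.linalg.norm(beta_new - beta) / max(np.linalg.norm(beta), 1e-30)
            beta = beta_new
            if step < params.inner_tol:
                break
        trace.append(objective(beta, H, T, Z, params, kappa=params.kappa))
        rel = abs(trace[-1] - trace[-2]) / max(abs(trace[-2]), 1e-30)
        if rel < params.tol:
            converged = True
            break

    weights = OutputWeights(
        beta=beta,
        method="csrgelm",
        n_iterations=it,
        converged=converged,
        objective_trace=list(trace),
    )
    state = HQState(
        tau=tau,
        omega=-tau,
        row_weights=d,
        objective_trace=list(trace),
        iteration=it,
    )
    return TrainedELM(
        hidden=hidden, weights=weights, classes=classes, params=params, hq_state=state
    )


def fit(
    X: np.ndarray,
    y: np.ndarray,
    method: str = "csrgelm",
    n_hidden: int = 100,
    seed: int = 0,
    classes: tuple | None = None,
    **hyper,
) -> TrainedELM:
    """Uniform fitting front-end over all four read-out solvers.

    ``method`` is one of ``relm`` (hyper: gamma), ``l21rfelm`` / ``lr21elm``
    (hyper: C, kappa, tol, max_iter) or ``csrgelm`` (hyper: any
    CSRGELMParams field).  Baselines share the same seeded hidden map and
    0/1 one-hot coding as the robust model.
    """
    if method == "csrgelm":
        params = CSRGELMParams(n_hidden=n_hidden, seed=seed, **hyper)
        return fit_csrgelm(X, y, params, classes=classes)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if classes is None:
        classes = tuple(np.unique(y).tolist())
    codes = {c: k for k, c in enumerate(classes)}
    y_codes = np.asarray([codes[v] for v in y.tolist()], dtype=int)
    T = one_hot(y_codes, len(classes))
    hidden = init_hidden_map(X.shape[1], n_hidden, seed=seed)
    H = hidden_output(hidden, X)
    if method == "relm":
        weights = fit_relm(H, T, gamma=hyper.get("gamma", 1.0))
    elif method == "l21rfelm":
        from .baselines import fit_l21rfelm

        weights = fit_l21rfelm(H, T, **{"C": 1.0, **hyper})
    elif method == "lr21elm":
        from .baselines import fit_lr21elm

        weights = fit_lr21elm(H, T, **{"C": 1.0, **hyper})
    else:
        raise ValueError(f"unknown method {method!r}")
    return TrainedELM(hidden=hidden, weights=weights, classes=classes, params=hyper)


def predict(model: TrainedELM, X: np.ndarray) -> np.ndarray:
    """Predicted class labels: argmax over output columns, first-index ties.

    The graph penalty acts only at training time; prediction is the plain
    network forward pass h(x) beta.
    """
    H = hidden_output(model.hidden, X)
    scores = H @ model.weights.beta
    idx = np.argmax(scores, axis=1)
    return np.asarray(model.classes, dtype=object)[idx]


def decision_scores(model: TrainedELM, X: np.ndarray) -> np.ndarray:
    """Raw per-class network outputs h(x) beta."""
    return hidden_output(model.hidden, X) @ model.weights.beta
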