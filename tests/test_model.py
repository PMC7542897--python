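import numpy as np
import pytest
from scipy.optimize import minimize

from robustelm import (
    CSRGELMParams,
    SyntheticSpec,
    correntropy_loss,
    fit,
    fit_csrgelm,
    gaussian_classes,
    label_similarity,
    laplacian,
    objective,
    predict,
    solve_beta,
    update_tau,
)
from robustelm.baselines import smoothed_l21
from robustelm.hidden import HiddenLayerMap
from robustelm.model import TrainedELM
from robustelm.baselines import OutputWeights


def _random_problem(rng, N, L, M):
    H = rng.uniform(0.05, 0.95, size=(N, L))
    y = rng.integers(0, M, size=N)
    y[:M] = np.arange(M)  # every class present
    T = np.zeros((N, M))
    T[np.arange(N), y] = 1.0
    Z = laplacian(label_similarity(y)).Z
    return H, T, Z, y


# ------------------------------------------------------- loss and objective

def test_correntropy_loss_closed_forms():
    sigma = 0.7
    assert correntropy_loss(np.array([0.0]), sigma)[0] == 0.0
    half = correntropy_loss(np.array([2 * sigma**2 * np.log(2)]), sigma)[0]
    assert half == pytest.approx(0.5)
    assert correntropy_loss(np.array([1e12]), sigma)[0] == pytest.approx(1.0)


def test_correntropy_loss_rejects_bad_inputs():
    with pytest.raises(ValueError):
        correntropy_loss(np.array([1.0]), sigma=0.0)
    with pytest.raises(ValueError):
        correntropy_loss(np.array([-1.0]), sigma=1.0)


def test_objective_vanishes_for_zero_problem(rng):
    params = CSRGELMParams(sigma=1.0, lam=1.0, C=1.0, n_hidden=3)
    H = rng.uniform(size=(5, 3))
    Z = laplacian(label_similarity(np.array([0, 0, 1, 1, 1]))).Z
    assert objective(np.zeros((3, 2)), H, np.zeros((5, 2)), Z, params) == 0.0


def test_objective_closed_form_at_zero_weights(rng):
    params = CSRGELMParams(sigma=0.8, lam=2.0, C=1.0, n_hidden=3)
    H, T, Z, _ = _random_problem(rng, 6, 3, 2)
    expected = np.sum(1 - np.exp(-np.sum(T**2, axis=1) / (2 * 0.8**2)))
    assert objective(np.zeros((3, 2)), H, T, Z, params) == pytest.approx(expected)


def test_objective_matches_termwise_brute_force(rng):
    params = CSRGELMParams(sigma=1.3, lam=0.7, C=0.4, n_hidden=4)
    H, T, Z, _ = _random_problem(rng, 8, 4, 2)
    beta = rng.normal(size=(4, 2))
    loss = sum(
        1 - np.exp(-np.sum((T[i] - H[i] @ beta) ** 2) / (2 * 1.3**2))
        for i in range(8)
    )
    l21 = sum(np.sqrt(np.sum(beta[i] ** 2)) for i in range(4))
    HB = H @ beta
    graph = sum(HB[:, k] @ Z @ HB[:, k] for k in range(2))
    expected = loss + 0.5 * 0.7 * l21 + 0.5 * 0.4 * graph
    assert objective(beta, H, T, Z, params) == pytest.approx(expected, abs=1e-12)


# ------------------------------------------------------- tau update

def test_tau_closed_forms(rng):
    H = np.eye(3)
    beta = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
    T = np.array([[1.0, 0.0], [0.0, 1.0], [10.0, 10.0]])
    tau = update_tau(H, T, beta, sigma=1.0)
    assert tau[0] == pytest.approx(-1.0)  # zero residual
    assert tau[1] == pytest.approx(-1.0)
    assert -1e-8 < tau[2] < 0  # huge residual -> weight ~ 0
    # ||xi||^2 = 2 sigma^2 gives tau = -1/e
    T2 = np.array([[1.0 + np.sqrt(2.0), 0.0], [0.0, 1.0], [0.0, 0.0]])
    tau2 = update_tau(H, T2, beta, sigma=1.0)
    assert tau2[0] == pytest.approx(-np.exp(-1.0))
    assert np.all(tau < 0) and np.all(-tau <= 1.0)


# ------------------------------------------------------- beta subproblem

def test_solve_beta_reduces_to_ridge_without_graph(rng):
    """With omega = 1, D = I and no graph coupling the update is a ridge solve."""
    H, T, Z, _ = _random_problem(rng, 8, 3, 2)
    params = CSRGELMParams(sigma=1.0, lam=2.0, C=1.0, n_hidden=3)
    beta = solve_beta(H, T, np.zeros_like(Z), np.ones(8), np.ones(3), params)
    ridge = np.linalg.solve(2.0 * np.eye(3) + H.T @ H, H.T @ T)
    assert np.allclose(beta, ridge, atol=1e-10)


def test_solve_beta_branch_equivalence(rng):
    """The L x L and N x N solution formulas agree when N = L."""
    N = L = 5
    H, T, Z, _ = _random_problem(rng, N, L, 2)
    params = CSRGELMParams(sigma=0.9, lam=0.5, C=0.2, n_hidden=L)
    omega = rng.uniform(0.2, 1.0, size=N)
    d = rng.uniform(0.5, 2.0, size=L)
    primal = solve_beta(H, T, Z, omega, d, params)
    # force the dual branch by viewing the same system as N < L
    from robustelm import model as m

    Dinv_Ht = H.T / d[:, None]
    eta = params.lam * params.sigma**2
    A = (
        np.eye(N)
        + (1 / eta) * (omega[:, None] * (H @ Dinv_Ht))
        + (params.C / params.lam) * (Z @ (H @ Dinv_Ht))
    )
    dual = (1 / eta) * Dinv_Ht @ np.linalg.solve(A, omega[:, None] * T)
    assert np.allclose(primal, dual, rtol=1e-6)


def test_solve_beta_satisfies_stationarity(rng):
    for N, L in [(12, 5), (5, 12)]:
        H, T, Z, _ = _random_problem(rng, N, L, 2)
        params = CSRGELMParams(sigma=0.8, lam=0.3, C=0.1, n_hidden=L)
        omega = rng.uniform(0.1, 1.0, size=N)
        d = rng.uniform(0.5, 2.0, size=L)
        beta = solve_beta(H, T, Z, omega, d, params)
        grad = (
            -(1 / params.sigma**2) * H.T @ (omega[:, None] * (T - H @ beta))
            + params.lam * d[:, None] * beta
            + params.C * H.T @ Z @ H @ beta
        )
        assert np.linalg.norm(grad) < 1e-8 * (
            1 + np.linalg.norm(H.T @ (omega[:, None] * T))
        )


def test_solve_beta_matches_surrogate_minimizer(rng):
    """Closed form equals a generic minimizer of the fixed-omega, fixed-D quadratic."""
    H, T, Z, _ = _random_problem(rng, 8, 3, 2)
    params = CSRGELMParams(sigma=1.1, lam=0.6, C=0.3, n_hidden=3)
    omega = rng.uniform(0.2, 1.0, size=8)
    d = rng.uniform(0.5, 2.0, size=3)

    def surrogate(B):
        R = T - H @ B
        data = np.sum(omega * np.sum(R**2, axis=1)) / (2 * params.sigma**2)
        reg = 0.5 * params.lam * np.sum(d * np.sum(B**2, axis=1))
        HB = H @ B
        return data + reg + 0.5 * params.C * np.trace(HB.T @ Z @ HB)

    res = minimize(lambda v: surrogate(v.reshape(3, 2)), np.zeros(6),
                   method="L-BFGS-B",
                   options={"maxiter": 20000, "ftol": 1e-16, "gtol": 1e-12})
    assert np.allclose(solve_beta(H, T, Z, omega, d, params),
                       res.x.reshape(3, 2), atol=1e-5)


# ------------------------------------------------------- full fit

def test_separable_gaussians_fit_to_high_training_accuracy(gaussian_dataset):
    ds = gaussian_dataset
    params = CSRGELMParams(sigma=1.0, lam=1.0, C=0.01, n_hidden=100, seed=0)
    model = fit_csrgelm(ds.X, ds.y, params)
    acc = np.mean(predict(model, ds.X) == ds.y)
    assert acc >= 0.99
    assert model.weights.converged


def test_objective_trace_non_increasing_under_label_noise():
    from robustelm import inject_label_noise

    ds = gaussian_classes(SyntheticSpec(seed=3))
    noisy = inject_label_noise(ds, 50, from_class=1, to_class=0, seed=3)
    params = CSRGELMParams(sigma=1.0, lam=1.0, C=0.01, n_hidden=100, seed=3)
    model = fit_csrgelm(noisy.X, noisy.y, params)
    trace = np.asarray(model.weights.objective_trace)
    assert np.all(np.diff(trace) <= 1e-8)
    assert model.weights.converged


def test_half_quadratic_descent_over_random_instances(rng):
    """Smoothed objective never increases, across many random problems."""
    for _ in range(15):
        N = int(rng.integers(20, 80))
        L = int(rng.integers(5, 40))
        M = int(rng.integers(2, 4))
        X = rng.normal(size=(N, 3))
        y = rng.integers(0, M, size=N)
        y[:M] = np.arange(M)
        params = CSRGELMParams(
            sigma=float(rng.uniform(0.3, 2.0)),
            lam=float(10.0 ** rng.uniform(-2, 1)),
            C=float(10.0 ** rng.uniform(-4, -1)),
            n_hidden=L,
            seed=int(rng.integers(0, 2**16)),
            max_iter=12,
        )
        model = fit_csrgelm(X, y, params)
        trace = np.asarray(model.weights.objective_trace)
        assert np.all(np.diff(trace) <= 1e-8)
        omega = model.hq_state.omega
        assert np.all(omega > 0) and np.all(omega <= 1)
        assert np.all(model.hq_state.tau < 0)


def test_large_bandwidth_limit_recovers_weighted_ridge(rng):
    """As sigma -> inf with eta, rho held fixed, all omega -> 1."""
    H, T, Z, y = _random_problem(rng, 10, 4, 2)
    sigma = 1e6
    eta, rho = 0.5, 0.05  # target lam * sigma^2 and C * sigma^2
    params = CSRGELMParams(sigma=sigma, lam=eta / sigma**2, C=rho / sigma**2,
                           n_hidden=4)
    d = np.ones(4)
    limit = solve_beta(H, T, Z, np.ones(10), d, params)
    explicit = np.linalg.solve(
        eta * np.eye(4) + H.T @ H + rho * H.T @ Z @ H, H.T @ T
    )
    assert np.allclose(limit, explicit, atol=1e-4)


def test_fit_rejects_single_class():
    X = np.random.default_rng(0).normal(size=(10, 2))
    with pytest.raises(ValueError):
        fit_csrgelm(X, np.zeros(10, dtype=int), CSRGELMParams())


def test_predict_argmax_and_tie_break():
    hidden = HiddenLayerMap(np.zeros((2, 1)), np.zeros(2))  # H = 0.5 always
    beta = np.array([[1.8, 0.2], [0.0, 0.0]])  # scores [0.9, 0.1]
    model = TrainedELM(hidden=hidden,
                       weights=OutputWeights(beta=beta, method="relm"),
                       classes=("pos", "neg"))
    assert predict(model, [[0.0]])[0] == "pos"
    model.weights.beta = np.array([[1.0, 1.0], [0.0, 0.0]])  # exact tie
    assert predict(model, [[0.0]])[0] == "pos"  # lowest class index wins


def test_predict_shape_error():
    model = fit(np.random.default_rng(0).normal(size=(20, 3)),
                np.array([0, 1] * 10), method="relm", n_hidden=5)
    with pytest.raises(ValueError):
        predict(model, np.zeros((2, 4)))


def test_csrgelm_sparser_than_relm(gaussian_dataset):
    ds = gaussian_dataset
    robust = fit(ds.X, ds.y, method="csrgelm", seed=0, sigma=1.0, lam=1.0, C=0.01)
    ridge = fit(ds.X, ds.y, method="relm", seed=0, gamma=1.0)

    def near_zero_fraction(beta):
        norms = np.linalg.norm(beta, axis=1)
        return np.mean(norms < 0.01 * norms.max())

    assert near_zero_fraction(robust.weights.beta) > near_zero_fraction(
        ridge.weights.beta
    )
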