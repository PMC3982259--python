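import numpy as np
import pytest

from fsvmcip import Dataset, HyperParams, KernelFSVMCIP, KernelSpec, gram, tau_squared
from fsvmcip.kernel import (
    assemble_M,
    assemble_Q,
    decision_kernel,
    fit_kernel,
    predict_kernel,
    sigma_grid,
)
from fsvmcip.linear import (
    assemble_linear_dual,
    decision_linear,
    recover_linear,
    solve_dual,
)
from fsvmcip.locality import GraphParams, build_graph, kernel_sq_dists, pairwise_sq_dists, scatter_linear
from fsvmcip.membership import MembershipParams, compute_membership
from conftest import random_dataset, random_hyperparams


def test_gram_basics(rng):
    X = rng.normal(size=(5, 3))
    K = gram(X, X, KernelSpec("rbf", sigma=2.0))
    np.testing.assert_allclose(np.diag(K), 1.0)
    assert np.array_equal(K, K.T)
    np.testing.assert_allclose(gram(X, X, KernelSpec("linear")), X @ X.T)


def test_tau_squared_hand_computation():
    X = np.array([[1.0, 0.0], [0.0, 2.0], [2.0, 2.0]])
    # squared norms: 1, 4, 8 -> mean 13/3
    assert tau_squared(X) == pytest.approx(13.0 / 3.0)
    grid = sigma_grid(X)
    assert len(grid) == 9
    assert grid[4] == pytest.approx(13.0 / 3.0)
    assert grid[0] == pytest.approx(13.0 / 48.0)
    # entry check with sigma = tau^2
    K = gram(X, X, KernelSpec("rbf", sigma=13.0 / 3.0))
    assert K[0, 1] == pytest.approx(np.exp(-5.0 / (13.0 / 3.0)))


def test_Q_reduces_to_K(rng):
    # eta = 0, and identical class members, both give Q = K
    X = rng.normal(size=(6, 2))
    y = np.array([1, 1, 1, -1, -1, -1])
    K = gram(X, X, KernelSpec("rbf", sigma=1.0))
    G = build_graph(y, kernel_sq_dists(K), GraphParams(k=1, t=1.0))
    np.testing.assert_allclose(assemble_Q(K, y, G, eta=0.0), K, atol=1e-12)
    Xd = np.vstack([np.ones((3, 2)), np.full((3, 2), 3.0)])
    Kd = gram(Xd, Xd, KernelSpec("rbf", sigma=1.0))
    Gd = build_graph(y, kernel_sq_dists(Kd), GraphParams(k=1, t=1.0))
    np.testing.assert_allclose(assemble_Q(Kd, y, Gd, eta=5.0), Kd, atol=1e-10)


def test_M_linear_kernel_simplification(rng):
    # full-rank linear kernel, eta = 0: M = Y K Y elementwise y_i y_j K_ij
    X = rng.normal(size=(4, 4)) + np.eye(4)
    y = np.array([1, 1, -1, -1])
    K = X @ X.T
    M, ridge = assemble_M(K, y, K)
    np.testing.assert_allclose(M, (y[:, None] * y[None, :]) * K, atol=1e-6)


def test_M_is_psd_on_random_instances(rng):
    for _ in range(6):
        ds = random_dataset(rng)
        K = gram(ds.X, ds.X, KernelSpec("rbf", sigma=1.5))
        G = build_graph(ds.y, kernel_sq_dists(K), GraphParams(k=2, t=1.0))
        Q = assemble_Q(K, ds.y, G, eta=1.0)
        M, _ = assemble_M(K, ds.y, Q)
        eigs = np.linalg.eigvalsh(M)
        assert eigs.min() >= -1e-8 * max(np.abs(eigs).max(), 1e-300)
        assert np.allclose(M, M.T)


def test_linear_kernel_reduction_matches_linear_core(rng):
    # adjudication check: with the linear kernel and eta = 0, kernel decision
    # values must reproduce the linear machinery's
    for _ in range(5):
        ds = random_dataset(rng, n_pos=7, n_neg=4, dim=3)
        mu = compute_membership(ds, MembershipParams(family="exponential", lam=0.5))
        hp = random_hyperparams(rng, ds, mu, eta_choices=(0.0,))
        S = scatter_linear(ds, build_graph(ds.y, pairwise_sq_dists(ds.X), hp.graph))
        dp = assemble_linear_dual(ds, mu, hp, S)
        sol = recover_linear(ds, mu, hp, S, solve_dual(dp))
        model = fit_kernel(ds, mu, hp, KernelSpec("linear"))
        Xtest = np.vstack([ds.X, ds.X.mean(axis=0, keepdims=True)])
        np.testing.assert_allclose(
            decision_kernel(model, Xtest), decision_linear(sol, Xtest), atol=1e-6
        )


def test_label_factor_threshold_variant_breaks_reduction(rng):
    # the printed extra y_j inside the threshold expansion double-counts the
    # labels; it must disagree with the linear reduction whenever negative
    # support-vector contributions are nonzero
    ds = random_dataset(rng, n_pos=6, n_neg=4, dim=2)
    mu = compute_membership(ds, MembershipParams(family="exponential", lam=0.5))
    hp = random_hyperparams(rng, ds, mu, eta_choices=(0.0,))
    S = scatter_linear(ds, build_graph(ds.y, pairwise_sq_dists(ds.X), hp.graph))
    sol = recover_linear(ds, mu, hp, S, solve_dual(assemble_linear_dual(ds, mu, hp, S)))
    variant = fit_kernel(ds, mu, hp, KernelSpec("linear"), threshold_label_factor=True)
    assert variant.metadata["threshold_variant"] == "label_factor"
    assert abs(variant.b_star - sol.b_star) > 1e-6


def test_xor_pattern_is_separable_with_rbf():
    ds = Dataset(
        X=np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]]),
        y=np.array([1, 1, -1, -1]),
    )
    # nu large enough that the feature-space margin gap nu*delta^2 clears 2
    hp = HyperParams(
        nu=4.0, v1=0.125, v2=0.125, eta=0.0,
        graph=GraphParams(k=1, t=1.0),
        membership=MembershipParams(family="exponential", lam=0.0),
    )
    est = KernelFSVMCIP(hp, KernelSpec("rbf", sigma=0.5)).fit(ds)
    assert np.array_equal(est.predict(ds.X), ds.y)
    assert est.model_.rho_star > 0


def test_representer_consistency(rng):
    # training decision values computed through beta on K and through alpha
    # via M's defining algebra must coincide: y_i (M alpha)_i = (K beta)_i
    ds = random_dataset(rng, n_pos=6, n_neg=4, dim=2)
    mu = compute_membership(ds, MembershipParams(family="exponential", lam=0.5))
    hp = random_hyperparams(rng, ds, mu)
    model = fit_kernel(ds, mu, hp, KernelSpec("rbf", sigma=tau_squared(ds.X)))
    K = gram(ds.X, ds.X, model.spec)
    G = build_graph(ds.y, kernel_sq_dists(K), hp.graph)
    Q = assemble_Q(K, ds.y, G, hp.eta)
    M, _ = assemble_M(K, ds.y, Q)
    np.testing.assert_allclose(ds.y * (M @ model.alpha), K @ model.beta, atol=1e-6)


def test_duplicate_training_point_same_decision(rng):
    ds = random_dataset(rng, n_pos=5, n_neg=3, dim=2)
    mu = np.ones(ds.n_samples)
    hp = random_hyperparams(rng, ds, mu)
    model = fit_kernel(ds, mu, hp, KernelSpec("rbf", sigma=2.0))
    d_train = decision_kernel(model, ds.X[2:3])
    d_dup = decision_kernel(model, ds.X[2:3].copy())
    assert d_train[0] == pytest.approx(d_dup[0], abs=1e-12)


def test_singular_gram_is_handled_by_ridge():
    # duplicated rows make the linear-kernel Gram singular
    X = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [3.0, 3.0], [3.0, 3.0]])
    y = np.array([1, 1, 1, -1, -1])
    ds = Dataset(X=X, y=y)
    hp = HyperParams(
        nu=1.0, v1=0.2, v2=0.2, eta=0.5,
        graph=GraphParams(k=1, t=1.0),
        membership=MembershipParams(family="exponential", lam=0.0),
    )
    model = fit_kernel(ds, np.ones(5), hp, KernelSpec("linear"))
    assert np.isfinite(model.beta).all()
    assert np.array_equal(predict_kernel(model, X), y)


def test_kernel_estimator_uses_feature_space_membership(rng):
    ds = random_dataset(rng, n_pos=8, n_neg=4, dim=2)
    hp = HyperParams(
        nu=2.0, v1=0.05, v2=0.05, eta=1.0,
        membership=MembershipParams(family="linear"),
    )
    est = KernelFSVMCIP(hp, KernelSpec("rbf", sigma=tau_squared(ds.X))).fit(ds)
    from fsvmcip.membership import kernel_membership

    K = gram(ds.X, ds.X, est.spec)
    expected = kernel_membership(K, ds.y, MembershipParams(family="linear", space="feature"))
    np.testing.assert_allclose(est.mu_, expected)
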