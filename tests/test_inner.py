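import numpy as np
import pytest

import focesens as fs
from focesens.compile import SolverConfig
from focesens.inner import solve_inner

from conftest import scalar_individual
from oracles import scalar_model_values

TIGHT = SolverConfig(rtol=1e-10, atol=1e-12)


class TestScalarClosedForms:
    """yhat = theta + eta, one observation d=1, sigma^2 = omega^2 = 1."""

    def test_loglik_value(self, scalar_model):
        ind = scalar_individual(d=1.0)
        l = fs.individual_loglik(scalar_model.inner, ind, [0.0], [0.0], TIGHT)
        assert np.isclose(l, -0.5 - np.log(2 * np.pi), atol=1e-10)

    def test_gradient_value(self, scalar_model):
        ind = scalar_individual(d=1.0)
        g = fs.grad_li_eta(scalar_model.inner, ind, [0.0], [0.0], TIGHT)
        assert np.isclose(g[0], 1.0, atol=1e-10)

    def test_approximate_hessian(self, scalar_model):
        ind = scalar_individual(d=1.0)
        H = fs.hessians_li_eta(
            scalar_model.inner, ind, [0.0], [0.0], mode="approx", solver=TIGHT
        )
        assert np.isclose(H[0, 0], -2.0, atol=1e-10)

    def test_posterior_mode(self, scalar_model):
        ind = scalar_individual(d=1.0)
        sol = solve_inner(scalar_model.inner, ind, [0.0], tol_digits=8, solver=TIGHT)
        oracle = scalar_model_values(1.0, 0.0)
        assert np.isclose(sol.eta_star[0], oracle["eta_star"], atol=1e-7)

    def test_stationary_start_returns_immediately(self, scalar_model):
        ind = scalar_individual(d=1.0)
        sol = solve_inner(scalar_model.inner, ind, [0.0], tol_digits=6, solver=TIGHT)
        again = solve_inner(
            scalar_model.inner, ind, [0.0], eta0=sol.eta_star,
            tol_digits=6, solver=TIGHT,
        )
        assert again.iterations <= 1
        assert np.allclose(again.eta_star, sol.eta_star, atol=1e-8)


def test_perfect_fit_reduces_to_determinant_terms(lingauss):
    """With eps = 0 and eta = 0 only the log det terms of l_i survive."""
    k, b, s2, w = 0.7, 4.0, 0.3, 0.5
    times = np.array([0.5, 1.0, 2.0])
    dv = b * np.exp(-k * times)  # exactly the eta=0 prediction
    ind = fs.IndividualRecord(id="1", times=times, dv=dv, t0=0.0)
    l = fs.individual_loglik(lingauss.inner, ind, [k, b, s2, w], [0.0], TIGHT)
    expected = -0.5 * (3 * np.log(2 * np.pi * s2) + np.log(2 * np.pi * w))
    assert np.isclose(l, expected, atol=1e-9)


def test_doubling_omega_lowers_loglik_by_half_log_two(lingauss):
    times = np.array([0.5, 1.0, 2.0])
    dv = np.array([3.0, 2.0, 1.0])
    ind = fs.IndividualRecord(id="1", times=times, dv=dv, t0=0.0)
    l1 = fs.individual_loglik(lingauss.inner, ind, [0.7, 4.0, 0.3, 0.5], [0.0], TIGHT)
    l2 = fs.individual_loglik(lingauss.inner, ind, [0.7, 4.0, 0.3, 1.0], [0.0], TIGHT)
    assert np.isclose(l1 - l2, 0.5 * np.log(2.0), atol=1e-9)


def test_eta_gradient_matches_finite_differences(m1, m1_small_data):
    cm = m1.compiled()
    data, _ = m1_small_data
    rng = np.random.default_rng(3)
    th = m1.theta_true * rng.uniform(0.9, 1.1, 6)
    eta = rng.normal(0, 0.2, 3)
    ind = data.individuals[0]
    g = fs.grad_li_eta(cm.inner, ind, th, eta, TIGHT)
    for k in range(3):
        h = 1e-6
        ep, em = eta.copy(), eta.copy()
        ep[k] += h
        em[k] -= h
        fd = (
            fs.individual_loglik(cm.inner, ind, th, ep, TIGHT)
            - fs.individual_loglik(cm.inner, ind, th, em, TIGHT)
        ) / (2 * h)
        assert abs(g[k] - fd) <= 1e-4 * max(abs(fd), 1.0)


def test_gradient_vanishes_at_eta_star(m1, m1_small_data):
    cm = m1.compiled()
    data, _ = m1_small_data
    sol = solve_inner(cm.inner, data.individuals[1], m1.theta_true,
                      tol_digits=6, solver=TIGHT)
    g = fs.grad_li_eta(cm.inner, data.individuals[1], m1.theta_true,
                       sol.eta_star, TIGHT)
    assert np.max(np.abs(g)) <= 1e-4 * max(1.0, np.max(np.abs(sol.eta_star)))


def test_exact_hessian_matches_fd_of_gradient(m1, m1_small_data):
    cm = m1.compiled()
    data, _ = m1_small_data
    rng = np.random.default_rng(4)
    th = m1.theta_true * rng.uniform(0.9, 1.1, 6)
    eta = rng.normal(0, 0.2, 3)
    ind = data.individuals[2]
    He = fs.hessians_li_eta(cm.outer, ind, th, eta, mode="exact", solver=TIGHT)
    np.testing.assert_allclose(He, He.T, atol=1e-12)
    for k in range(3):
        h = 1e-6
        ep, em = eta.copy(), eta.copy()
        ep[k] += h
        em[k] -= h
        fd = (
            fs.grad_li_eta(cm.inner, ind, th, ep, TIGHT)
            - fs.grad_li_eta(cm.inner, ind, th, em, TIGHT)
        ) / (2 * h)
        np.testing.assert_allclose(He[:, k], fd, rtol=2e-4, atol=1e-6)


def test_foce_focei_hessians_equal_for_constant_R(m1, m1_small_data):
    """M1 has a state- and eta-free residual variance, so the interaction
    terms vanish and the two approximate Hessians coincide."""
    cm = m1.compiled()
    data, _ = m1_small_data
    ind = data.individuals[0]
    eta = np.array([0.1, -0.1, 0.2])
    Hf = fs.hessians_li_eta(cm.inner, ind, m1.theta_true, eta,
                            mode="approx", method="FOCE", solver=TIGHT)
    Hi = fs.hessians_li_eta(cm.inner, ind, m1.theta_true, eta,
                            mode="approx", method="FOCEI", solver=TIGHT)
    np.testing.assert_allclose(Hf, Hi, rtol=0, atol=1e-13)


def test_exact_equals_approx_hessian_for_linear_model(lingauss, lingauss_data):
    """h linear in (x, eta), f linear in x, R constant: the dropped
    second-order terms are identically zero."""
    ind = lingauss_data.individuals[0]
    th = [0.7, 4.0, 0.3, 0.5]
    Ha = fs.hessians_li_eta(lingauss.inner, ind, th, [0.2], mode="approx",
                            solver=TIGHT)
    He = fs.hessians_li_eta(lingauss.outer, ind, th, [0.2], mode="exact",
                            solver=TIGHT)
    np.testing.assert_allclose(Ha, He, rtol=1e-8)
    # and -H equals the conjugate posterior precision Omega^-1 + G'R^-1 G
    G = np.exp(-0.7 * ind.times)
    prec = 1.0 / 0.5 + G @ G / 0.3
    assert np.isclose(-Ha[0, 0], prec, rtol=1e-8)


def test_inner_solution_respects_digit_tolerance(m1, m1_small_data):
    cm = m1.compiled()
    data, _ = m1_small_data
    for ind in data:
        sol = solve_inner(cm.inner, ind, m1.theta_true, tol_digits=6, solver=TIGHT)
        scale = max(1.0, np.max(np.abs(sol.eta_star)))
        assert sol.grad_norm <= 1e-3 * scale
        assert np.all(np.linalg.eigvalsh(-sol.approx_hessian) > 0)


def test_posterior_collapses_to_truth_as_noise_vanishes(lingauss):
    """Data generated at eta = 0.3 with tiny residual noise pins eta*."""
    k, b, s2, w = 0.7, 4.0, 1e-8, 0.5
    times = np.array([0.5, 1.0, 2.0])
    dv = (b + 0.3) * np.exp(-k * times)
    ind = fs.IndividualRecord(id="1", times=times, dv=dv, t0=0.0)
    sol = solve_inner(lingauss.inner, ind, [k, b, s2, w], tol_digits=8,
                      solver=TIGHT)
    assert abs(sol.eta_star[0] - 0.3) < 1e-4
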