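import numpy as np
import pytest

import focesens as fs
from focesens.compile import SolverConfig
from focesens.gradient import (
    deta_star_dtheta,
    grad_logLF,
    mixed_second_derivatives,
    dli_dtheta_at_star,
    dH_dtheta,
)
from focesens.inner import solve_inner
from focesens.objective import population_loglik

from conftest import LINGAUSS_THETA, LINGAUSS_TIMES, scalar_individual
from oracles import lingauss_marginal, lingauss_posterior, scalar_model_values

TIGHT = SolverConfig(rtol=1e-10, atol=1e-12)
VTIGHT = SolverConfig(rtol=1e-12, atol=1e-14)


class TestScalarClosedForms:
    """yhat = theta + eta with d = 1, sigma^2 = omega^2 = 1."""

    def test_mixed_second_derivative(self, scalar_model):
        ind = scalar_individual(d=1.0)
        M = mixed_second_derivatives(scalar_model.outer, ind, [0.0], [0.0], TIGHT)
        oracle = scalar_model_values(1.0, 0.0)
        # d/dtheta of dl/deta = d(eps - eta)/dtheta = -1/sigma^2
        assert np.isclose(M[0, 0], oracle["mixed"], atol=1e-9)

    def test_implicit_derivative(self, scalar_model):
        ind = scalar_individual(d=1.0)
        sol = solve_inner(scalar_model.inner, ind, [0.0], tol_digits=10,
                          solver=TIGHT)
        M = mixed_second_derivatives(
            scalar_model.outer, ind, [0.0], sol.eta_star, TIGHT
        )
        He = fs.hessians_li_eta(scalar_model.outer, ind, [0.0], sol.eta_star,
                                mode="exact", solver=TIGHT)
        dd = deta_star_dtheta(He, M)
        assert np.isclose(dd[0, 0], scalar_model_values(1.0, 0.0)["deta_dtheta"],
                          atol=1e-8)


def test_linear_gaussian_gradient_is_exact(lingauss, lingauss_data):
    """grad log L_F equals the analytic gradient of the exact marginal."""
    val, inners = population_loglik(
        lingauss.inner, lingauss_data, LINGAUSS_THETA, "FOCE",
        tol_digits=10, solver=VTIGHT,
    )
    og = grad_logLF(lingauss.outer, lingauss_data, LINGAUSS_THETA, "FOCE",
                    inners, VTIGHT)
    _, g_cf = lingauss_marginal(
        LINGAUSS_THETA, LINGAUSS_TIMES, [ind.dv for ind in lingauss_data]
    )
    np.testing.assert_allclose(og.grad, g_cf, rtol=1e-8, atol=1e-10)


def test_eta_star_and_implicit_derivative_match_conjugate_forms(
    lingauss, lingauss_data
):
    val, inners = population_loglik(
        lingauss.inner, lingauss_data, LINGAUSS_THETA, "FOCE",
        tol_digits=10, solver=VTIGHT,
    )
    grad_logLF(lingauss.outer, lingauss_data, LINGAUSS_THETA, "FOCE",
               inners, VTIGHT)
    for ind, sol in zip(lingauss_data, inners):
        eta_cf, dd_cf = lingauss_posterior(LINGAUSS_THETA, LINGAUSS_TIMES, ind.dv)
        assert np.isclose(sol.eta_star[0], eta_cf, atol=1e-9)
        np.testing.assert_allclose(sol.deta_dtheta[0], dd_cf, rtol=1e-7,
                                   atol=1e-10)


def test_outer_gradient_matches_central_fd(m1, m1_small_data):
    """The sensitivity-equation gradient agrees with a central FD of the
    objective computed with tight inner and solver tolerances."""
    cm = m1.compiled()
    data, _ = m1_small_data
    th = m1.theta_true * np.array([1.1, 0.9, 1.05, 1.2, 0.8, 1.1])
    val, inners = population_loglik(cm.inner, data, th, "FOCE",
                                    tol_digits=10, solver=VTIGHT)
    og = grad_logLF(cm.outer, data, th, "FOCE", inners, VTIGHT)
    eta0 = [s.eta_star for s in inners]
    for m in range(6):
        h = 1e-3 * abs(th[m])
        tp, tm_ = th.copy(), th.copy()
        tp[m] += h
        tm_[m] -= h
        vp, _ = population_loglik(cm.inner, data, tp, "FOCE", eta0=eta0,
                                  tol_digits=10, solver=VTIGHT)
        vm, _ = population_loglik(cm.inner, data, tm_, "FOCE", eta0=eta0,
                                  tol_digits=10, solver=VTIGHT)
        fd = (vp.logLF - vm.logLF) / (2 * h)
        assert abs(og.grad[m] - fd) <= 1e-3 * max(abs(fd), 0.1)


def test_focei_gradient_matches_central_fd_on_interaction_model(m3):
    """Proportional error makes R depend on eta both directly and through
    the states; the FOCEI gradient must still track the objective."""
    cm = m3.compiled()
    data, _ = fs.simulate_population(m3, N=2, seed=3)
    rng = np.random.default_rng(0)
    th = m3.theta_true * (1 + 0.1 * rng.uniform(-1, 1, m3.theta_true.size))
    val, inners = population_loglik(cm.inner, data, th, "FOCEI",
                                    tol_digits=10, solver=VTIGHT)
    og = grad_logLF(cm.outer, data, th, "FOCEI", inners, VTIGHT)
    eta0 = [s.eta_star for s in inners]
    for m in range(th.size):
        h = 1e-4 * abs(th[m])
        tp, tm_ = th.copy(), th.copy()
        tp[m] += h
        tm_[m] -= h
        vp, _ = population_loglik(cm.inner, data, tp, "FOCEI", eta0=eta0,
                                  tol_digits=10, solver=VTIGHT)
        vm, _ = population_loglik(cm.inner, data, tm_, "FOCEI", eta0=eta0,
                                  tol_digits=10, solver=VTIGHT)
        fd = (vp.logLF - vm.logLF) / (2 * h)
        assert abs(og.grad[m] - fd) <= 2e-3 * max(abs(fd), 0.1)


def test_dH_dtheta_is_symmetric_and_matches_fd(m1, m1_small_data):
    cm = m1.compiled()
    data, _ = m1_small_data
    ind = data.individuals[0]
    th = m1.theta_true * np.array([1.1, 0.9, 1.05, 1.2, 0.8, 1.1])
    sol = solve_inner(cm.inner, ind, th, tol_digits=11, solver=VTIGHT)
    dH = dH_dtheta(cm.outer, ind, th, sol, method="FOCE", solver=VTIGHT)
    np.testing.assert_allclose(dH, np.swapaxes(dH, 1, 2), atol=1e-12)

    def H_at(thv):
        s = solve_inner(cm.inner, ind, thv, eta0=sol.eta_star, tol_digits=11,
                        solver=VTIGHT)
        return fs.hessians_li_eta(cm.inner, ind, thv, s.eta_star,
                                  mode="approx", method="FOCE", solver=VTIGHT)

    for m in [0, 3]:  # one structural, one covariance parameter
        h = 1e-4 * abs(th[m])
        tp, tm_ = th.copy(), th.copy()
        tp[m] += h
        tm_[m] -= h
        fd = (H_at(tp) - H_at(tm_)) / (2 * h)
        np.testing.assert_allclose(dH[m], fd, rtol=1e-3, atol=5e-3)


def test_pure_omega_parameter_pieces(m1, m1_small_data):
    """For a parameter appearing only in Omega the data terms vanish:
    dl*/dtheta_m reduces to the prior expression and the mixed matrix
    column to the Omega term."""
    cm = m1.compiled()
    data, _ = m1_small_data
    ind = data.individuals[1]
    th = m1.theta_true.copy()
    sol = solve_inner(cm.inner, ind, th, tol_digits=8, solver=TIGHT)
    dli = dli_dtheta_at_star(cm.outer, ind, th, sol, TIGHT)
    om = np.diag(th[3:])
    om_inv = np.linalg.inv(om)
    eta = sol.eta_star
    for j, m in enumerate([3, 4, 5]):
        dOm = np.zeros((3, 3))
        dOm[j, j] = 1.0
        expected = 0.5 * eta @ om_inv @ dOm @ om_inv @ eta - 0.5 * np.trace(
            om_inv @ dOm
        )
        assert np.isclose(dli[m], expected, rtol=1e-6, atol=1e-9)


def test_implicit_function_quadratic_remainder(m1, m1_small_data):
    """After a theta step delta, the predicted eta* + (deta*/dtheta) delta
    leaves an inner gradient of size O(|delta|^2)."""
    cm = m1.compiled()
    data, _ = m1_small_data
    ind = data.individuals[0]
    th = m1.theta_true
    sol = solve_inner(cm.inner, ind, th, tol_digits=11, solver=VTIGHT)
    He = fs.hessians_li_eta(cm.outer, ind, th, sol.eta_star, mode="exact",
                            solver=VTIGHT)
    M = mixed_second_derivatives(cm.outer, ind, th, sol.eta_star, VTIGHT)
    dd = deta_star_dtheta(He, M)
    rng = np.random.default_rng(9)
    direction = rng.normal(size=6)
    direction /= np.linalg.norm(direction)
    norms = []
    for scale in (1e-2, 1e-3, 1e-4):
        delta = scale * direction * np.abs(th)
        g = fs.grad_li_eta(cm.inner, ind, th + delta,
                           sol.eta_star + dd @ delta, VTIGHT)
        norms.append(np.linalg.norm(g))
    # quadratic scaling: each 10x smaller step shrinks the norm ~100x
    assert norms[1] <= 0.05 * norms[0]
    assert norms[2] <= 0.05 * norms[1]


def test_gradient_requires_stationary_inner_solutions(m1, m1_small_data):
    cm = m1.compiled()
    data, _ = m1_small_data
    val, inners = population_loglik(cm.inner, data, m1.theta_true, tol_digits=6)
    inners[0].eta_star = inners[0].eta_star + 0.5  # stale
    inners[0].grad_norm = 10.0
    with pytest.raises(fs.PreconditionError):
        grad_logLF(cm.outer, data, m1.theta_true, "FOCE", inners)
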