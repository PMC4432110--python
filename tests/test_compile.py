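import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import focesens as fs
from focesens.compile import SolverConfig, count_equations, integrate
from focesens.errors import DomainError


TIGHT = SolverConfig(rtol=1e-11, atol=1e-13)


@pytest.mark.parametrize(
    "n,p,q,level,expected",
    [
        (2, 0, 3, "inner", 8),     # M1/M2 inner
        (2, 0, 4, "inner", 10),    # M3/M4 inner
        (2, 3, 3, "outer", 44),    # M1 outer
        (2, 5, 3, "outer", 60),    # M2 outer
        (2, 5, 4, "outer", 80),    # M3/M4 outer
        (5, 0, 0, "inner", 5),     # no random effects in the ODE
        (3, 0, 0, "outer", 3),
    ],
)
def test_equation_counts(n, p, q, level, expected):
    assert count_equations(n, p, q, level) == expected


def test_equation_count_rejects_negative_inputs():
    with pytest.raises(DomainError):
        count_equations(0, 1, 1, "inner")
    with pytest.raises(DomainError):
        count_equations(2, -1, 1, "outer")
    with pytest.raises(DomainError):
        count_equations(2, 1, 1, "middle")


@settings(derandomize=True, max_examples=60)
@given(
    n=st.integers(1, 8), p=st.integers(0, 12), q=st.integers(0, 8)
)
def test_outer_count_equals_expanded_block_sum(n, p, q):
    """The factored count n(1+q)(1+p+q/2) equals the explicit sum of the
    state, eta, theta, mixed and unordered second-order eta blocks."""
    blocks = n * (1 + q + p + p * q + q * (q + 1) // 2)
    assert count_equations(n, p, q, "outer") == blocks


def test_compiled_benchmark_totals(m1, m3):
    cm1, cm3 = m1.compiled(), m3.compiled()
    assert cm1.inner.total_equations == 8
    assert cm1.outer.total_equations == 44
    assert cm3.inner.total_equations == 10
    assert cm3.outer.total_equations == 80
    # second-order eta blocks stored once per unordered pair
    pairs = [k for k in cm3.outer.layout if k[0] == "eta_eta"]
    assert len(pairs) == 4 * 5 // 2
    assert all(k[1] <= k[2] for k in pairs)


@pytest.fixture(scope="module")
def decay():
    """dx/dt = -k e^{eta} x, x0 = 1: closed-form x = exp(-k e^{eta} t)."""
    decl = {
        "states": ["x"],
        "odes": {"x": "-(k * exp(eta1)) * x"},
        "x0": ["1.0"],
        "observations": [{"h": "x", "r": "0.01"}],
        "theta": ["k"],
        "eta": ["eta1"],
        "omega": {"diagonal": ["0.1"]},
    }
    return fs.compile_model(fs.build_model(decl))


def test_sensitivities_match_closed_form(decay):
    k, e1 = 0.8, 0.3
    times = np.array([0.5, 1.0, 2.0])
    ind = fs.IndividualRecord(id="1", times=times, dv=np.zeros(3), t0=0.0)
    traj = integrate(decay.outer, ind, [k], [e1], TIGHT)
    a = k * np.exp(e1)
    x = np.exp(-a * times)
    np.testing.assert_allclose(traj.x[:, 0], x, rtol=1e-8)
    np.testing.assert_allclose(traj.S_eta[:, 0, 0], -a * times * x, rtol=1e-7)
    np.testing.assert_allclose(
        traj.S_theta[:, 0, 0], -np.exp(e1) * times * x, rtol=1e-7
    )
    # d2x/deta dk = e^eta t x (a t - 1); d2x/deta2 = a t x (a t - 1)
    np.testing.assert_allclose(
        traj.S_eta_theta[:, 0, 0, 0],
        np.exp(e1) * times * x * (a * times - 1.0),
        rtol=1e-6,
    )
    np.testing.assert_allclose(
        traj.S_eta_eta[:, 0, 0, 0],
        a * times * x * (a * times - 1.0),
        rtol=1e-6,
    )


def test_zero_influence_eta_block_is_dropped_and_zero():
    """A random effect appearing only in the observation model produces no
    sensitivity equations and an identically zero dense block."""
    decl = {
        "states": ["x"],
        "odes": {"x": "-k*x"},
        "x0": ["1.0"],
        "observations": [{"h": "x * exp(eta2)", "r": "0.01"}],
        "theta": ["k"],
        "eta": ["eta1", "eta2"],
        "omega": {"diagonal": ["0.1", "0.1"]},
    }
    # note eta1 influences nothing at all; eta2 only h
    cm = fs.compile_model(fs.build_model(decl))
    assert cm.inner.q == 0
    assert cm.inner.total_equations == 1
    ind = fs.IndividualRecord(id="1", times=np.array([1.0]), dv=np.array([0.5]))
    traj = integrate(cm.inner, ind, [0.5], [0.1, -0.2], TIGHT)
    assert np.all(traj.S_eta == 0.0)


def test_sensitivity_blocks_match_reintegrated_finite_differences(m1):
    """Central FD of re-integrated trajectories confirms every block on the
    nonlinear benchmark."""
    cm = m1.compiled()
    rng = np.random.default_rng(11)
    th = m1.theta_true * rng.uniform(0.9, 1.1, 6)
    eta = rng.normal(0, 0.2, 3)
    times = np.array([0.5, 2.0, 8.0])
    ind = fs.IndividualRecord(id="1", times=times, dv=np.zeros(3), t0=0.0)
    traj = integrate(cm.outer, ind, th, eta, TIGHT)

    def xs(thv, ev):
        return integrate(cm.inner, ind, thv, ev, TIGHT).x

    for k in range(3):
        h = 1e-6
        ep, em = eta.copy(), eta.copy()
        ep[k] += h
        em[k] -= h
        fd = (xs(th, ep) - xs(th, em)) / (2 * h)
        np.testing.assert_allclose(traj.S_eta[:, :, k], fd, rtol=1e-4, atol=1e-8)
    for m in range(3):  # the three structural parameters
        h = 1e-6 * th[m]
        tp, tm_ = th.copy(), th.copy()
        tp[m] += h
        tm_[m] -= h
        fd = (xs(tp, eta) - xs(tm_, eta)) / (2 * h)
        np.testing.assert_allclose(traj.S_theta[:, :, m], fd, rtol=1e-4, atol=1e-8)
    # mixed block via FD of the eta-sensitivity in theta
    def se(thv):
        return integrate(cm.outer, ind, thv, eta, TIGHT).S_eta

    m = 0
    h = 1e-6 * th[m]
    tp, tm_ = th.copy(), th.copy()
    tp[m] += h
    tm_[m] -= h
    fd = (se(tp) - se(tm_)) / (2 * h)
    np.testing.assert_allclose(
        traj.S_eta_theta[:, :, :, m], fd, rtol=1e-4, atol=1e-7
    )


def test_second_order_eta_block_symmetry(m1, m1_small_data):
    cm = m1.compiled()
    data, _ = m1_small_data
    traj = integrate(cm.outer, data.individuals[0], m1.theta_true, [0.1, -0.2, 0.05])
    np.testing.assert_allclose(
        traj.S_eta_eta, np.swapaxes(traj.S_eta_eta, 2, 3), rtol=0, atol=1e-12
    )


def test_integration_failure_carries_time():
    decl = {
        "states": ["x"],
        "odes": {"x": "k * x**2"},  # finite-time blow-up at t = 1/(k x0)
        "x0": ["10.0"],
        "observations": [{"h": "x", "r": "1.0"}],
        "theta": ["k"],
        "eta": ["eta1"],
        "omega": {"diagonal": ["0.1"]},
    }
    cm = fs.compile_model(fs.build_model(decl))
    ind = fs.IndividualRecord(id="1", times=np.array([5.0]), dv=np.array([0.0]))
    with pytest.raises(fs.IntegrationError) as err:
        integrate(cm.inner, ind, [1.0], [0.0])
    assert err.value.t is not None


def test_piecewise_constant_covariate_segments():
    """An input covariate that switches value mid-experiment is integrated
    segment-wise: dx/dt = -k x + u with u stepping from 0 to 2 at t=1."""
    decl = {
        "states": ["x"],
        "odes": {"x": "-k*x + u"},
        "x0": ["1.0"],
        "observations": [{"h": "x", "r": "0.01"}],
        "theta": ["k"],
        "eta": ["eta1"],
        "omega": {"diagonal": ["0.1"]},
        "covariates": ["u"],
    }
    cm = fs.compile_model(fs.build_model(decl))
    k = 0.5
    times = np.array([0.5, 1.0, 2.0])
    ind = fs.IndividualRecord(
        id="1", times=times, dv=np.zeros(3), t0=0.0,
        covariates={"u": (np.array([0.0, 1.0]), np.array([0.0, 2.0]))},
    )
    traj = integrate(cm.inner, ind, [k], [0.0], TIGHT)
    # segment 1: pure decay; segment 2: decay toward u/k = 4
    x1 = np.exp(-k * 1.0)
    expected = np.array(
        [
            np.exp(-k * 0.5),
            x1,
            4.0 + (x1 - 4.0) * np.exp(-k * 1.0),
        ]
    )
    np.testing.assert_allclose(traj.x[:, 0], expected, rtol=1e-8)
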