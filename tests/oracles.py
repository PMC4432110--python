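"""Independent closed-form oracles used by the test suite.

Everything here is computed directly from textbook Gaussian algebra with
plain numpy — none of it goes through the package's sensitivity or
likelihood code paths.
"""

import numpy as np

LOG2PI = float(np.log(2.0 * np.pi))


def lingauss_design(k, times):
    """Design vector G_j = exp(-k t_j) of the one-state decay model
    dx/dt = -k x, x0 = b + eta, h = x."""
    return np.exp(-k * np.asarray(times, dtype=float))


def lingauss_marginal(theta, times, dvs):
    """Exact marginal log-likelihood and gradient for the linear-Gaussian
    decay model with theta = (k, b, s2, w): d_i ~ N(b G, w G G' + s2 I).

    ``dvs`` is a list of per-individual observation vectors.
    """
    k, b, s2, w = theta
    times = np.asarray(times, dtype=float)
    G = lingauss_design(k, times)
    T = times.size
    Sig = w * np.outer(G, G) + s2 * np.eye(T)
    iS = np.linalg.inv(Sig)
    dG = -times * G
    dmu = {0: b * dG, 1: G, 2: np.zeros(T), 3: np.zeros(T)}
    dSig = {
        0: w * (np.outer(dG, G) + np.outer(G, dG)),
        1: np.zeros((T, T)),
        2: np.eye(T),
        3: np.outer(G, G),
    }
    _, logdet = np.linalg.slogdet(Sig)
    l = 0.0
    grad = np.zeros(4)
    for dv in dvs:
        r = np.asarray(dv, dtype=float) - b * G
        l += -0.5 * (r @ iS @ r + logdet + T * LOG2PI)
        for m in range(4):
            grad[m] += (
                dmu[m] @ iS @ r
                - 0.5 * np.trace(iS @ dSig[m])
                + 0.5 * r @ iS @ dSig[m] @ iS @ r
            )
    return l, grad


def lingauss_posterior(theta, times, dv):
    """Conjugate posterior mode of eta and its theta-sensitivities for one
    individual of the decay model; returns (eta_star, deta_dtheta[4])."""
    k, b, s2, w = theta
    times = np.asarray(times, dtype=float)
    G = lingauss_design(k, times)
    dG = -times * G
    r = np.asarray(dv, dtype=float) - b * G
    prec = 1.0 / w + G @ G / s2
    num = G @ r / s2
    eta = num / prec
    # partials by direct differentiation of eta(theta) = num/prec
    dnum = {
        0: (dG @ r - G @ (b * dG)) / s2,
        1: -(G @ G) / s2,
        2: -num / s2,
        3: 0.0,
    }
    dprec = {0: 2.0 * (G @ dG) / s2, 1: 0.0, 2: -(G @ G) / s2**2, 3: -1.0 / w**2}
    dd = np.array(
        [(dnum[m] * prec - num * dprec[m]) / prec**2 for m in range(4)]
    )
    return eta, dd


def scalar_model_values(d, theta, s2=1.0, w=1.0):
    """Closed forms for the degenerate model yhat = theta + eta with one
    observation d: eta*, l at eta=0, inner gradient at eta=0, the
    approximate/exact Hessian, d2l/deta dtheta and deta*/dtheta."""
    eps0 = d - theta
    eta_star = w * eps0 / (w + s2)
    l0 = -0.5 * (eps0**2 / s2 + np.log(2 * np.pi * s2) + np.log(2 * np.pi * w))
    grad0 = eps0 / s2
    hess = -1.0 / s2 - 1.0 / w
    mixed = -1.0 / s2
    deta_dtheta = -w / (w + s2)
    return {
        "eta_star": eta_star,
        "l_at_zero": l0,
        "grad_at_zero": grad0,
        "hessian": hess,
        "mixed": mixed,
        "deta_dtheta": deta_dtheta,
    }
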