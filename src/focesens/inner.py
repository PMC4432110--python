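"""The inner problem: individual joint log-likelihood and its eta-optimum.

For individual i with residuals eps_j = d_j - yhat_j and scalar residual
variances R_j per output group, the joint log-likelihood of data and random
effects is

    l_i = -1/2 sum_j [ eps_j^2 / R_j + log(2 pi R_j) ]
          - 1/2 eta' Omega^-1 eta - 1/2 log det(2 pi Omega).

Its gradient with respect to eta uses the total derivatives of eps and R
through the state sensitivities dx/deta (chain rule through h and R), and
the inner problem max_eta l_i is solved by BFGS with that exact gradient.
Both the exact Hessian d2l/deta2 (second-order terms kept) and the
first-order approximate Hessian H_i used in the FOCE/FOCEI objective are
assembled here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .compile import (
    CompiledSensitivitySystem,
    SolverConfig,
    Trajectory,
    covariate_vector,
    integrate,
)
from .data import IndividualRecord
from .errors import (
    DomainError,
    InnerFailureError,
    IntegrationError,
    NumericDomainError,
)

__all__ = [
    "ObsCache",
    "InnerSolution",
    "individual_loglik",
    "grad_li_eta",
    "hessians_li_eta",
    "solve_inner",
]

LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class GroupCache:
    rows: np.ndarray
    eps: np.ndarray          # (T,)
    R: np.ndarray            # (T,)
    deps_eta: np.ndarray | None = None    # (T, d)
    dR_eta: np.ndarray | None = None
    deps_th: np.ndarray | None = None     # (T, P)
    dR_th: np.ndarray | None = None
    d2eps_ee: np.ndarray | None = None    # (T, d, d)
    d2R_ee: np.ndarray | None = None
    d2eps_et: np.ndarray | None = None    # (T, d, P)
    d2R_et: np.ndarray | None = None


@dataclass
class ObsCache:
    """Residuals, residual variances, Omega factors and their derivatives
    for one individual at a given (theta, eta), to the requested order."""

    groups: list
    omega: np.ndarray
    omega_inv: np.ndarray
    omega_logdet: float
    eta: np.ndarray
    theta: np.ndarray
    order: int


def _chain_scalar(nb, path, t, x, theta, eta, z, S_eta, S_theta, S_et, S_ee, order):
    """Total derivatives of one scalar model function (h or r entry)."""
    g = {}
    val = float(nb.eval(path + ("val",), t, x, theta, eta, z))
    Hx = nb.eval(path + ("x",), t, x, theta, eta, z)
    He = nb.eval(path + ("eta",), t, x, theta, eta, z)
    g["val"] = val
    g["eta"] = He + Hx @ S_eta
    if order >= 2:
        Ht = nb.eval(path + ("theta",), t, x, theta, eta, z)
        Hxx = nb.eval(path + ("x_x",), t, x, theta, eta, z)
        Hxt = nb.eval(path + ("x_theta",), t, x, theta, eta, z)
        Hex = nb.eval(path + ("eta_x",), t, x, theta, eta, z)
        Het = nb.eval(path + ("eta_theta",), t, x, theta, eta, z)
        Hee = nb.eval(path + ("eta_eta",), t, x, theta, eta, z)
        g["theta"] = Ht + Hx @ S_theta
        g["eta_eta"] = (
            Hee
            + Hex @ S_eta
            + (Hex @ S_eta).T
            + S_eta.T @ Hxx @ S_eta
            + np.einsum("a,akl->kl", Hx, S_ee)
        )
        g["eta_theta"] = (
            Het
            + Hex @ S_theta
            + S_eta.T @ Hxt
            + S_eta.T @ Hxx @ S_theta
            + np.einsum("a,akm->km", Hx, S_et)
        )
    return g


def evaluate_observations(
    system: CompiledSensitivitySystem,
    individual: IndividualRecord,
    traj: Trajectory,
    theta,
    eta,
    order: int = 1,
) -> ObsCache:
    """Residuals/variances and their eta (order>=1) and theta/second-order
    (order>=2) total derivatives at every observation.

    ``order=2`` requires an outer-level trajectory.
    """
    spec = system.spec
    nb = system.numeric
    theta = np.asarray(theta, dtype=float)
    eta = np.asarray(eta, dtype=float)
    d, P = spec.d, spec.P
    if order >= 2 and traj.S_theta is None:
        raise DomainError("order-2 observation cache needs an outer-level trajectory")

    groups = []
    for g in range(1, spec.n_outputs + 1):
        rows = individual.group_rows(g)
        T = rows.size
        gc = GroupCache(
            rows=rows, eps=np.zeros(T), R=np.zeros(T),
            deps_eta=np.zeros((T, d)), dR_eta=np.zeros((T, d)),
        )
        if order >= 2:
            gc.deps_th = np.zeros((T, P))
            gc.dR_th = np.zeros((T, P))
            gc.d2eps_ee = np.zeros((T, d, d))
            gc.d2R_ee = np.zeros((T, d, d))
            gc.d2eps_et = np.zeros((T, d, P))
            gc.d2R_et = np.zeros((T, d, P))
        for j, row in enumerate(rows):
            t = float(individual.times[row])
            tr = traj.row(t)
            x = traj.x[tr]
            z = covariate_vector(spec, individual, t)
            Se = traj.S_eta[tr]
            St = traj.S_theta[tr] if order >= 2 else None
            Set = traj.S_eta_theta[tr] if order >= 2 else None
            See = traj.S_eta_eta[tr] if order >= 2 else None
            hd = _chain_scalar(
                nb, ("h", g - 1), t, x, theta, eta, z, Se, St, Set, See, order
            )
            rd = _chain_scalar(
                nb, ("r", g - 1), t, x, theta, eta, z, Se, St, Set, See, order
            )
            if rd["val"] <= 0.0 or not np.isfinite(rd["val"]):
                raise NumericDomainError(
                    f"residual variance R is not positive (individual "
                    f"{individual.id}, t={t}, output {g})"
                )
            gc.eps[j] = individual.dv[row] - hd["val"]
            gc.R[j] = rd["val"]
            gc.deps_eta[j] = -hd["eta"]
            gc.dR_eta[j] = rd["eta"]
            if order >= 2:
                gc.deps_th[j] = -hd["theta"]
                gc.dR_th[j] = rd["theta"]
                gc.d2eps_ee[j] = -hd["eta_eta"]
                gc.d2R_ee[j] = rd["eta_eta"]
                gc.d2eps_et[j] = -hd["eta_theta"]
                gc.d2R_et[j] = rd["eta_theta"]
        groups.append(gc)

    om, _, om_inv, logdet = nb.omega_factor(theta)
    return ObsCache(
        groups=groups, omega=om, omega_inv=om_inv, omega_logdet=logdet,
        eta=eta, theta=theta, order=order,
    )


# ---------------------------------------------------------------------------
# likelihood pieces assembled from a cache


def loglik_from_cache(cache: ObsCache) -> float:
    l = 0.0
    for gc in cache.groups:
        l += -0.5 * float(np.sum(gc.eps**2 / gc.R + np.log(2.0 * np.pi * gc.R)))
    d = cache.eta.size
    l += -0.5 * float(cache.eta @ cache.omega_inv @ cache.eta)
    l += -0.5 * (cache.omega_logdet + d * LOG2PI)
    return l


def _grad_data_block(eps, R, deps, dR):
    """-1/2 sum_j [2 eps deps_a/R - eps^2 dR_a/R^2 + dR_a/R] for each
    direction a; shared by the eta gradient and the theta partials."""
    w1 = eps / R
    w2 = eps**2 / R**2
    w3 = 1.0 / R
    return -0.5 * (2.0 * w1 @ deps - w2 @ dR + w3 @ dR)


def grad_from_cache(cache: ObsCache) -> np.ndarray:
    g = np.zeros(cache.eta.size)
    for gc in cache.groups:
        g += _grad_data_block(gc.eps, gc.R, gc.deps_eta, gc.dR_eta)
    g -= cache.omega_inv @ cache.eta
    return g


def _second_data_block(eps, R, da_e, db_e, dab_e, da_R, db_R, dab_R):
    """Data part of the exact second derivative of l_i along directions
    (a, b): returns the (A, B) matrix

    -1/2 sum_j [ 2 db_e da_e/R - 2 eps db_R da_e/R^2 + 2 eps dab_e/R
                 - eps^2 dab_R/R^2 + 2 eps^2 da_R db_R/R^3
                 - 2 eps da_R db_e/R^2 - da_R db_R/R^2 + dab_R/R ].
    """
    iR = 1.0 / R
    e1 = eps * iR
    e2 = eps**2 * iR**2
    out = 2.0 * np.einsum("t,ta,tb->ab", iR, da_e, db_e)
    out -= 2.0 * np.einsum("t,ta,tb->ab", e1 * iR, da_e, db_R)
    out += 2.0 * np.einsum("t,tab->ab", e1, dab_e)
    out -= np.einsum("t,tab->ab", e2, dab_R)
    out += 2.0 * np.einsum("t,ta,tb->ab", e2 * iR, da_R, db_R)
    out -= 2.0 * np.einsum("t,ta,tb->ab", e1 * iR, da_R, db_e)
    out -= np.einsum("t,ta,tb->ab", iR**2, da_R, db_R)
    out += np.einsum("t,tab->ab", iR, dab_R)
    return -0.5 * out


def exact_hessian_from_cache(cache: ObsCache) -> np.ndarray:
    if cache.order < 2:
        raise DomainError("exact Hessian needs second-order eta sensitivities")
    d = cache.eta.size
    H = np.zeros((d, d))
    for gc in cache.groups:
        H += _second_data_block(
            gc.eps, gc.R, gc.deps_eta, gc.deps_eta, gc.d2eps_ee,
            gc.dR_eta, gc.dR_eta, gc.d2R_ee,
        )
    H -= cache.omega_inv
    return 0.5 * (H + H.T)


def approx_hessian_from_cache(cache: ObsCache, method: str = "FOCE") -> np.ndarray:
    """First-order Hessian H_i: all second-derivative terms of eps and R are
    dropped; FOCE additionally drops every dR/deta term (the residual
    covariance is treated as independent of the random effects), FOCEI keeps
    them (the 'interaction')."""
    if method not in ("FOCE", "FOCEI"):
        raise DomainError(f"unknown method {method!r}")
    d = cache.eta.size
    H = np.zeros((d, d))
    for gc in cache.groups:
        if method == "FOCEI":
            a = gc.deps_eta - (gc.eps / gc.R)[:, None] * gc.dR_eta
            c = gc.dR_eta / gc.R[:, None]
            H += -np.einsum("t,ta,tb->ab", 1.0 / gc.R, a, a) + 0.5 * np.einsum(
                "ta,tb->ab", c, c
            )
        else:
            a = gc.deps_eta
            H += -np.einsum("t,ta,tb->ab", 1.0 / gc.R, a, a)
    H -= cache.omega_inv
    return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# public single-shot wrappers


def _point(system, individual, theta, eta, solver, order=1):
    traj = integrate(system, individual, theta, eta, solver)
    cache = evaluate_observations(system, individual, traj, theta, eta, order)
    return cache


def individual_loglik(system, individual, theta, eta, solver=None) -> float:
    """l_i at (theta, eta); one integration of the inner-level system."""
    return loglik_from_cache(_point(system, individual, theta, eta, solver, order=1))


def grad_li_eta(system, individual, theta, eta, solver=None) -> np.ndarray:
    """Exact dl_i/deta via the eta-sensitivity equations."""
    return grad_from_cache(_point(system, individual, theta, eta, solver, order=1))


def hessians_li_eta(
    system, individual, theta, eta, mode="approx", method="FOCE", solver=None
) -> np.ndarray:
    """d x d Hessian of l_i in eta: ``mode='approx'`` gives the first-order
    H_i of the objective (per ``method``); ``mode='exact'`` keeps all
    second-order terms and requires an outer-level ``system``."""
    if mode == "approx":
        return approx_hessian_from_cache(
            _point(system, individual, theta, eta, solver, order=1), method
        )
    if mode == "exact":
        return exact_hessian_from_cache(
            _point(system, individual, theta, eta, solver, order=2)
        )
    raise DomainError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# inner optimization


@dataclass
class InnerSolution:
    """Converged empirical-Bayes estimate for one individual.

    ``deta_dtheta`` and ``exact_hessian`` are filled by the outer-gradient
    pass, which is where the second-order sensitivities are integrated.
    """

    eta_star: np.ndarray
    li_at_star: float
    grad_norm: float
    approx_hessian: np.ndarray
    iterations: int
    tol_digits: float
    method: str
    exact_hessian: np.ndarray | None = None
    deta_dtheta: np.ndarray | None = None
    cache: ObsCache | None = field(default=None, repr=False)


def solve_inner(
    system,
    individual,
    theta,
    eta0=None,
    tol_digits: float = 4.0,
    method: str = "FOCE",
    solver: SolverConfig | None = None,
    max_iter: int = 100,
) -> InnerSolution:
    """Maximize l_i over eta by BFGS with sensitivity-equation gradients.

    Convergence at "k digits": the per-component step, the objective change
    and the gradient are all below 10^-k on a max(1, |.|) relative scale.
    The initial inverse-Hessian estimate is (-H_i(eta0))^-1 when that matrix
    is positive definite.
    """
    spec = system.spec
    d = spec.d
    eta = np.zeros(d) if eta0 is None else np.asarray(eta0, dtype=float).copy()
    if not np.all(np.isfinite(eta)):
        raise DomainError("eta0 must be finite")
    tol = 10.0 ** (-float(tol_digits))

    def evaluate(e):
        with np.errstate(all="ignore"):
            cache = _point(system, individual, theta, e, solver, order=1)
            return loglik_from_cache(cache), grad_from_cache(cache), cache

    l, g, cache = evaluate(eta)
    nH = -approx_hessian_from_cache(cache, method)
    try:
        Binv = np.linalg.inv(nH)
        if not np.all(np.linalg.eigvalsh(nH) > 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        Binv = np.eye(d)

    def line_search(p):
        """Backtracking Armijo; returns accepted tuple or None.  The second
        flag reports whether any trial point evaluated at all."""
        gTp = g @ p
        alpha, any_eval = 1.0, False
        for _ in range(40):
            trial = eta + alpha * p
            try:
                l_t, g_t, cache_t = evaluate(trial)
            except (NumericDomainError, IntegrationError):
                alpha *= 0.5
                continue
            any_eval = True
            if np.isfinite(l_t) and l_t >= l + 1e-4 * alpha * gTp:
                return (trial, l_t, g_t, cache_t, alpha * p), any_eval
            alpha *= 0.5
        return None, any_eval

    def noise_floor(gv):
        # the smallest gradient worth chasing: limited by the requested
        # digits but floored by the ODE-solution noise; beyond this the
        # step-based convergence criterion takes over
        return 1e3 * max(tol, 1e-8) * max(1.0, float(np.max(np.abs(eta))))

    it = 0
    stall = 0
    for it in range(max_iter):
        if np.max(np.abs(g)) <= tol * max(1.0, float(np.max(np.abs(eta)))):
            break
        if stall >= 2:
            # consecutive zero-progress steps: the objective is flat to
            # machine/solver precision around the iterate
            break
        p = Binv @ g
        if g @ p <= 0.0:
            Binv = np.eye(d)
            p = g.copy()
        # cap the proposed step: eta is a standardized random effect, so
        # steps far beyond O(1) only destabilize the integrator
        cap = 2.0 * max(1.0, float(np.max(np.abs(eta))))
        pmax = float(np.max(np.abs(p)))
        if pmax > cap:
            p = p * (cap / pmax)
        accepted, any_eval = line_search(p)
        if accepted is None and not np.array_equal(p, g):
            # quasi-Newton direction failed: fall back to steepest ascent
            Binv = np.eye(d)
            p = g.copy()
            pmax = float(np.max(np.abs(p)))
            if pmax > cap:
                p = p * (cap / pmax)
            accepted, any_eval2 = line_search(p)
            any_eval = any_eval or any_eval2
        if accepted is None:
            if any_eval:
                # trial points evaluated but none improved l_i even at
                # vanishing steps along an ascent direction: the iterate is
                # the best point resolvable at this solver precision
                break
            raise InnerFailureError(
                f"inner line search failed for individual {individual.id} "
                f"(grad norm {np.max(np.abs(g)):.3e})",
                best_eta=eta, best_value=l,
            )
        s = accepted[4]
        y = accepted[2] - g
        step_ok = np.all(np.abs(s) <= tol * np.maximum(1.0, np.abs(eta)))
        obj_ok = abs(accepted[1] - l) <= tol * max(1.0, abs(l))
        if accepted[1] == l and float(np.max(np.abs(s))) <= 1e-12:
            stall += 1
        else:
            stall = 0
        eta, l, g, cache = accepted[:4]
        sy = s @ y
        if sy < -1e-12:  # curvature condition for a maximization
            ym = -y
            rho = 1.0 / (ym @ s)
            I = np.eye(d)
            V = I - rho * np.outer(s, ym)
            Binv = V @ Binv @ V.T + rho * np.outer(s, s)
        if step_ok and obj_ok and np.max(np.abs(g)) <= noise_floor(g):
            it += 1
            break
    else:
        if np.max(np.abs(g)) > max(noise_floor(g), 1e-3):
            raise InnerFailureError(
                f"inner problem did not converge in {max_iter} iterations "
                f"for individual {individual.id}",
                best_eta=eta, best_value=l,
            )

    H = approx_hessian_from_cache(cache, method)
    return InnerSolution(
        eta_star=eta,
        li_at_star=l,
        grad_norm=float(np.max(np.abs(g))),
        approx_hessian=H,
        iterations=it,
        tol_digits=float(tol_digits),
        method=method,
        cache=cache,
    )
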