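"""Exact gradient of log L_F with respect to the fixed effects theta.

Because eta*_i is an implicit function of theta, every theta-derivative of
an eta*-conditioned quantity decomposes into a direct part (at fixed eta)
plus an indirect part through deta*/dtheta.  The chain is:

1. the stationarity of l_i at eta* gives, by the implicit function theorem,

       deta*/dtheta = -(d2l_i/deta2)^-1 (d2l_i/deta dtheta),

   with the *exact* eta-Hessian (second-order sensitivities kept) and the
   mixed second derivatives assembled from first-order theta sensitivities
   and mixed second-order state sensitivities;

2. d l_i(eta*)/dtheta needs only the direct part (the indirect term is
   multiplied by dl_i/deta(eta*) = 0);

3. the total derivative of the approximate Hessian, dH_i(eta*)/dtheta,
   keeps both parts, so the starred totals of eps, R, deps/deta and
   dR/deta all carry a deta*/dtheta correction;

4. d log L_F/dtheta_m = sum_i [ dl_i(eta*)/dtheta_m
                                - 1/2 tr( H_i^-1 dH_i(eta*)/dtheta_m ) ].

Note the deliberate asymmetry: the exact Hessian is used inside the
implicit derivative (step 1), while the approximate H_i appears in the
objective and in the trace term (step 4) — exactly mirroring how the
objective itself is defined.  Trace terms are computed through linear
solves against H_i, never an explicit inverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .compile import integrate
from .data import PopulationData
from .errors import GradientFailure, PreconditionError
from .inner import (
    ObsCache,
    approx_hessian_from_cache,
    evaluate_observations,
    exact_hessian_from_cache,
    _grad_data_block,
    _second_data_block,
)

__all__ = [
    "OuterGradient",
    "deta_star_dtheta",
    "mixed_second_derivatives",
    "dli_dtheta_at_star",
    "dH_dtheta",
    "grad_logLF",
]


@dataclass
class OuterGradient:
    """d log L_F/dtheta plus the per-individual pieces used to build it."""

    grad: np.ndarray                 # (P,)
    per_individual: list = field(default_factory=list)


def deta_star_dtheta(exact_hessian: np.ndarray, mixed: np.ndarray) -> np.ndarray:
    """deta*/dtheta = -(d2l/deta2)^-1 (d2l/deta dtheta), both at eta*."""
    try:
        return -np.linalg.solve(exact_hessian, mixed)
    except np.linalg.LinAlgError as exc:
        raise GradientFailure(f"singular exact eta-Hessian: {exc}")


def mixed_from_cache(cache: ObsCache) -> np.ndarray:
    """d2 l_i / deta dtheta at fixed eta (direct part), shape (d, P).

    Data terms share their structure with the exact eta-Hessian (theta
    replacing the second eta direction); the prior term is the theta
    derivative of -Omega^-1 eta, i.e. +Omega^-1 (dOmega/dtheta_m) Omega^-1
    eta per column (d(Omega^-1)/dtheta = -Omega^-1 dOmega Omega^-1).
    """
    d = cache.eta.size
    P = cache.theta.size
    M = np.zeros((d, P))
    for gc in cache.groups:
        M += _second_data_block(
            gc.eps, gc.R, gc.deps_eta, gc.deps_th, gc.d2eps_et,
            gc.dR_eta, gc.dR_th, gc.d2R_et,
        )
    M += np.einsum(
        "kl,lam,ab,b->km", cache.omega_inv, cache.dOmega, cache.omega_inv, cache.eta
    )
    return M


def dli_from_cache(cache: ObsCache) -> np.ndarray:
    """Direct part of d l_i(eta*)/dtheta (the indirect term vanishes at the
    stationary eta*): data terms with deps/dtheta and dR/dtheta plus the
    Omega prior terms, shape (P,)."""
    P = cache.theta.size
    g = np.zeros(P)
    for gc in cache.groups:
        g += _grad_data_block(gc.eps, gc.R, gc.deps_th, gc.dR_th)
    oe = cache.omega_inv @ cache.eta
    g += 0.5 * np.einsum("k,kam,a->m", oe, cache.dOmega, oe)
    g -= 0.5 * np.einsum("kl,lkm->m", cache.omega_inv, cache.dOmega)
    return g


def dH_from_cache(cache: ObsCache, detadth: np.ndarray, method: str) -> np.ndarray:
    """Total derivative of the approximate Hessian after eta* substitution,
    shape (P, d, d); includes the indirect dependence through eta*(theta).

    FOCE zeroes every dR/deta-derived piece of H; the total derivatives of
    the remaining pieces still carry the full indirect dependence, so the
    result is the exact gradient of the FOCE objective.
    """
    d = cache.eta.size
    P = cache.theta.size
    dH = np.zeros((P, d, d))
    for gc in cache.groups:
        iR = 1.0 / gc.R
        # starred totals: direct theta part plus the deta*/dtheta correction
        Deps = gc.deps_th + gc.deps_eta @ detadth                 # (T, P)
        DR = gc.dR_th + gc.dR_eta @ detadth                       # (T, P)
        Ddeps = gc.d2eps_et + np.einsum("tkl,lm->tkm", gc.d2eps_ee, detadth)
        DdR = gc.d2R_et + np.einsum("tkl,lm->tkm", gc.d2R_ee, detadth)
        if method == "FOCEI":
            a = gc.deps_eta - (gc.eps * iR)[:, None] * gc.dR_eta  # (T, d)
            da = (
                Ddeps
                - np.einsum("tm,tk,t->tkm", Deps, gc.dR_eta, iR)
                + np.einsum("t,tm,tk->tkm", gc.eps * iR**2, DR, gc.dR_eta)
                - np.einsum("t,tkm->tkm", gc.eps * iR, DdR)
            )
            c = gc.dR_eta * iR[:, None]
            dc = -np.einsum("t,tm,tk->tkm", iR**2, DR, gc.dR_eta) + np.einsum(
                "t,tkm->tkm", iR, DdR
            )
        else:
            a = gc.deps_eta
            da = Ddeps
            c = dc = None
        B = 2.0 * iR
        dB = -2.0 * iR[:, None] ** 2 * DR                         # (T, P)
        blk = np.einsum("tlm,t,tk->mkl", da, B, a)
        blk += np.einsum("tl,tm,tk->mkl", a, dB, a)
        blk += np.einsum("tl,t,tkm->mkl", a, B, da)
        if c is not None:
            blk -= np.einsum("tlm,tk->mkl", dc, c) + np.einsum(
                "tl,tkm->mkl", c, dc
            )
        dH += -0.5 * blk
    # -d(Omega^-1)/dtheta_m = Omega^-1 dOmega/dtheta_m Omega^-1
    dH += np.einsum(
        "kl,lam,ab->mkb", cache.omega_inv, cache.dOmega, cache.omega_inv
    )
    dH = 0.5 * (dH + np.swapaxes(dH, 1, 2))
    return dH


def _attach_domega(system, cache: ObsCache):
    if not hasattr(cache, "dOmega"):
        cache.dOmega = system.numeric.omega_dtheta(cache.theta)


def _outer_cache(system, individual, theta, eta_star, solver):
    traj = integrate(system, individual, theta, eta_star, solver)
    cache = evaluate_observations(system, individual, traj, theta, eta_star, order=2)
    _attach_domega(system, cache)
    return cache


# ---------------------------------------------------------------------------
# public single-shot wrappers (one outer-level integration each)


def mixed_second_derivatives(system, individual, theta, eta_star, solver=None):
    """d2 l_i/deta dtheta at fixed eta = eta*, shape (d, P)."""
    return mixed_from_cache(_outer_cache(system, individual, theta, eta_star, solver))


def dli_dtheta_at_star(system, individual, theta, inner, solver=None):
    """d l_i(eta*)/dtheta, shape (P,); requires a stationary eta*."""
    _check_stationary(inner, individual)
    return dli_from_cache(
        _outer_cache(system, individual, theta, inner.eta_star, solver)
    )


def dH_dtheta(system, individual, theta, inner, method="FOCE", solver=None):
    """Stack of P symmetric d x d matrices dH_i(eta*)/dtheta_m."""
    _check_stationary(inner, individual)
    cache = _outer_cache(system, individual, theta, inner.eta_star, solver)
    He = exact_hessian_from_cache(cache)
    M = mixed_from_cache(cache)
    return dH_from_cache(cache, deta_star_dtheta(He, M), method)


def _check_stationary(inner, individual):
    # sanity guard against a grossly stale eta*; the threshold is floored
    # because at very tight digit settings the achievable gradient norm is
    # limited by ODE-solver noise rather than the optimizer
    tol = max(1e3 * 10.0 ** (-inner.tol_digits), 1e-3)
    scale = max(1.0, float(np.max(np.abs(inner.eta_star))))
    if inner.grad_norm > tol * scale:
        raise PreconditionError(
            f"eta* for individual {individual.id} is not stationary "
            f"(grad norm {inner.grad_norm:.3e})"
        )


def grad_logLF(
    system,
    data: PopulationData,
    theta,
    method: str = "FOCE",
    inner_solutions=None,
    solver=None,
) -> OuterGradient:
    """Gradient of log L_F at theta given converged inner solutions.

    One outer-level integration per individual; fills ``exact_hessian`` and
    ``deta_dtheta`` on each :class:`InnerSolution` as a side effect.
    """
    theta = np.asarray(theta, dtype=float)
    P = system.spec.P
    grad = np.zeros(P)
    pieces = []
    for ind, inner in zip(data, inner_solutions):
        _check_stationary(inner, ind)
        try:
            cache = _outer_cache(system, ind, theta, inner.eta_star, solver)
            He = exact_hessian_from_cache(cache)
            M = mixed_from_cache(cache)
            dd = deta_star_dtheta(He, M)
            dli = dli_from_cache(cache)
            Ha = approx_hessian_from_cache(cache, method)
            dH = dH_from_cache(cache, dd, method)
            lu = lu_factor(Ha)
            tr = np.array(
                [np.trace(lu_solve(lu, dH[m])) for m in range(P)]
            )
        except Exception as exc:
            raise GradientFailure(
                f"outer gradient failed for individual {ind.id}: {exc}"
            ) from exc
        inner.exact_hessian = He
        inner.deta_dtheta = dd
        contrib = dli - 0.5 * tr
        grad += contrib
        pieces.append(
            {"id": ind.id, "dli_dtheta": dli, "deta_dtheta": dd, "contribution": contrib}
        )
    return OuterGradient(grad=grad, per_individual=pieces)
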