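"""The FOCE/FOCEI approximation of the population log-likelihood.

The Laplacian approximation expanded at the posterior mode eta* of each
individual joint log-likelihood gives

    log L_F(theta) = sum_i [ l_i(eta*_i) - 1/2 log det( -H_i(eta*_i) / 2pi ) ],

with H_i the first-order approximate Hessian (FOCE drops all dR/deta terms,
FOCEI keeps them).  Every evaluation nests one inner optimization per
individual.  A failed inner solve or a non-positive-definite -H_i raises
:class:`ObjectiveFailure` so outer line searches can backtrack instead of
being fed a penalty value that would distort curvature estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import LinAlgError, cho_factor

from .data import PopulationData
from .errors import (
    InnerFailureError,
    IntegrationError,
    NumericDomainError,
    ObjectiveFailure,
)
from .inner import InnerSolution, solve_inner

__all__ = ["ObjectiveValue", "population_loglik"]

LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class ObjectiveValue:
    """log L_F and its 2N per-individual contributions."""

    logLF: float
    li_terms: np.ndarray        # l_i(eta*_i)
    logdet_terms: np.ndarray    # -1/2 log det(-H_i/2pi)
    method: str


def laplace_logdet_term(H: np.ndarray) -> float:
    """-1/2 log det(-H/2pi) via a symmetric factorization of -H; raises
    :class:`ObjectiveFailure` on a non-PD -H."""
    d = H.shape[0]
    try:
        c, _ = cho_factor(-H, lower=True)
    except (LinAlgError, ValueError):
        raise ObjectiveFailure("-H_i is not positive definite")
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    return -0.5 * (logdet - d * LOG2PI)


def population_loglik(
    system,
    data: PopulationData,
    theta,
    method: str = "FOCE",
    eta0=None,
    tol_digits: float = 4.0,
    solver=None,
    max_inner: int = 100,
):
    """Evaluate log L_F(theta) with one inner solve per individual.

    ``eta0`` optionally provides per-individual warm starts (list of
    d-vectors, or None for eta=0).  Returns ``(ObjectiveValue, [InnerSolution])``.
    """
    theta = np.asarray(theta, dtype=float)
    li_terms = np.empty(data.N)
    ld_terms = np.empty(data.N)
    inners: list[InnerSolution] = []
    for i, ind in enumerate(data):
        start = None if eta0 is None else eta0[i]
        try:
            sol = solve_inner(
                system, ind, theta, eta0=start, tol_digits=tol_digits,
                method=method, solver=solver, max_iter=max_inner,
            )
        except (InnerFailureError, IntegrationError, NumericDomainError) as exc:
            raise ObjectiveFailure(
                f"objective failed at individual {ind.id}: {exc}"
            ) from exc
        li_terms[i] = sol.li_at_star
        ld_terms[i] = laplace_logdet_term(sol.approx_hessian)
        inners.append(sol)
    value = ObjectiveValue(
        logLF=float(np.sum(li_terms) + np.sum(ld_terms)),
        li_terms=li_terms,
        logdet_terms=ld_terms,
        method=method,
    )
    return value, inners
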