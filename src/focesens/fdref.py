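"""Finite-difference reference gradients and the precision/accuracy sweep.

Finite differences of log L_F are the baseline the sensitivity-equation
gradients are validated against (and compared with).  With relative step
10^-h in direction m:

    forward:  [F(theta_m (1+10^-h)) - F(theta_m)] / (theta_m 10^-h)
    central:  [F(theta_m (1+10^-h)) - F(theta_m (1-10^-h))] / (2 theta_m 10^-h)

The sweep evaluates both schemes over a grid of h with the inner problems
solved to a fixed digit precision and *randomized* inner starting values
redrawn for every h (so successive differences do not share one realization
of the numerical noise), and reports the sensitivity-equation gradient as
the reference together with its relative standard error over repeated
randomized-start evaluations.

Also here: the evaluation-count cost model for mixed analytical/finite-
difference outer gradients (the "S-F/S" scheme, where the Omega-parameter
block of the gradient is obtained analytically and only the remaining
directions are finite-differenced).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, ObjectiveFailure

__all__ = [
    "fd_gradient",
    "sfs_cost_percent",
    "precision_sweep",
    "FDSweepResult",
    "scheme_evaluation_counts",
]


def fd_gradient(objective, theta, m: int, h: float, scheme: str = "central",
                f0: float | None = None) -> float:
    """One finite-difference component of the gradient of ``objective``.

    ``h`` is the step *exponent*: the relative step is 10^-h.  ``f0``
    optionally supplies the already-known value at theta for the forward
    scheme.  Requires theta_m != 0 (the step is relative).
    """
    theta = np.asarray(theta, dtype=float)
    if theta[m] == 0.0:
        raise DomainError(f"relative FD step undefined at theta[{m}] = 0")
    step = 10.0 ** (-float(h))
    tp = theta.copy()
    tp[m] = theta[m] * (1.0 + step)
    try:
        fp = objective(tp)
        if scheme == "forward":
            fm = objective(theta) if f0 is None else f0
            return (fp - fm) / (theta[m] * step)
        if scheme == "central":
            tm_ = theta.copy()
            tm_[m] = theta[m] * (1.0 - step)
            fm = objective(tm_)
            return (fp - fm) / (2.0 * theta[m] * step)
    except ObjectiveFailure as exc:
        raise ObjectiveFailure(f"FD evaluation failed in direction {m}: {exc}")
    raise DomainError(f"unknown scheme {scheme!r}")


def fd_gradient_full(objective, theta, h: float, scheme: str = "central"):
    """All P components; shares the base evaluation for the forward scheme."""
    theta = np.asarray(theta, dtype=float)
    f0 = objective(theta) if scheme == "forward" else None
    return np.array(
        [fd_gradient(objective, theta, m, h, scheme, f0=f0) for m in range(theta.size)]
    )


def sfs_cost_percent(P_theta: int, P_omega: int, scheme: str = "forward") -> float:
    """Relative cost (in %) of a mixed analytical/FD outer gradient.

    When the P_omega covariance-parameter directions of the gradient are
    obtained analytically (they need only second-order eta sensitivities)
    and the remaining directions by finite differences, the reference cost
    of a full FD gradient drops to

        forward:  100 (1 + P_theta - P_omega) / (1 + P_theta)
        central:  100 (1 + 2 P_theta - 2 P_omega) / (1 + 2 P_theta)

    under the assumption that every perturbed log L_F evaluation costs the
    same and the analytic Omega block is free.
    """
    if not (0 <= P_omega <= P_theta):
        raise DomainError(f"need 0 <= P_omega <= P_theta, got {P_omega}, {P_theta}")
    if scheme == "forward":
        return 100.0 * (1 + P_theta - P_omega) / (1 + P_theta)
    if scheme == "central":
        return 100.0 * (1 + 2 * P_theta - 2 * P_omega) / (1 + 2 * P_theta)
    raise DomainError(f"unknown scheme {scheme!r}")


def scheme_evaluation_counts(P_theta: int, q: int, n: int, p: int | None = None):
    """Objective-evaluation and ODE counts per outer-gradient computation
    for the gradient schemes compared in the timing ladder.

    Keys are scheme tags: F and S denote finite-difference and sensitivity
    gradients at (inner, outer) level respectively.  Counts are per outer
    iterate and per individual; "objective evaluations" include the base
    point.  For the F inner level the inner ODE count is the n-state system
    solved (1+q) times per inner gradient, numerically equivalent to the
    n(1+q) combined system.
    """
    if p is None:
        p = P_theta
    inner_odes_S = n * (1 + q)
    out = {
        "F-F": {
            "outer_objective_evals_forward": 1 + P_theta,
            "outer_objective_evals_central": 1 + 2 * P_theta,
            "inner_odes_per_inner_gradient": n * (1 + q),
            "inner_gradient_style": "finite differences (1+q solves of n ODEs)",
        },
        "S-F": {
            "outer_objective_evals_forward": 1 + P_theta,
            "outer_objective_evals_central": 1 + 2 * P_theta,
            "inner_odes_per_inner_gradient": inner_odes_S,
            "inner_gradient_style": "sensitivities (one combined solve)",
        },
        "S-S": {
            "outer_objective_evals_forward": 1,
            "outer_objective_evals_central": 1,
            "outer_odes_per_gradient": n * (1 + q) * (2 + 2 * p + q) // 2,
            "inner_odes_per_inner_gradient": inner_odes_S,
            "inner_gradient_style": "sensitivities (one combined solve)",
        },
    }
    out["S-S-eta"] = dict(out["S-S"], warm_start="Taylor (mode B)")
    return out


# ---------------------------------------------------------------------------
# the precision/accuracy sweep


@dataclass
class FDSweepResult:
    """Tidy sweep output.

    ``rows`` is a list of dicts (direction, scheme, h, value, reference);
    ``reference`` the sensitivity gradient at theta; ``rel_std_error`` its
    per-direction relative standard error over randomized-start repeats.
    """

    rows: list
    reference: np.ndarray
    rel_std_error: np.ndarray
    theta: np.ndarray
    seed: int

    def frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows)


def precision_sweep(
    model,
    data,
    theta,
    method: str = "FOCE",
    h_grid=None,
    n_repeats: int = 50,
    seed: int = 0,
    tol_digits: float = 4.0,
    solver=None,
):
    """Precision/accuracy sweep of FD gradients of log L_F against the
    sensitivity-equation reference.

    For every h and scheme the inner problems are solved to ``tol_digits``
    digits from starting values drawn fresh as eta0 ~ N(0, Omega(theta)).
    The reference gradient and its relative standard error are estimated
    from ``n_repeats`` randomized-start sensitivity-gradient evaluations.
    """
    from .gradient import grad_logLF
    from .objective import population_loglik

    theta = np.asarray(theta, dtype=float)
    h_grid = np.arange(0.5, 7.01, 0.5) if h_grid is None else np.asarray(h_grid, float)
    if np.any(h_grid <= 0) or np.any(np.diff(h_grid) <= 0):
        raise DomainError("h grid must be positive and strictly increasing")
    rng = np.random.default_rng(seed)
    omega = model.numeric.omega(theta)
    d = model.spec.d

    def random_starts():
        return [rng.multivariate_normal(np.zeros(d), omega) for _ in range(data.N)]

    def objective(th, eta0):
        val, _ = population_loglik(
            model.inner, data, th, method=method, eta0=eta0,
            tol_digits=tol_digits, solver=solver,
        )
        return val.logLF

    def sens_grad(eta0):
        _, inners = population_loglik(
            model.inner, data, theta, method=method, eta0=eta0,
            tol_digits=tol_digits, solver=solver,
        )
        og = grad_logLF(model.outer, data, theta, method=method,
                        inner_solutions=inners, solver=solver)
        return og.grad

    reps = np.stack([sens_grad(random_starts()) for _ in range(max(n_repeats, 2))])
    reference = reps.mean(axis=0)
    sd = reps.std(axis=0, ddof=1) / np.sqrt(reps.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        rse = np.abs(sd / reference)

    rows = []
    P = theta.size
    for h in h_grid:
        for scheme in ("forward", "central"):
            eta0 = random_starts()  # fresh randomization per h (and scheme)
            f0 = objective(theta, eta0) if scheme == "forward" else None
            for m in range(P):
                val = fd_gradient(
                    lambda th: objective(th, eta0), theta, m, h, scheme, f0=f0
                )
                rows.append(
                    {
                        "direction": m,
                        "scheme": scheme,
                        "h": float(h),
                        "value": float(val),
                        "reference": float(reference[m]),
                    }
                )
    return FDSweepResult(
        rows=rows, reference=reference, rel_std_error=rse, theta=theta, seed=seed
    )


def plot_sweep(result: FDSweepResult, path):
    """Optional diagnostic figure (one panel per gradient direction)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = result.frame()
    P = int(df["direction"].max()) + 1
    fig, axes = plt.subplots(P, 1, figsize=(6, 2.2 * P), sharex=True)
    axes = np.atleast_1d(axes)
    for m, ax in enumerate(axes):
        sub = df[df["direction"] == m]
        for scheme, color in (("forward", "tab:blue"), ("central", "tab:red")):
            ss = sub[sub["scheme"] == scheme]
            ax.plot(ss["h"], ss["value"], "o", ms=3, color=color, label=scheme)
        ax.axhline(result.reference[m], color="k", lw=1, label="sensitivity")
        ax.axhline(0.0, color="gray", ls="--", lw=0.8)
        ax.set_ylabel(f"dlogLF/dtheta[{m}]")
        if m == 0:
            ax.legend(fontsize=7)
    axes[-1].set_xlabel("h (relative step 10^-h)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
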