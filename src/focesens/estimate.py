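"""Outer optimization of log L_F over theta: nested BFGS with warm starts.

Each outer iterate evaluates log L_F (N inner BFGS solves) and its exact
sensitivity-equation gradient (N outer-level integrations).  Between outer
steps the inner problems are warm-started: mode A reuses the previous
optimum eta*_s, mode B adds the first-order Taylor correction

    eta0_{s+1} = eta*_s + (deta*_s/dtheta)(theta_{s+1} - theta_s),

exploiting that deta*/dtheta is already available from the gradient
computation.  The very first evaluation starts every eta at zero.

Fixed effects are optimized on a normalized scale (theta divided by
max(|theta0|, 1) per component) because PK parameters span orders of
magnitude.  Objective failures along a line search (non-PD Omega or -H_i,
inner non-convergence, integrator blow-up) trigger step shrinkage rather
than penalty values.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np

from .compile import CompiledModel, SolverConfig
from .data import PopulationData
from .errors import DomainError, FitFailure, GradientFailure, ObjectiveFailure
from .fdref import fd_gradient
from .gradient import grad_logLF
from .objective import population_loglik

__all__ = ["FitConfig", "WarmStartState", "FitResult", "warm_start_eta", "fit",
           "standard_errors"]


@dataclass
class FitConfig:
    method: str = "FOCE"
    inner_digits: float = 4.0
    outer_digits: float = 3.0
    warm_start: str = "B"              # "A" | "B" | "zero"
    gradient: str = "sensitivity"      # "sensitivity" | "fd_forward" | "fd_central"
    fd_rel_step: float = 1e-2
    solver: SolverConfig = field(default_factory=SolverConfig)
    max_outer: int = 200
    max_inner: int = 100
    seed: int | None = None

    def __post_init__(self):
        if self.method not in ("FOCE", "FOCEI"):
            raise DomainError(f"unknown method {self.method!r}")
        if self.warm_start not in ("A", "B", "zero"):
            raise DomainError(f"unknown warm start mode {self.warm_start!r}")
        if self.gradient not in ("sensitivity", "fd_forward", "fd_central"):
            raise DomainError(f"unknown gradient scheme {self.gradient!r}")


@dataclass
class WarmStartState:
    """Per-individual eta*_s and deta*_s/dtheta from outer step s."""

    theta: np.ndarray
    eta_star: list                      # N vectors of length d
    deta_dtheta: list | None = None     # N matrices d x P (None until a
                                        # sensitivity gradient was computed)


def warm_start_eta(state: WarmStartState, theta_next, theta_curr=None, mode="B"):
    """Starting values eta0 for every individual at theta_next.

    mode A: previous optimum.  mode B: first-order Taylor prediction using
    deta*/dtheta (falls back to A when no implicit derivative is stored).
    """
    theta_next = np.asarray(theta_next, dtype=float)
    theta_curr = state.theta if theta_curr is None else np.asarray(theta_curr, float)
    if theta_next.shape != theta_curr.shape:
        raise DomainError("theta dimension mismatch in warm start")
    if mode == "zero":
        return [np.zeros_like(e) for e in state.eta_star]
    if mode == "A" or state.deta_dtheta is None:
        return [e.copy() for e in state.eta_star]
    if mode != "B":
        raise DomainError(f"unknown warm start mode {mode!r}")
    step = theta_next - theta_curr
    out = []
    for e, dd in zip(state.eta_star, state.deta_dtheta):
        if dd is None:
            out.append(e.copy())
        else:
            if dd.shape != (e.size, step.size):
                raise DomainError("deta*/dtheta dimension mismatch in warm start")
            out.append(e + dd @ step)
    return out


@dataclass
class FitResult:
    theta_hat: np.ndarray
    logLF_hat: float
    trace: list                     # dicts: iter, theta, logLF, grad_norm, ...
    inner_solutions: list
    method: str
    config: FitConfig
    converged: bool
    n_outer_iterations: int
    total_inner_iterations: int
    theta_names: tuple = ()
    seed: int | None = None

    def to_dict(self):
        return {
            "theta_hat": dict(zip(self.theta_names, map(float, self.theta_hat)))
            if self.theta_names
            else [float(v) for v in self.theta_hat],
            "logLF": self.logLF_hat,
            "method": self.method,
            "converged": self.converged,
            "n_outer_iterations": self.n_outer_iterations,
            "total_inner_iterations": self.total_inner_iterations,
            "seed": self.seed,
            "config": {
                "inner_digits": self.config.inner_digits,
                "outer_digits": self.config.outer_digits,
                "warm_start": self.config.warm_start,
                "gradient": self.config.gradient,
                "solver_rtol": self.config.solver.rtol,
                "solver_atol": self.config.solver.atol,
            },
        }

    def to_json(self, path=None, **kw):
        text = json.dumps(self.to_dict(), indent=2, **kw)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def trace_frame(self):
        import pandas as pd

        rows = []
        for rec in self.trace:
            row = {"iteration": rec["iter"], "logLF": rec["logLF"],
                   "grad_norm": rec["grad_norm"],
                   "inner_iterations": rec["inner_iterations"]}
            for nm, v in zip(
                self.theta_names or range(len(rec["theta"])), rec["theta"]
            ):
                row[f"theta_{nm}"] = v
            rows.append(row)
        return pd.DataFrame(rows)


def _objective(model, data, theta, cfg, eta0):
    return population_loglik(
        model.inner, data, theta, method=cfg.method, eta0=eta0,
        tol_digits=cfg.inner_digits, solver=cfg.solver, max_inner=cfg.max_inner,
    )


def _gradient(model, data, theta, cfg, inners, obj_value):
    """Outer gradient per the configured scheme.  The FD schemes re-solve
    the inner problems at each perturbed theta, warm-started at the current
    eta* (the protocol used when timing finite differences)."""
    if cfg.gradient == "sensitivity":
        og = grad_logLF(
            model.outer, data, theta, method=cfg.method,
            inner_solutions=inners, solver=cfg.solver,
        )
        return og.grad, [s.deta_dtheta for s in inners]
    scheme = "forward" if cfg.gradient == "fd_forward" else "central"
    h = -float(np.log10(cfg.fd_rel_step))
    eta_star = [s.eta_star for s in inners]

    def F(th):
        val, _ = _objective(model, data, th, cfg, eta_star)
        return val.logLF

    g = np.array(
        [
            fd_gradient(F, theta, m, h, scheme, f0=obj_value.logLF)
            for m in range(theta.size)
        ]
    )
    return g, None


def fit(
    model: CompiledModel,
    data: PopulationData,
    theta0,
    cfg: FitConfig | None = None,
    theta_names=None,
) -> FitResult:
    """Maximize log L_F over theta by BFGS (Algorithm: nested FOCE/FOCEI
    with sensitivity-equation gradients and warm-started inner problems)."""
    cfg = cfg or FitConfig()
    theta = np.asarray(theta0, dtype=float).copy()
    P = theta.size
    if theta_names is None:
        theta_names = tuple(s.name for s in model.spec.theta)
    tol = 10.0 ** (-float(cfg.outer_digits))
    # normalize each component by its starting magnitude so BFGS sees O(1)
    # coordinates; a unit scale is only used where theta0 is exactly zero
    # (a floor at 1 would make unit steps 10-100x the size of variance-scale
    # parameters and destabilize the line search)
    scale = np.where(np.abs(theta) > 0.0, np.abs(theta), 1.0)

    N = data.N
    d = model.spec.d
    try:
        value, inners = _objective(
            model, data, theta, cfg, [np.zeros(d)] * N
        )
    except ObjectiveFailure as exc:
        raise FitFailure(f"objective failed at theta0: {exc}")
    g, dd = _gradient(model, data, theta, cfg, inners, value)
    state = WarmStartState(theta=theta.copy(),
                           eta_star=[s.eta_star for s in inners],
                           deta_dtheta=dd)
    total_inner = sum(s.iterations for s in inners)
    trace = [
        {"iter": 0, "theta": theta.copy(), "logLF": value.logLF,
         "grad_norm": float(np.max(np.abs(g))),
         "inner_iterations": sum(s.iterations for s in inners)}
    ]

    u = theta / scale
    gu = g * scale
    Binv = np.eye(P)
    converged = False
    F_cur = value.logLF
    def line_search(p):
        gTp = gu @ p
        alpha, any_eval = 1.0, False
        for _ in range(40):
            u_try = u + alpha * p
            theta_try = u_try * scale
            mode = cfg.warm_start if cfg.gradient == "sensitivity" else (
                "A" if cfg.warm_start == "B" else cfg.warm_start
            )
            eta0 = warm_start_eta(state, theta_try, theta, mode=mode)
            try:
                val_t, inners_t = _objective(model, data, theta_try, cfg, eta0)
            except ObjectiveFailure:
                alpha *= 0.5
                continue
            any_eval = True
            if val_t.logLF >= F_cur + 1e-4 * alpha * gTp:
                return (u_try, theta_try, val_t, inners_t, alpha), True
            alpha *= 0.5
        return None, any_eval

    def capped(p):
        # limit any single relative parameter change to 50% per trial step
        pmax = float(np.max(np.abs(p)))
        return p * (0.5 / pmax) if pmax > 0.5 else p

    for s_iter in range(1, cfg.max_outer + 1):
        p = Binv @ gu
        if gu @ p <= 0.0:
            Binv = np.eye(P)
            p = gu.copy()
        p = capped(p)
        accepted, any_eval = line_search(p)
        if accepted is None:
            # quasi-Newton direction exhausted: retry along the gradient
            Binv = np.eye(P)
            p = capped(gu.copy())
            accepted, ev2 = line_search(p)
            any_eval = any_eval or ev2
        if accepted is None:
            if any_eval:
                # trial points evaluated but none improved the objective
                # even at vanishing step sizes: the iterate sits at a
                # numerical maximum
                converged = True
                break
            raise FitFailure(
                "outer line search failed to find an ascent step "
                "(every trial point was infeasible)", trace=trace,
            )
        u_new, theta_new, val_new, inners_new, alpha = accepted
        try:
            g_new, dd_new = _gradient(
                model, data, theta_new, cfg, inners_new, val_new
            )
        except GradientFailure as exc:
            raise FitFailure(f"gradient failed at accepted step: {exc}", trace=trace)
        gu_new = g_new * scale

        step = u_new - u
        y = gu_new - gu
        sy = step @ y
        if sy < -1e-12:
            ym = -y
            rho = 1.0 / (ym @ step)
            I = np.eye(P)
            V = I - rho * np.outer(step, ym)
            Binv = V @ Binv @ V.T + rho * np.outer(step, step)

        step_ok = np.all(np.abs(step) <= tol * np.maximum(1.0, np.abs(u)))
        obj_ok = abs(val_new.logLF - F_cur) <= tol * max(1.0, abs(F_cur))

        u, theta, gu = u_new, theta_new, gu_new
        F_cur = val_new.logLF
        value, inners = val_new, inners_new
        state = WarmStartState(theta=theta.copy(),
                               eta_star=[s.eta_star for s in inners],
                               deta_dtheta=dd_new)
        it_inner = sum(s.iterations for s in inners)
        total_inner += it_inner
        trace.append(
            {"iter": s_iter, "theta": theta.copy(), "logLF": F_cur,
             "grad_norm": float(np.max(np.abs(g_new))),
             "inner_iterations": it_inner}
        )
        if step_ok and obj_ok:
            converged = True
            break

    return FitResult(
        theta_hat=theta,
        logLF_hat=F_cur,
        trace=trace,
        inner_solutions=inners,
        method=cfg.method,
        config=cfg,
        converged=converged,
        n_outer_iterations=len(trace) - 1,
        total_inner_iterations=total_inner,
        theta_names=theta_names,
        seed=cfg.seed,
    )


def standard_errors(model, data, theta_hat, cfg=None, rel_step=1e-3):
    """Asymptotic standard errors from a central-FD Hessian of log L_F built
    on the analytic gradient.  Returns (se, hessian).

    When the negative Hessian is not positive definite — which happens when
    a variance component sits on the Omega boundary, where a Wald standard
    error does not exist — the offending directions are identified from the
    scale-normalized negative-curvature eigenvectors, their SEs reported as
    inf, and the remaining PD principal submatrix inverted.
    """
    cfg = cfg or FitConfig()
    theta_hat = np.asarray(theta_hat, dtype=float)
    P = theta_hat.size
    H = np.zeros((P, P))

    def gradient_at(th):
        val, inners = _objective(model, data, th, cfg, None)
        og = grad_logLF(model.outer, data, th, method=cfg.method,
                        inner_solutions=inners, solver=cfg.solver)
        return og.grad

    for m in range(P):
        hstep = rel_step * max(abs(theta_hat[m]), 1e-3)
        tp, tm_ = theta_hat.copy(), theta_hat.copy()
        tp[m] += hstep
        tm_[m] -= hstep
        H[:, m] = (gradient_at(tp) - gradient_at(tm_)) / (2.0 * hstep)
    H = 0.5 * (H + H.T)

    s = np.maximum(np.abs(theta_hat), 1e-8)
    scaled = -H * np.outer(s, s)
    keep = list(range(P))
    while keep:
        sub = scaled[np.ix_(keep, keep)]
        w, V = np.linalg.eigh(sub)
        if w[0] > 0:
            break
        keep.pop(int(np.argmax(np.abs(V[:, 0]))))
    se = np.full(P, np.inf)
    if keep:
        cov = np.linalg.inv((-H)[np.ix_(keep, keep)])
        d = np.diag(cov)
        if np.all(d > 0):
            se[keep] = np.sqrt(d)
    return se, H
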