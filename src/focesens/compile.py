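"""Generation and integration of augmented sensitivity ODE systems.

Differentiating the model ODE system dx/dt = f(x, t, Z, theta, eta) with
respect to the random effects eta and the fixed effects theta yields the
forward sensitivity equations.  Writing S_k = dx/deta_k, T_m = dx/dtheta_m,
U_km = d2x/deta_k dtheta_m and V_kl = d2x/deta_k deta_l:

    S_k' = df/deta_k + (df/dx) S_k
    T_m' = df/dtheta_m + (df/dx) T_m
    U_km' = d2f/deta_k dtheta_m + (d2f/deta_k dx) T_m
            + (d2f/dx dtheta_m + (d2f/dx2) T_m) S_k + (df/dx) U_km
    V_kl' = d2f/deta_k deta_l + (d2f/deta_k dx) S_l
            + (d2f/dx deta_l + (d2f/dx2) S_l) S_k + (df/dx) V_kl

with initial conditions given by the matching partials of x0.  The *inner*
level (needed for the individual log-likelihood l_i and dl_i/deta) augments
the n states with the q non-trivial eta sensitivities: n(1+q) equations.
The *outer* level (needed for d log L_F / dtheta) additionally carries the p
non-trivial theta sensitivities, the q*p mixed blocks and the q(q+1)/2
unordered second-order eta blocks: n(1+q)(1+p+q/2) equations in total.

A sensitivity is *trivially zero* when the parameter appears in neither f
nor x0 (detected symbolically, e.g. pure covariance parameters); such blocks
are dropped from the integrated system and reconstituted as zeros on output.
The whole augmented system is built symbolically, compiled to a single
numpy-callable right-hand side (with common-subexpression elimination) and
always solved simultaneously — never by repeated solves of the base system.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import sympy as sp
from scipy.integrate import odeint
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .errors import DomainError, IntegrationError, NumericDomainError
from .model import TIME, DerivativeBundle, ModelSpec, TensorFamily

__all__ = [
    "SolverConfig",
    "CompiledSensitivitySystem",
    "CompiledModel",
    "NumericBundle",
    "Trajectory",
    "count_equations",
    "compile_system",
    "compile_model",
    "integrate",
]


@dataclass(frozen=True)
class SolverConfig:
    """LSODA tolerances.  ``ESTIMATION`` is the default for parameter fits;
    ``VALIDATION`` for gradient cross-checks against finite differences."""

    rtol: float = 1e-6
    atol: float = 1e-8
    mxstep: int = 100000


ESTIMATION = SolverConfig(rtol=1e-6, atol=1e-8)
VALIDATION = SolverConfig(rtol=1e-8, atol=1e-10)


def count_equations(n: int, p: int, q: int, level: str) -> int:
    """Number of ODEs solved simultaneously per individual.

    inner:  n(1+q)           — states plus first-order eta sensitivities
    outer:  n(1+q)(1+p+q/2)  — plus theta, mixed and second-order eta blocks

    The outer count is always an integer because (1+q)(2+2p+q) is even.
    """
    if n < 1 or p < 0 or q < 0:
        raise DomainError(f"invalid counts n={n}, p={p}, q={q}")
    if level == "inner":
        return n * (1 + q)
    if level == "outer":
        return n * (1 + q) * (2 + 2 * p + q) // 2
    raise DomainError(f"unknown level {level!r}")


# ---------------------------------------------------------------------------
# numeric evaluation of the symbolic derivative bundle


class NumericBundle:
    """Lazily lambdified views of a :class:`DerivativeBundle`.

    Every family is compiled once to a numpy callable with flat argument
    list ``(t, *states, *theta, *eta, *covariates)`` and reshaped on return.
    """

    def __init__(self, bundle: DerivativeBundle):
        self.bundle = bundle
        self.spec = bundle.spec
        s = self.spec
        self._args = (TIME, *s.states, *s.theta, *s.eta, *s.covariates)
        self._fns = {}

    def _family(self, path):
        kind = path[0]
        if kind in ("h", "r"):
            fam = getattr(self.bundle, kind)[path[1]][path[2]]
        else:
            fam = getattr(self.bundle, kind)[path[1]]
        return fam

    def _fn(self, path):
        fn = self._fns.get(path)
        if fn is None:
            fam = self._family(path)
            lam = sp.lambdify(self._args, list(fam.exprs), modules="numpy", cse=True)
            shape = fam.shape
            self._fns[path] = fn = (lam, shape)
        return fn

    def eval(self, path, t, x, theta, eta, z=()):
        lam, shape = self._fn(path)
        out = np.asarray(lam(t, *x, *theta, *eta, *z), dtype=float)
        return out.reshape(shape)

    # Omega helpers ---------------------------------------------------------

    def omega(self, theta):
        d = self.spec.d
        return self.eval(("omega", "val"), 0.0, (0.0,) * self.spec.n, theta, (0.0,) * d)

    def omega_dtheta(self, theta):
        d = self.spec.d
        return self.eval(
            ("omega", "theta"), 0.0, (0.0,) * self.spec.n, theta, (0.0,) * d
        )

    def omega_factor(self, theta):
        """(Omega, cholesky factor, Omega^-1, log det Omega); raises
        :class:`NumericDomainError` when Omega(theta) is not PD."""
        om = self.omega(theta)
        try:
            c, low = cho_factor(om, lower=True)
        except (LinAlgError, ValueError):
            raise NumericDomainError("Omega(theta) is not positive definite")
        d = om.shape[0]
        om_inv = cho_solve((c, low), np.eye(d))
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        return om, (c, low), om_inv, logdet


# ---------------------------------------------------------------------------
# compiled augmented systems


@dataclass
class CompiledSensitivitySystem:
    """A compiled augmented ODE system at inner or outer order.

    ``layout`` maps block keys to slices of the augmented state vector:
    ``("x",)``, ``("eta", k)``, ``("theta", m)``, ``("eta_theta", k, m)``
    and ``("eta_eta", k, l)`` with k <= l (second-order eta blocks are
    stored once per unordered pair).
    """

    spec: ModelSpec
    bundle: DerivativeBundle
    numeric: NumericBundle
    level: str
    n_states: int
    q: int
    p: int
    eta_idx: tuple[int, ...]
    theta_idx: tuple[int, ...]
    total_equations: int
    layout: dict
    _rhs: object
    _y0: object

    def rhs(self, t, y, theta, eta, z=()):
        return np.asarray(self._rhs(t, *y, *theta, *eta, *z), dtype=float)

    def y0(self, theta, eta, z=()):
        return np.asarray(self._y0(0.0, *theta, *eta, *z), dtype=float)


def _nontrivial(bundle: DerivativeBundle, syms):
    free = set()
    for e in bundle.spec.f:
        free |= e.free_symbols
    for e in bundle.spec.x0:
        free |= e.free_symbols
    return tuple(i for i, s in enumerate(syms) if s in free)


def compile_system(
    spec: ModelSpec,
    bundle: DerivativeBundle,
    level: str,
    numeric: NumericBundle | None = None,
) -> CompiledSensitivitySystem:
    """Build the augmented symbolic system at the requested level and compile
    its right-hand side and initial conditions to numpy callables."""
    if level not in ("inner", "outer"):
        raise DomainError(f"unknown level {level!r}")
    if bundle.spec is not spec:
        raise DomainError("bundle was not derived from this spec")
    if numeric is None:
        numeric = NumericBundle(bundle)

    n, d, P = spec.n, spec.d, spec.P
    eta_idx = _nontrivial(bundle, spec.eta)
    theta_idx = _nontrivial(bundle, spec.theta) if level == "outer" else ()
    q, p = len(eta_idx), len(theta_idx)

    f = bundle.f
    fx = sp.Matrix(n, n, lambda i, a: f["x"][i, a])

    def sym(name):
        return sp.Symbol(name, real=True)

    # symbolic placeholders for the sensitivity blocks
    Se = {k: sp.Matrix([sym(f"_se{a}_{k}") for a in range(n)]) for k in eta_idx}
    St = {m: sp.Matrix([sym(f"_st{a}_{m}") for a in range(n)]) for m in theta_idx}
    Set = {
        (k, m): sp.Matrix([sym(f"_su{a}_{k}_{m}") for a in range(n)])
        for k in eta_idx
        for m in theta_idx
    }
    pairs = [(k, l) for ki, k in enumerate(eta_idx) for l in eta_idx[ki:]]
    See = {
        (k, l): sp.Matrix([sym(f"_sv{a}_{k}_{l}") for a in range(n)])
        for (k, l) in pairs
    }

    def see(k, l):
        return See[(k, l)] if (k, l) in See else See[(l, k)]

    y_syms, rhs_exprs, y0_exprs, layout = [], [], [], {}

    def emit(key, vec_syms, vec_rhs, vec_y0):
        off = len(y_syms)
        layout[key] = slice(off, off + n)
        y_syms.extend(vec_syms)
        rhs_exprs.extend(vec_rhs)
        y0_exprs.extend(vec_y0)

    x_syms = list(spec.states)
    emit(("x",), x_syms, list(spec.f), list(spec.x0))

    x0f = bundle.x0
    for k in eta_idx:
        rhs = sp.Matrix([f["eta"][i, k] for i in range(n)]) + fx * Se[k]
        emit(("eta", k), list(Se[k]), list(rhs), [x0f["eta"][i, k] for i in range(n)])
    if level == "outer":
        for m in theta_idx:
            rhs = sp.Matrix([f["theta"][i, m] for i in range(n)]) + fx * St[m]
            emit(
                ("theta", m),
                list(St[m]),
                list(rhs),
                [x0f["theta"][i, m] for i in range(n)],
            )
        for k in eta_idx:
            for m in theta_idx:
                rhs = []
                for i in range(n):
                    e = f["eta_theta"][i, k, m]
                    for a in range(n):
                        e += f["eta_x"][i, k, a] * St[m][a]
                        inner = f["x_theta"][i, a, m]
                        for b in range(n):
                            inner += f["x_x"][i, a, b] * St[m][b]
                        e += inner * Se[k][a]
                        e += fx[i, a] * Set[(k, m)][a]
                    rhs.append(e)
                emit(
                    ("eta_theta", k, m),
                    list(Set[(k, m)]),
                    rhs,
                    [x0f["eta_theta"][i, k, m] for i in range(n)],
                )
        for (k, l) in pairs:
            rhs = []
            for i in range(n):
                e = f["eta_eta"][i, k, l]
                for a in range(n):
                    e += f["eta_x"][i, k, a] * Se[l][a]
                    inner = f["eta_x"][i, l, a]
                    for b in range(n):
                        inner += f["x_x"][i, a, b] * Se[l][b]
                    e += inner * Se[k][a]
                    e += fx[i, a] * see(k, l)[a]
                rhs.append(e)
            emit(
                ("eta_eta", k, l),
                list(see(k, l)),
                rhs,
                [x0f["eta_eta"][i, k, l] for i in range(n)],
            )

    total = len(y_syms)
    assert total == count_equations(n, p, q, level)

    args = (TIME, *y_syms, *spec.theta, *spec.eta, *spec.covariates)
    rhs_fn = sp.lambdify(args, rhs_exprs, modules="numpy", cse=True)
    y0_args = (TIME, *spec.theta, *spec.eta, *spec.covariates)
    y0_fn = sp.lambdify(y0_args, y0_exprs, modules="numpy", cse=True)

    return CompiledSensitivitySystem(
        spec=spec,
        bundle=bundle,
        numeric=numeric,
        level=level,
        n_states=n,
        q=q,
        p=p,
        eta_idx=eta_idx,
        theta_idx=theta_idx,
        total_equations=total,
        layout=layout,
        _rhs=rhs_fn,
        _y0=y0_fn,
    )


# ---------------------------------------------------------------------------
# integration


@dataclass
class Trajectory:
    """States and sensitivity blocks at the requested times.

    Arrays are dense over the full eta/theta dimensions; trivially-zero
    blocks are zero-filled.  ``S_eta[j, a, k] = dx_a/deta_k at t_j`` etc.
    """

    times: np.ndarray
    x: np.ndarray
    S_eta: np.ndarray
    S_theta: np.ndarray | None = None
    S_eta_theta: np.ndarray | None = None
    S_eta_eta: np.ndarray | None = None

    def row(self, t) -> int:
        j = int(np.searchsorted(self.times, t))
        if j >= len(self.times) or self.times[j] != t:
            raise KeyError(f"time {t} not on trajectory grid")
        return j


def _covariate_value(series, t):
    if np.isscalar(series) or isinstance(series, (int, float)):
        return float(series)
    ts, vs = series
    i = int(np.searchsorted(ts, t, side="right")) - 1
    return float(vs[max(i, 0)])


def covariate_vector(spec: ModelSpec, individual, t):
    """Piecewise-constant covariate values at time t (latest record <= t)."""
    return tuple(
        _covariate_value(individual.covariates[s.name], t) for s in spec.covariates
    )


def _covariate_breaks(spec, individual, t0, t1):
    breaks = set()
    for s in spec.covariates:
        series = individual.covariates[s.name]
        if not (np.isscalar(series) or isinstance(series, (int, float))):
            for t in np.asarray(series[0], dtype=float):
                if t0 < t <= t1:
                    breaks.add(float(t))
    return sorted(breaks)


def integrate(
    system: CompiledSensitivitySystem,
    individual,
    theta,
    eta,
    solver: SolverConfig | None = None,
) -> Trajectory:
    """Solve the combined augmented system for one individual and return the
    states and all sensitivity blocks at the observation times."""
    solver = solver or ESTIMATION
    spec = system.spec
    theta = np.asarray(theta, dtype=float)
    eta = np.asarray(eta, dtype=float)
    t0 = float(individual.t0)
    obs_t = np.asarray(individual.times, dtype=float)
    if obs_t.size and obs_t[0] < t0:
        raise DomainError(f"observation at t={obs_t[0]} precedes t0={t0}")

    eval_ts = np.unique(obs_t)
    t_end = eval_ts[-1] if eval_ts.size else t0
    y = system.y0(theta, eta, covariate_vector(spec, individual, t0))
    if not np.all(np.isfinite(y)):
        raise IntegrationError("non-finite initial condition", t=t0)

    out = np.empty((eval_ts.size, system.total_equations))
    done = 0
    seg_edges = [t0] + _covariate_breaks(spec, individual, t0, t_end) + [t_end]
    for a, b in zip(seg_edges[:-1], seg_edges[1:]):
        z = covariate_vector(spec, individual, a)
        mask = (eval_ts > a) & (eval_ts <= b) if a > t0 else (eval_ts >= a) & (eval_ts <= b)
        ts_seg = eval_ts[mask]
        grid = np.concatenate(([a], ts_seg))
        keep = np.ones(ts_seg.size, dtype=bool)
        if ts_seg.size and ts_seg[0] == a:
            grid = grid[1:]
            # a requested time coincides with the segment start
            out[done] = y
            done += 1
            keep[0] = False
            ts_seg = ts_seg[1:]
        if ts_seg.size:
            rhs = system._rhs

            def func(yv, tv):
                return rhs(tv, *yv, *theta, *eta, *z)

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ys, info = odeint(
                    func,
                    y,
                    grid,
                    rtol=solver.rtol,
                    atol=solver.atol,
                    mxstep=solver.mxstep,
                    full_output=True,
                )
            if info["message"] != "Integration successful.":
                raise IntegrationError(
                    f"ODE solver failed: {info['message']}",
                    t=float(info["tcur"][-1]) if len(info["tcur"]) else a,
                )
            sol = ys[1:]
            if not np.all(np.isfinite(sol)):
                raise IntegrationError("non-finite trajectory", t=b)
            out[done : done + sol.shape[0]] = sol
            done += sol.shape[0]
            y = ys[-1]
        elif b > a:
            # advance across a sample-free segment
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ys, info = odeint(
                    lambda yv, tv: system._rhs(tv, *yv, *theta, *eta, *z),
                    y,
                    np.array([a, b]),
                    rtol=solver.rtol,
                    atol=solver.atol,
                    mxstep=solver.mxstep,
                    full_output=True,
                )
            if info["message"] != "Integration successful.":
                raise IntegrationError(f"ODE solver failed: {info['message']}", t=b)
            y = ys[-1]
    if done != eval_ts.size:
        raise IntegrationError("internal time-bookkeeping error")

    return _unpack(system, eval_ts, out)


def _unpack(system, times, Y):
    spec = system.spec
    T = Y.shape[0]
    n, d, P = spec.n, spec.d, spec.P
    x = Y[:, system.layout[("x",)]]
    S_eta = np.zeros((T, n, d))
    for k in system.eta_idx:
        S_eta[:, :, k] = Y[:, system.layout[("eta", k)]]
    if system.level == "inner":
        return Trajectory(times=times, x=x, S_eta=S_eta)
    S_theta = np.zeros((T, n, P))
    for m in system.theta_idx:
        S_theta[:, :, m] = Y[:, system.layout[("theta", m)]]
    S_et = np.zeros((T, n, d, P))
    for k in system.eta_idx:
        for m in system.theta_idx:
            S_et[:, :, k, m] = Y[:, system.layout[("eta_theta", k, m)]]
    S_ee = np.zeros((T, n, d, d))
    for key in system.layout:
        if key[0] == "eta_eta":
            _, k, l = key
            blk = Y[:, system.layout[key]]
            S_ee[:, :, k, l] = blk
            S_ee[:, :, l, k] = blk
    return Trajectory(
        times=times,
        x=x,
        S_eta=S_eta,
        S_theta=S_theta,
        S_eta_theta=S_et,
        S_eta_eta=S_ee,
    )


# ---------------------------------------------------------------------------
# convenience wrapper


@dataclass
class CompiledModel:
    """A model compiled at both levels, sharing one numeric bundle.

    ``inner`` drives inner solves and objective evaluations; ``outer`` drives
    outer-gradient evaluations.
    """

    spec: ModelSpec
    bundle: DerivativeBundle
    numeric: NumericBundle
    inner: CompiledSensitivitySystem
    outer: CompiledSensitivitySystem


def compile_model(spec: ModelSpec, bundle: DerivativeBundle | None = None) -> CompiledModel:
    from .model import differentiate_model

    if bundle is None:
        bundle = differentiate_model(spec)
    numeric = NumericBundle(bundle)
    inner = compile_system(spec, bundle, "inner", numeric)
    outer = compile_system(spec, bundle, "outer", numeric)
    return CompiledModel(spec=spec, bundle=bundle, numeric=numeric, inner=inner, outer=outer)
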