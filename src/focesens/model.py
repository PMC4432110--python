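"""Symbolic declaration of nonlinear mixed-effects (NLME) models.

An NLME model couples a per-individual dynamical system

    dx/dt = f(x, t, Z, theta, eta),      x(t0) = x0(Z(t0), theta, eta),

with an observation model

    y_j = h(x(t_j), t_j, Z(t_j), theta, eta) + e_j,
    e_j ~ N(0, R(x(t_j), t_j, Z(t_j), theta, eta)),

where theta are fixed effects shared by the population, eta are
per-individual random effects with eta ~ N(0, Omega(theta)), and Z are
covariates.  The elements of Omega that are estimated are carried inside
theta, so the population likelihood is a function of theta alone.

This module holds the symbolic intermediate representation (:class:`ModelSpec`)
and every symbolic partial derivative of f, x0, h, R and Omega that the
sensitivity-equation and gradient machinery downstream consumes
(:class:`DerivativeBundle`).  All differentiation is done once, symbolically,
per model; numerical code never finite-differences the model functions except
in the dedicated reference path.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass, field

import sympy as sp
from sympy.core.function import AppliedUndef

from .errors import UnsupportedExpressionError, ValidationError

__all__ = [
    "ModelSpec",
    "ObsGroup",
    "TensorFamily",
    "DerivativeBundle",
    "build_model",
    "differentiate_model",
]

#: The single time symbol shared by all models.
TIME = sp.Symbol("t", real=True)


@dataclass(frozen=True)
class ObsGroup:
    """One scalar output group: mean expression h and residual variance r."""

    h: sp.Expr
    r: sp.Expr


@dataclass(frozen=True)
class ModelSpec:
    """Validated symbolic representation of an NLME model.

    Invariants (enforced by :func:`build_model`):

    * every free symbol of ``f``, ``x0``, ``h``, ``r`` is a state, ``t``, a
      covariate, a theta component or an eta component;
    * ``omega`` is symmetric by construction and depends on theta only;
    * ``n >= 1``, ``d >= 1``, ``P >= 1``.
    """

    states: tuple[sp.Symbol, ...]
    f: tuple[sp.Expr, ...]
    x0: tuple[sp.Expr, ...]
    obs: tuple[ObsGroup, ...]
    omega: sp.ImmutableMatrix
    theta: tuple[sp.Symbol, ...]
    eta: tuple[sp.Symbol, ...]
    covariates: tuple[sp.Symbol, ...] = ()
    name: str = "model"

    @property
    def n(self) -> int:
        return len(self.states)

    @property
    def d(self) -> int:
        return len(self.eta)

    @property
    def P(self) -> int:
        return len(self.theta)

    @property
    def n_outputs(self) -> int:
        return len(self.obs)

    def theta_index(self, name: str) -> int:
        for i, s in enumerate(self.theta):
            if s.name == name:
                return i
        raise KeyError(name)


class TensorFamily:
    """A dense tensor of sympy expressions, stored flat in row-major order.

    Differentiating a family with respect to a symbol list appends one axis
    (the symbol index) as the last axis.
    """

    __slots__ = ("exprs", "shape")

    def __init__(self, exprs, shape):
        self.exprs = tuple(exprs)
        self.shape = tuple(shape)
        size = 1
        for s in self.shape:
            size *= s
        if size != len(self.exprs):
            raise ValueError("shape/size mismatch")

    def __getitem__(self, idx):
        if isinstance(idx, int):
            idx = (idx,)
        flat = 0
        for i, (j, s) in enumerate(zip(idx, self.shape)):
            flat = flat * s + j
        return self.exprs[flat]

    def diff(self, syms) -> "TensorFamily":
        out = []
        for e in self.exprs:
            for s in syms:
                out.append(sp.diff(e, s))
        return TensorFamily(out, self.shape + (len(syms),))


@dataclass(frozen=True)
class DerivativeBundle:
    """All symbolic partials of a model required by the sensitivity systems
    and the inner/outer gradient expressions.

    ``f``, ``x0`` and each entry of ``h``/``r`` are dicts keyed by derivative
    family: ``val``, ``x``, ``theta``, ``eta`` (first order) and ``x_x``,
    ``x_theta``, ``eta_x``, ``eta_theta``, ``eta_eta`` (second order, axis
    order as the key reads).  ``omega`` holds ``val`` (d, d) and ``theta``
    (d, d, P).  Mixed second partials obey Clairaut symmetry because sympy
    differentiates exactly.
    """

    spec: ModelSpec
    f: dict
    x0: dict
    h: tuple
    r: tuple
    omega: dict


# ---------------------------------------------------------------------------
# building


def _as_symbols(names, kind):
    syms = []
    seen = set()
    for nm in names:
        if not isinstance(nm, str) or not nm.isidentifier():
            raise ValidationError(f"invalid {kind} name: {nm!r}")
        if nm in seen:
            raise ValidationError(f"duplicate {kind} name: {nm!r}")
        seen.add(nm)
        syms.append(sp.Symbol(nm, real=True))
    return tuple(syms)


def _sympify(text, namespace, where):
    if isinstance(text, numbers.Number):
        return sp.sympify(text)
    try:
        expr = sp.sympify(text, locals=dict(namespace))
    except (sp.SympifyError, SyntaxError, TypeError) as exc:
        raise ValidationError(f"cannot parse expression for {where}: {text!r} ({exc})")
    return expr


def _check_closure(expr, allowed, where):
    unknown = sorted(s.name for s in expr.free_symbols if s not in allowed)
    if unknown:
        raise ValidationError(
            f"undefined symbol(s) {', '.join(unknown)} in expression for {where}"
        )
    undef_fns = {type(a).__name__ for a in expr.atoms(AppliedUndef)}
    if undef_fns:
        raise ValidationError(
            f"undefined function(s) {', '.join(sorted(undef_fns))} in {where}"
        )


def build_model(declaration: dict) -> ModelSpec:
    """Build a validated :class:`ModelSpec` from a structured declaration.

    The declaration is a plain mapping (typically parsed from YAML) with keys

    ``states``
        list of state names.
    ``odes``
        mapping state name -> right-hand-side expression (or a list aligned
        with ``states``).
    ``x0``
        list of initial-condition expressions aligned with ``states``.
    ``observations``
        list of ``{"h": expr, "r": expr}`` scalar output groups; ``r`` is the
        residual *variance*.
    ``theta`` / ``eta``
        lists of estimated fixed-effect and random-effect names.
    ``omega``
        either ``{"diagonal": [expr, ...]}`` or ``{"matrix": [[...], ...]}``;
        entries are expressions in theta.  A full matrix must be symmetric.
    ``fixed``
        optional mapping of parameter name -> numeric value; these are
        substituted as constants before differentiation and are not counted
        in theta.
    ``defs``
        optional ordered mapping of intermediate definitions, substituted in
        order into all expressions (purely notational).
    ``covariates``
        optional list of covariate names.
    """
    try:
        state_names = list(declaration["states"])
        theta_names = list(declaration["theta"])
        eta_names = list(declaration["eta"])
        odes = declaration["odes"]
        x0_decl = list(declaration["x0"])
        obs_decl = list(declaration["observations"])
        omega_decl = declaration["omega"]
    except KeyError as exc:
        raise ValidationError(f"declaration is missing required block {exc}")

    cov_names = list(declaration.get("covariates", []))
    fixed = dict(declaration.get("fixed", {}))
    defs = declaration.get("defs", {})

    states = _as_symbols(state_names, "state")
    theta = _as_symbols(theta_names, "theta")
    eta = _as_symbols(eta_names, "eta")
    covs = _as_symbols(cov_names, "covariate")

    if len(states) < 1 or len(eta) < 1 or len(theta) < 1:
        raise ValidationError("need at least one state, one theta and one eta")

    namespace = {"t": TIME}
    for s in states + theta + eta + covs:
        if s.name in namespace:
            raise ValidationError(f"name {s.name!r} declared twice")
        namespace[s.name] = s
    for nm, val in fixed.items():
        if nm in namespace:
            raise ValidationError(f"fixed parameter {nm!r} shadows a declared symbol")
        if not isinstance(val, numbers.Number):
            raise ValidationError(f"fixed parameter {nm!r} must be numeric")
        namespace[nm] = sp.Float(val)
    for nm, text in defs.items():
        if nm in namespace:
            raise ValidationError(f"definition {nm!r} shadows a declared symbol")
        namespace[nm] = _sympify(text, namespace, f"defs[{nm}]")

    allowed_dyn = set(states) | set(theta) | set(eta) | set(covs) | {TIME}
    allowed_x0 = set(theta) | set(eta) | set(covs)

    if isinstance(odes, dict):
        try:
            ode_list = [odes[nm] for nm in state_names]
        except KeyError as exc:
            raise ValidationError(f"odes block is missing state {exc}")
    else:
        ode_list = list(odes)
    if len(ode_list) != len(states) or len(x0_decl) != len(states):
        raise ValidationError("odes/x0 must have one entry per state")

    f_exprs = []
    for nm, text in zip(state_names, ode_list):
        e = _sympify(text, namespace, f"d{nm}/dt")
        _check_closure(e, allowed_dyn, f"d{nm}/dt")
        f_exprs.append(e)
    x0_exprs = []
    for nm, text in zip(state_names, x0_decl):
        e = _sympify(text, namespace, f"x0[{nm}]")
        _check_closure(e, allowed_x0, f"x0[{nm}]")
        x0_exprs.append(e)

    obs = []
    for g, block in enumerate(obs_decl, start=1):
        h = _sympify(block["h"], namespace, f"observation {g} mean")
        r = _sympify(block["r"], namespace, f"observation {g} variance")
        _check_closure(h, allowed_dyn, f"observation {g} mean")
        _check_closure(r, allowed_dyn, f"observation {g} variance")
        obs.append(ObsGroup(h=h, r=r))
    if not obs:
        raise ValidationError("at least one output group is required")

    d = len(eta)
    if isinstance(omega_decl, dict) and "diagonal" in omega_decl:
        diag = [_sympify(e, namespace, "omega diagonal") for e in omega_decl["diagonal"]]
        if len(diag) != d:
            raise ValidationError("omega diagonal must have one entry per eta")
        om = sp.diag(*diag)
    elif isinstance(omega_decl, dict) and "matrix" in omega_decl:
        rows = omega_decl["matrix"]
        if len(rows) != d or any(len(r_) != d for r_ in rows):
            raise ValidationError("omega matrix must be d x d")
        om = sp.Matrix(
            [[_sympify(e, namespace, "omega matrix") for e in row] for row in rows]
        )
        if sp.simplify(om - om.T) != sp.zeros(d, d):
            raise ValidationError("omega declaration is not symmetric")
    else:
        raise ValidationError("omega must declare either 'diagonal' or 'matrix'")
    allowed_omega = set(theta)
    for e in om:
        _check_closure(e, allowed_omega, "omega (theta only)")

    return ModelSpec(
        states=states,
        f=tuple(f_exprs),
        x0=tuple(x0_exprs),
        obs=tuple(obs),
        omega=sp.ImmutableMatrix(om),
        theta=theta,
        eta=eta,
        covariates=covs,
        name=str(declaration.get("name", "model")),
    )


# ---------------------------------------------------------------------------
# differentiation


_BAD_ATOMS = (sp.Derivative, sp.DiracDelta, sp.Heaviside)


def _check_differentiable(fam: TensorFamily, where: str):
    for e in fam.exprs:
        bad = e.atoms(*_BAD_ATOMS)
        if bad:
            raise UnsupportedExpressionError(
                f"expression in {where} is not smoothly differentiable: "
                f"{sorted(map(str, bad))}"
            )


def _families(val: TensorFamily, spec: ModelSpec, with_states: bool, where: str):
    """First- and second-order partials of one model function."""
    th, et = spec.theta, spec.eta
    fam = {"val": val}
    fam["theta"] = val.diff(th)
    fam["eta"] = val.diff(et)
    fam["eta_theta"] = fam["eta"].diff(th)
    fam["eta_eta"] = fam["eta"].diff(et)
    if with_states:
        xs = spec.states
        fam["x"] = val.diff(xs)
        fam["x_x"] = fam["x"].diff(xs)
        fam["x_theta"] = fam["x"].diff(th)
        fam["eta_x"] = fam["eta"].diff(xs)
    for key, f in fam.items():
        _check_differentiable(f, f"{where} ({key})")
    return fam


def differentiate_model(spec: ModelSpec) -> DerivativeBundle:
    """Produce every symbolic partial the sensitivity and gradient code needs.

    Raises :class:`UnsupportedExpressionError` when an expression contains a
    non-differentiable construct.
    """
    n, d, P = spec.n, spec.d, spec.P
    f_val = TensorFamily(spec.f, (n,))
    x0_val = TensorFamily(spec.x0, (n,))
    f_fam = _families(f_val, spec, with_states=True, where="f")
    x0_fam = _families(x0_val, spec, with_states=False, where="x0")

    h_fams, r_fams = [], []
    for g, grp in enumerate(spec.obs, start=1):
        h_fams.append(
            _families(TensorFamily((grp.h,), ()), spec, True, f"h[{g}]")
        )
        r_fams.append(
            _families(TensorFamily((grp.r,), ()), spec, True, f"r[{g}]")
        )

    om_val = TensorFamily(tuple(spec.omega), (d, d))
    om_fam = {"val": om_val, "theta": om_val.diff(spec.theta)}

    return DerivativeBundle(
        spec=spec,
        f=f_fam,
        x0=x0_fam,
        h=tuple(h_fams),
        r=tuple(r_fams),
        omega=om_fam,
    )
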