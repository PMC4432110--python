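"""Benchmark models M1-M4: two-compartment PK with capacity-limited elimination.

The structural model is a two-compartment system with Michaelis-Menten
(capacity-limited) elimination from the central compartment.  With amounts
A1 (central) and A2 (peripheral), concentrations C1 = A1/V1, C2 = A2/V2:

    dA1/dt = -Vmax C1 / (Km + C1) - Q C1 + Q C2
    dA2/dt =  Q C1 - Q C2,         A1(0) = dose,  A2(0) = 0.

Random effects act multiplicatively on parameters, p_i = p exp(eta_p), with
eta ~ N(0, Omega).  Four variants of increasing complexity:

M1  estimate {Vmax, V1, Km} + diagonal Omega(3); V2, Q and the additive
    residual SD fixed; observe C1 (additive error).          P=6,  d=3, FOCE
M2  estimate all five ODE parameters, the additive residual SD and the full
    Omega(3) (6 elements).                                   P=12, d=3, FOCE
M3  adds a fourth random effect (on Q), full Omega(4) (10 elements) and a
    second output: C1 with additive+proportional error (2 parameters), C2
    with additive error (1 parameter).                       P=18, d=4, FOCE
M4  identical to M3, estimated with FOCEI.

True values and the sampling design are package fixtures chosen as
realistic PK magnitudes with nonlinear elimination around Km (they are
documented defaults, not literature estimates): Vmax=10 mg/h, Km=5 mg/L,
V1=10 L, V2=30 L, Q=2 L/h, 100 mg bolus, samples at 0.25-24 h, omega^2=0.1
(off-diagonals 0.01 where a full matrix is estimated), sigma_add=0.25 mg/L,
sigma_prop=0.1, N=20 individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .compile import (
    CompiledModel,
    SolverConfig,
    compile_model,
    count_equations,
    covariate_vector,
    integrate,
)
from .data import IndividualRecord, PopulationData
from .errors import DomainError, IntegrationError, ValidationError
from .model import ModelSpec, build_model, differentiate_model

__all__ = ["BenchmarkModel", "make_benchmark", "simulate_population", "draw_etas"]

#: fixture design shared by all four variants
TRUE_VALUES = {
    "Vmax": 10.0, "Km": 5.0, "V1": 10.0, "V2": 30.0, "Q": 2.0,
    "sigma_add": 0.25, "sigma_prop": 0.1, "sigma_add2": 0.25,
    "omega_diag": 0.1, "omega_offdiag": 0.01,
}
DOSE = 100.0
SAMPLE_TIMES = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 24.0)
DEFAULT_N = 20

#: structural counts each variant must reproduce
EXPECTED_COUNTS = {
    "M1": {"P": 6, "d": 3, "q": 3, "p": 3, "inner": 8, "outer": 44,
           "method": "FOCE"},
    "M2": {"P": 12, "d": 3, "q": 3, "p": 5, "inner": 8, "outer": 60,
           "method": "FOCE"},
    "M3": {"P": 18, "d": 4, "q": 4, "p": 5, "inner": 10, "outer": 80,
           "method": "FOCE"},
    "M4": {"P": 18, "d": 4, "q": 4, "p": 5, "inner": 10, "outer": 80,
           "method": "FOCEI"},
}


@dataclass
class BenchmarkModel:
    tag: str
    spec: ModelSpec
    method: str
    theta_true: np.ndarray
    theta_names: tuple
    omega_true: np.ndarray
    dose: float = DOSE
    sample_times: tuple = SAMPLE_TIMES
    default_N: int = DEFAULT_N
    expected: dict = field(default_factory=dict)
    _compiled: CompiledModel | None = field(default=None, repr=False)

    def compiled(self) -> CompiledModel:
        if self._compiled is None:
            self._compiled = compile_model(self.spec)
        return self._compiled


def _omega_full(names, d):
    """Lower-triangle theta names arranged as a symmetric matrix block."""
    rows = []
    it = iter(names)
    tri = [[None] * d for _ in range(d)]
    for i in range(d):
        for j in range(i + 1):
            tri[i][j] = next(it)
    for i in range(d):
        rows.append([tri[i][j] if j <= i else tri[j][i] for j in range(d)])
    return rows


def _declaration(tag: str) -> dict:
    tv = TRUE_VALUES
    base_defs = {
        "C1": "A1 / V1i",
        "C2": "A2 / V2i",
    }
    odes = {
        "A1": "-Vmax_i * C1 / (Km_i + C1) - Q_i * C1 + Q_i * C2",
        "A2": "Q_i * C1 - Q_i * C2",
    }
    if tag == "M1":
        theta = ["Vmax", "V1", "Km", "w11", "w22", "w33"]
        defs = {
            "Vmax_i": "Vmax * exp(eta1)",
            "V1i": "V1 * exp(eta2)",
            "Km_i": "Km * exp(eta3)",
            "Q_i": str(tv["Q"]),
            "V2i": str(tv["V2"]),
            **base_defs,
        }
        eta = ["eta1", "eta2", "eta3"]
        omega = {"diagonal": ["w11", "w22", "w33"]}
        observations = [{"h": "C1", "r": str(tv["sigma_add"] ** 2)}]
        fixed = {}
    elif tag == "M2":
        theta = ["Vmax", "Km", "V1", "V2", "Q", "sigma_add",
                 "w11", "w21", "w22", "w31", "w32", "w33"]
        defs = {
            "Vmax_i": "Vmax * exp(eta1)",
            "V1i": "V1 * exp(eta2)",
            "Km_i": "Km * exp(eta3)",
            "Q_i": "Q",
            "V2i": "V2",
            **base_defs,
        }
        eta = ["eta1", "eta2", "eta3"]
        omega = {"matrix": _omega_full(["w11", "w21", "w22", "w31", "w32", "w33"], 3)}
        observations = [{"h": "C1", "r": "sigma_add**2"}]
        fixed = {}
    elif tag in ("M3", "M4"):
        omega_names = ["w11", "w21", "w22", "w31", "w32", "w33",
                       "w41", "w42", "w43", "w44"]
        theta = ["Vmax", "Km", "V1", "V2", "Q",
                 "sigma_add", "sigma_prop", "sigma_add2"] + omega_names
        defs = {
            "Vmax_i": "Vmax * exp(eta1)",
            "V1i": "V1 * exp(eta2)",
            "Km_i": "Km * exp(eta3)",
            "Q_i": "Q * exp(eta4)",
            "V2i": "V2",
            **base_defs,
        }
        eta = ["eta1", "eta2", "eta3", "eta4"]
        omega = {"matrix": _omega_full(omega_names, 4)}
        observations = [
            {"h": "C1", "r": "sigma_add**2 + sigma_prop**2 * C1**2"},
            {"h": "C2", "r": "sigma_add2**2"},
        ]
        fixed = {}
    else:
        raise DomainError(f"unknown benchmark tag {tag!r}")
    return {
        "name": tag,
        "states": ["A1", "A2"],
        "odes": odes,
        "x0": [str(DOSE), "0"],
        "observations": observations,
        "theta": theta,
        "eta": eta,
        "omega": omega,
        "fixed": fixed,
        "defs": defs,
    }


def _true_theta(tag, spec):
    tv = TRUE_VALUES
    vals = []
    for s in spec.theta:
        nm = s.name
        if nm in tv:
            vals.append(tv[nm])
        elif nm.startswith("w"):
            i, j = int(nm[1]), int(nm[2])
            vals.append(tv["omega_diag"] if i == j else tv["omega_offdiag"])
        else:
            raise DomainError(f"no fixture value for {nm}")
    return np.array(vals)


def make_benchmark(tag: str) -> BenchmarkModel:
    """Declare one benchmark variant and verify its structural counts."""
    tag = tag.upper()
    if tag not in EXPECTED_COUNTS:
        raise DomainError(f"unknown benchmark tag {tag!r} (expected M1-M4)")
    spec = build_model(_declaration(tag))
    expected = EXPECTED_COUNTS[tag]
    bundle = differentiate_model(spec)
    from .compile import _nontrivial

    q = len(_nontrivial(bundle, spec.eta))
    p = len(_nontrivial(bundle, spec.theta))
    got = {
        "P": spec.P, "d": spec.d, "q": q, "p": p,
        "inner": count_equations(spec.n, 0, q, "inner"),
        "outer": count_equations(spec.n, p, q, "outer"),
        "method": expected["method"],
    }
    if got != expected:
        raise ValidationError(
            f"benchmark {tag} structural counts {got} do not reproduce the "
            f"declared table {expected}"
        )
    theta_true = _true_theta(tag, spec)
    # evaluate Omega at the true theta for the simulator
    from .compile import NumericBundle

    omega_true = NumericBundle(bundle).omega(theta_true)
    return BenchmarkModel(
        tag=tag,
        spec=spec,
        method=expected["method"],
        theta_true=theta_true,
        theta_names=tuple(s.name for s in spec.theta),
        omega_true=omega_true,
        expected=expected,
    )


def draw_etas(model: BenchmarkModel, N: int, rng) -> np.ndarray:
    """N draws of eta ~ N(0, Omega_true); separated out so the sampling law
    can be checked without integrating any ODEs."""
    return rng.multivariate_normal(np.zeros(model.spec.d), model.omega_true, size=N)


def simulate_population(
    model: BenchmarkModel,
    N: int | None = None,
    seed: int = 0,
    solver: SolverConfig | None = None,
    sample_times=None,
):
    """Simulate a population from the benchmark's true parameters.

    Per individual: draw eta ~ N(0, Omega_true), integrate the ODEs, and
    add residual noise e_ij ~ N(0, R_ij) evaluated on the true trajectory.
    Deterministic under ``seed``.  Returns ``(PopulationData, etas)``.
    """
    N = model.default_N if N is None else int(N)
    if N < 1:
        raise DomainError("N must be >= 1")
    times = np.asarray(sample_times if sample_times is not None
                       else model.sample_times, dtype=float)
    rng = np.random.default_rng(seed)
    etas = draw_etas(model, N, rng)
    cm = model.compiled()
    spec = model.spec
    G = spec.n_outputs
    all_times = np.tile(times, G)
    all_out = np.repeat(np.arange(1, G + 1), times.size)
    order = np.lexsort((all_out, all_times))
    individuals = []
    for i in range(N):
        ind = IndividualRecord(
            id=str(i + 1),
            times=all_times[order],
            dv=np.zeros(all_times.size),
            out=all_out[order],
            t0=0.0,
        )
        try:
            traj = integrate(cm.inner, ind, model.theta_true, etas[i], solver)
        except IntegrationError as exc:
            raise IntegrationError(
                f"simulation failed for individual {ind.id}: {exc}", t=exc.t
            )
        dv = np.empty(ind.n_obs)
        for j in range(ind.n_obs):
            t = ind.times[j]
            g = int(ind.out[j])
            x = traj.x[traj.row(t)]
            z = covariate_vector(spec, ind, t)
            h = float(cm.numeric.eval(("h", g - 1, "val"), t, x,
                                      model.theta_true, etas[i], z))
            r = float(cm.numeric.eval(("r", g - 1, "val"), t, x,
                                      model.theta_true, etas[i], z))
            dv[j] = h + rng.normal(0.0, np.sqrt(max(r, 0.0)))
        ind.dv = dv
        individuals.append(ind)
    return PopulationData(individuals), etas
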