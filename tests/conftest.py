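import numpy as np
import pytest

import focesens as fs
from focesens.compile import SolverConfig

TIGHT = SolverConfig(rtol=1e-10, atol=1e-12)
VERY_TIGHT = SolverConfig(rtol=1e-12, atol=1e-14)


# ---------------------------------------------------------------------------
# model fixtures (session-scoped: symbolic compilation is the slow part)


@pytest.fixture(scope="session")
def m1():
    bm = fs.make_benchmark("M1")
    bm.compiled()
    return bm


@pytest.fixture(scope="session")
def m3():
    bm = fs.make_benchmark("M3")
    bm.compiled()
    return bm


@pytest.fixture(scope="session")
def m1_small_data(m1):
    data, etas = fs.simulate_population(m1, N=3, seed=1)
    return data, etas


LINGAUSS_DECL = {
    "name": "lingauss",
    "states": ["x"],
    "odes": {"x": "-k*x"},
    "x0": ["b + eta1"],
    "observations": [{"h": "x", "r": "s2"}],
    "theta": ["k", "b", "s2", "w"],
    "eta": ["eta1"],
    "omega": {"diagonal": ["w"]},
}

LINGAUSS_THETA = np.array([0.7, 4.0, 0.3, 0.5])
LINGAUSS_TIMES = np.array([0.5, 1.0, 2.0])


@pytest.fixture(scope="session")
def lingauss():
    """One-state linear-Gaussian decay model: FOCE/Laplace are exact."""
    spec = fs.build_model(LINGAUSS_DECL)
    return fs.compile_model(spec)


@pytest.fixture(scope="session")
def lingauss_data():
    rng = np.random.default_rng(7)
    k, b, s2, w = LINGAUSS_THETA
    inds = []
    for i in range(4):
        e = rng.normal(0, np.sqrt(w))
        mu = (b + e) * np.exp(-k * LINGAUSS_TIMES)
        dv = mu + rng.normal(0, np.sqrt(s2), size=LINGAUSS_TIMES.size)
        inds.append(
            fs.IndividualRecord(id=str(i + 1), times=LINGAUSS_TIMES, dv=dv, t0=0.0)
        )
    return fs.PopulationData(inds)


SCALAR_DECL = {
    # degenerate dynamics: yhat = theta + eta through a frozen state
    "name": "scalar",
    "states": ["x"],
    "odes": {"x": "0"},
    "x0": ["mu + eta1"],
    "observations": [{"h": "x", "r": "1.0"}],
    "theta": ["mu"],
    "eta": ["eta1"],
    "omega": {"diagonal": ["1.0"]},
}


@pytest.fixture(scope="session")
def scalar_model():
    spec = fs.build_model(SCALAR_DECL)
    return fs.compile_model(spec)


def scalar_individual(d=1.0, t=1.0):
    return fs.IndividualRecord(id="1", times=np.array([t]), dv=np.array([d]), t0=0.0)
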