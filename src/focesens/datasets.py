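"""Reading and writing longitudinal datasets in a NONMEM-like CSV layout.

Columns: ID (string or integer), TIME (model time units), DV (observed
value), OUT (1-based output-group index, optional, default 1), plus one
column per declared covariate.  Rows must be sorted by (ID, TIME); repeated
(ID, TIME, OUT) rows are retained as genuine repeated observations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import IndividualRecord, PopulationData
from .errors import ParseError, ValidationError
from .model import ModelSpec

__all__ = ["read_dataset", "write_dataset"]

REQUIRED = ("ID", "TIME", "DV")


def read_dataset(path, spec: ModelSpec, t0: float | None = None) -> PopulationData:
    """Parse a dataset CSV into :class:`PopulationData`.

    ``t0`` overrides the integration start time for every individual;
    by default it is each individual's first record TIME.
    """
    df = pd.read_csv(path)
    for col in REQUIRED:
        if col not in df.columns:
            raise ParseError(f"dataset is missing required column {col!r}")
    if "OUT" not in df.columns:
        df = df.assign(OUT=1)
    cov_names = [s.name for s in spec.covariates]
    for nm in cov_names:
        if nm not in df.columns:
            raise ParseError(f"dataset is missing covariate column {nm!r}")

    n_groups = spec.n_outputs
    bad = df.index[~df["OUT"].isin(range(1, n_groups + 1))]
    if len(bad):
        row = int(bad[0]) + 2  # header + 1-based
        raise ParseError(
            f"row {row}: OUT={df.loc[bad[0], 'OUT']} outside the declared "
            f"{n_groups} output group(s)"
        )
    if not np.all(np.isfinite(df["DV"].to_numpy(dtype=float))):
        row = int(df.index[~np.isfinite(df["DV"].astype(float))][0]) + 2
        raise ParseError(f"row {row}: non-finite DV")

    individuals = []
    seen = []
    for ident, grp in df.groupby("ID", sort=False):
        times = grp["TIME"].to_numpy(dtype=float)
        if np.any(np.diff(times) < 0):
            pos = int(grp.index[np.flatnonzero(np.diff(times) < 0)[0] + 1]) + 2
            raise ParseError(f"row {pos}: TIME not sorted within ID={ident}")
        covs = {}
        for nm in cov_names:
            vals = grp[nm].to_numpy(dtype=float)
            if np.all(vals == vals[0]):
                covs[nm] = float(vals[0])
            else:
                covs[nm] = (times.copy(), vals)
        individuals.append(
            IndividualRecord(
                id=str(ident),
                times=times,
                dv=grp["DV"].to_numpy(dtype=float),
                out=grp["OUT"].to_numpy(dtype=int),
                covariates=covs,
                t0=float(times[0]) if t0 is None else float(t0),
            )
        )
        seen.append(str(ident))
    if len(set(seen)) != len(seen):
        raise ParseError("dataset IDs are not contiguous (an ID reappears "
                         "after another ID); sort rows by (ID, TIME)")
    return PopulationData(individuals)


def write_dataset(data: PopulationData, path=None, spec: ModelSpec | None = None):
    """Serialize a population back to the CSV dialect; returns the frame."""
    rows = []
    cov_names = [s.name for s in spec.covariates] if spec is not None else []
    for ind in data:
        for j in range(ind.n_obs):
            row = {
                "ID": ind.id,
                "TIME": ind.times[j],
                "DV": ind.dv[j],
                "OUT": int(ind.out[j]),
            }
            for nm in cov_names:
                series = ind.covariates[nm]
                if np.isscalar(series) or isinstance(series, (int, float)):
                    row[nm] = float(series)
                else:
                    ts, vs = series
                    k = int(np.searchsorted(ts, ind.times[j], side="right")) - 1
                    row[nm] = float(vs[max(k, 0)])
            rows.append(row)
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df
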