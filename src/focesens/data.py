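"""Longitudinal data containers: per-individual records and populations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["IndividualRecord", "PopulationData"]


@dataclass
class IndividualRecord:
    """Observations for one individual.

    ``times`` must be non-decreasing and not precede ``t0``; ``out`` holds
    the 1-based output-group index of each observation.  ``covariates`` maps
    a covariate name to either a constant or a ``(times, values)`` pair
    interpreted as a piecewise-constant series.
    """

    id: str
    times: np.ndarray
    dv: np.ndarray
    out: np.ndarray | None = None
    covariates: dict = field(default_factory=dict)
    t0: float = 0.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.dv = np.asarray(self.dv, dtype=float)
        if self.out is None:
            self.out = np.ones(self.times.size, dtype=int)
        self.out = np.asarray(self.out, dtype=int)
        if not (self.times.size == self.dv.size == self.out.size):
            raise ValidationError(f"individual {self.id}: ragged record arrays")
        if np.any(np.diff(self.times) < 0):
            raise ValidationError(f"individual {self.id}: times not sorted")
        if not np.all(np.isfinite(self.dv)):
            raise ValidationError(f"individual {self.id}: non-finite DV")

    @property
    def n_obs(self) -> int:
        return int(self.times.size)

    def group_rows(self, g: int) -> np.ndarray:
        return np.nonzero(self.out == g)[0]


@dataclass
class PopulationData:
    """A collection of individuals with unique ids."""

    individuals: list

    def __post_init__(self):
        if len(self.individuals) < 1:
            raise ValidationError("population must contain at least one individual")
        ids = [ind.id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate individual ids")

    @property
    def N(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)

    def __len__(self):
        return len(self.individuals)
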