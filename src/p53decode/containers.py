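"""Core in-memory containers shared across the pipeline.

All abundances are relative (TPM-like for mRNA, TMT reporter-intensity-like
for protein); time is in hours.  The experimental design being emulated is a
two-condition ("oscillatory" vs "rising" p53), two-replicate time course
sampled hourly from 0 to 9 h with one additional point at 24 h.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

OSCILLATORY = "oscillatory"
RISING = "rising"
CONDITIONS = (OSCILLATORY, RISING)

#: default sampling grid: hourly over the first 9 h, then 24 h
DEFAULT_TIMES: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 24.0)


@dataclass(frozen=True)
class TimeGrid:
    """An ordered set of sampling times (hours)."""

    times: tuple[float, ...] = DEFAULT_TIMES

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size == 0:
            raise ValueError("TimeGrid must contain at least one time point")
        if np.any(t < 0):
            raise ValueError("TimeGrid times must be non-negative")
        if t[0] != 0.0:
            raise ValueError("TimeGrid must start at t=0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("TimeGrid times must be strictly increasing")
        object.__setattr__(self, "times", tuple(float(x) for x in t))

    def __len__(self) -> int:
        return len(self.times)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of grid points inside the closed window [lo, hi]."""
        t = self.array
        return (t >= lo) & (t <= hi)

    def index_of(self, time: float) -> int:
        t = self.array
        idx = np.where(np.isclose(t, time))[0]
        if idx.size == 0:
            raise KeyError(f"time {time} not on grid")
        return int(idx[0])


@dataclass
class TimeCourse:
    """Relative levels of one species for one condition/replicate."""

    species: str
    condition: str
    replicate: int
    grid: TimeGrid
    levels: np.ndarray

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        if self.levels.ndim != 1 or self.levels.size != len(self.grid):
            raise ValueError(
                f"{self.species}: levels length {self.levels.size} does not match "
                f"grid length {len(self.grid)}"
            )
        if np.any(~np.isfinite(self.levels)):
            raise ValueError(f"{self.species}: non-finite levels")
        if np.any(self.levels < 0):
            raise ValueError(f"{self.species}: negative levels")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")

    @property
    def basal(self) -> float:
        return float(self.levels[0])

    def with_levels(self, levels: np.ndarray) -> "TimeCourse":
        return replace(self, levels=np.asarray(levels, dtype=float))


def mean_course(replicates: Iterable[TimeCourse]) -> TimeCourse:
    """Average replicate time courses into a single course (replicate id 0)."""
    reps = list(replicates)
    if not reps:
        raise ValueError("no replicates to average")
    grid = reps[0].grid
    for r in reps[1:]:
        if r.grid.times != grid.times:
            raise ValueError("replicates must share one grid")
    levels = np.mean([r.levels for r in reps], axis=0)
    return TimeCourse(reps[0].species, reps[0].condition, 0, grid, levels)


@dataclass
class GeneRecord:
    """Paired mRNA + protein time courses for one gene across conditions/replicates.

    ``mrna`` and ``protein`` map ``(condition, replicate)`` to a TimeCourse.
    ``mechanism``/``params`` carry the generator's ground truth when the record
    is synthetic.
    """

    gene_id: str
    mrna: dict[tuple[str, int], TimeCourse] = field(default_factory=dict)
    protein: dict[tuple[str, int], TimeCourse] = field(default_factory=dict)
    mechanism: str | None = None
    params: dict | None = None

    def courses(self, modality: str) -> Mapping[tuple[str, int], TimeCourse]:
        if modality == "mRNA":
            return self.mrna
        if modality == "protein":
            return self.protein
        raise ValueError(f"unknown modality {modality!r}")

    def replicates(self, modality: str, condition: str) -> list[TimeCourse]:
        store = self.courses(modality)
        reps = [tc for (cond, _), tc in sorted(store.items()) if cond == condition]
        return reps

    def replicate_mean(self, modality: str, condition: str) -> TimeCourse:
        return mean_course(self.replicates(modality, condition))

    @property
    def grid(self) -> TimeGrid:
        for store in (self.mrna, self.protein):
            for tc in store.values():
                return tc.grid
        raise ValueError(f"{self.gene_id}: empty record")


@dataclass
class KineticParams:
    """The five parameters of the production-degradation model.

    kp_mrna : mRNA production rate per hour per p53 relative unit
    kd_mrna : mRNA degradation fraction per hour, in [0, 1]
    kp_prot : protein production rate per hour per mRNA relative unit
    kd_prot : protein degradation fraction per hour, in [0, 1]
    tdel    : translational time delay in hours, >= 0
    """

    kp_mrna: float = 1.0
    kd_mrna: float = 0.5
    kp_prot: float = 1.0
    kd_prot: float = 0.5
    tdel: float = 0.0

    def __post_init__(self) -> None:
        for name in ("kd_mrna", "kd_prot"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1] (discrete-step stability)")
        for name in ("kp_mrna", "kp_prot"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tdel < 0:
            raise ValueError("tdel must be non-negative")


@dataclass
class FitResult:
    """Outcome of fitting the kinetic model to an observed trajectory."""

    params: KineticParams
    r2: float
    fitted: TimeCourse | None = None
    n_evals: int = 0
    flagged: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError(f"r2={self.r2} outside [0, 1]")
        self.r2 = float(min(self.r2, 1.0))
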