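"""Reading/writing time-course expression tables and elementary per-gene transforms.

Table dialect: delimited text (comma or tab, auto-detected), UTF-8, header
``gene_id,condition,replicate,<t0>,<t1>,...`` with time columns in hours
(decimal allowed), conditions spelled "oscillatory"/"rising", 1-based
replicate indices.  The writer emits the same dialect deterministically
(rows sorted by key).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CONDITIONS, GeneRecord, TimeCourse, TimeGrid, mean_course

log = logging.getLogger(__name__)

MODALITIES = ("mRNA", "protein")
MAX_FC_WINDOW = (1.0, 9.0)  # "largest FC value from 1 to 9 h"
ZSCORE_WINDOW = (0.0, 9.0)  # clustering analyses the first 9 h only


@dataclass
class ExpressionTable:
    """A collection of TimeCourse records sharing one grid, for one modality."""

    modality: str
    records: dict[tuple[str, str, int], TimeCourse] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        grids = {tc.grid.times for tc in self.records.values()}
        if len(grids) > 1:
            raise ValueError("all records must share one TimeGrid")

    @property
    def grid(self) -> TimeGrid:
        for tc in self.records.values():
            return tc.grid
        raise ValueError("empty table")

    @property
    def species(self) -> list[str]:
        return sorted({key[0] for key in self.records})

    def add(self, tc: TimeCourse) -> None:
        key = (tc.species, tc.condition, tc.replicate)
        if key in self.records:
            raise ValueError(f"duplicate key {key}")
        if self.records and tc.grid.times != self.grid.times:
            raise ValueError("grid mismatch")
        self.records[key] = tc

    def replicates(self, species: str, condition: str) -> list[TimeCourse]:
        return [tc for (s, c, _), tc in sorted(self.records.items())
                if s == species and c == condition]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (species, condition, rep) in sorted(self.records):
            tc = self.records[(species, condition, rep)]
            row: dict = {"gene_id": species, "condition": condition, "replicate": rep}
            for t, level in zip(tc.grid.times, tc.levels):
                row[_fmt_time(t)] = level
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, path: str | Path, sep: str = ",") -> None:
        self.to_dataframe().to_csv(path, sep=sep, index=False)


def _fmt_time(t: float) -> str:
    return str(int(t)) if float(t).is_integer() else str(t)


def read_table(path: str | Path, modality: str) -> ExpressionTable:
    """Parse a delimited time-course table; the grid is inferred from headers."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = ["gene_id", "condition", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    time_cols = [c for c in df.columns if c not in required]
    try:
        times = [float(c) for c in time_cols]
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric time column header: {exc}") from None
    order = np.argsort(times)
    time_cols = [time_cols[i] for i in order]
    grid = TimeGrid(tuple(times[i] for i in order))

    table = ExpressionTable(modality=modality)
    for idx, row in df.iterrows():
        condition = str(row["condition"])
        if condition not in CONDITIONS:
            raise ValueError(f"{path} row {idx}: unknown condition {condition!r}")
        levels = row[time_cols].to_numpy(dtype=float)
        if np.any(~np.isfinite(levels)):
            raise ValueError(f"{path} row {idx} ({row['gene_id']}): non-numeric level")
        if np.any(levels < 0):
            raise ValueError(f"{path} row {idx} ({row['gene_id']}): negative level")
        tc = TimeCourse(str(row["gene_id"]), condition, int(row["replicate"]), grid, levels)
        key = (tc.species, tc.condition, tc.replicate)
        if key in table.records:
            raise ValueError(f"{path} row {idx}: duplicate key {key}")
        table.records[key] = tc
    return table


def table_to_records(
    mrna: ExpressionTable,
    protein: ExpressionTable,
    truth: pd.DataFrame | None = None,
) -> list[GeneRecord]:
    """Join mRNA and protein tables into GeneRecords (genes present in both)."""
    genes = sorted(set(mrna.species) & set(protein.species))
    dropped = (set(mrna.species) | set(protein.species)) - set(genes)
    if dropped:
        log.info("dropping %d species missing one modality", len(dropped))
    truth_map = {}
    if truth is not None:
        truth_map = {str(r["gene_id"]): r for _, r in truth.iterrows()}
    out = []
    for g in genes:
        rec = GeneRecord(gene_id=g)
        for (s, c, r), tc in mrna.records.items():
            if s == g:
                rec.mrna[(c, r)] = tc
        for (s, c, r), tc in protein.records.items():
            if s == g:
                rec.protein[(c, r)] = tc
        if g in truth_map:
            rec.mechanism = str(truth_map[g].get("mechanism"))
        out.append(rec)
    return out


@dataclass
class FoldChangeSeries:
    """Per-time-point fold change relative to basal (t=0) expression."""

    species: str
    condition: str
    grid: TimeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isclose(self.values[0], 1.0):
            raise ValueError("fold change at t=0 must equal 1")
        if np.any(self.values <= 0):
            raise ValueError("fold changes must be positive")


def fold_change(course: TimeCourse | list[TimeCourse]) -> FoldChangeSeries:
    """Fold change relative to t=0, computed on the replicate mean."""
    tc = mean_course(course) if isinstance(course, list) else course
    if tc.basal <= 0:
        raise ValueError(f"{tc.species}: zero basal level, fold change undefined")
    return FoldChangeSeries(tc.species, tc.condition, tc.grid, tc.levels / tc.basal)


def max_fold_change(fc: FoldChangeSeries, window: tuple[float, float] = MAX_FC_WINDOW) -> float:
    """Maximum fold change over grid points inside the closed window."""
    mask = fc.grid.window_mask(*window)
    if not mask.any():
        raise ValueError(f"no grid points in window {window}")
    return float(fc.values[mask].max())


def min_fold_change(fc: FoldChangeSeries, window: tuple[float, float] = MAX_FC_WINDOW) -> float:
    mask = fc.grid.window_mask(*window)
    if not mask.any():
        raise ValueError(f"no grid points in window {window}")
    return float(fc.values[mask].min())


def zscore(
    course: TimeCourse | np.ndarray,
    grid: TimeGrid | None = None,
    window: tuple[float, float] = ZSCORE_WINDOW,
) -> np.ndarray:
    """z-score a trace over the window (sample sd, ddof=1).

    Constant traces have no scale and return zeros (flagged via a log entry)
    rather than raising, since flat species are an analysis outcome.
    """
    if isinstance(course, TimeCourse):
        levels, grid = course.levels, course.grid
    else:
        levels = np.asarray(course, dtype=float)
        if grid is None:
            raise ValueError("grid required when passing a raw array")
    mask = grid.window_mask(*window)
    x = levels[mask]
    if x.size < 2:
        raise ValueError("need at least two points to z-score")
    sd = np.std(x, ddof=1)
    if sd < 1e-12:
        log.warning("constant trace, z-score set to zeros")
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def replicate_correlation(rep1: TimeCourse, rep2: TimeCourse) -> float:
    """Pearson correlation between two biological replicates of one species."""
    if rep1.grid.times != rep2.grid.times:
        raise ValueError("replicates must share one grid")
    if np.std(rep1.levels) < 1e-12 or np.std(rep2.levels) < 1e-12:
        raise ValueError("zero variance in a replicate, correlation undefined")
    r, _ = stats.pearsonr(rep1.levels, rep2.levels)
    return float(r)
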