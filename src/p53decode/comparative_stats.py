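"""Between-condition area statistics and the functional-class comparison.

``diff`` quantifies how much lower the basal-normalized protein trajectory is
under oscillatory ("pulsed") p53 than under rising ("sustained") p53, summed
over the 3-9 h grid points::

    diff       = sum_{t=3..9}  1 - [prot(t)/prot(0)]_osc / [prot(t)/prot(0)]_rise
    diff_early = sum_{t=0..3}  (same summand)

Both windows are inclusive at both ends, so the t=3 h term appears in each,
as the definitions are printed.  The t=0 term of diff_early is identically
zero (both normalized trajectories equal 1 there).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import OSCILLATORY, RISING, GeneRecord
from .expression_io import fold_change

DIFF_WINDOW = (3.0, 9.0)
DIFF_EARLY_WINDOW = (0.0, 3.0)
_WINDOWS = {"late": DIFF_WINDOW, "early": DIFF_EARLY_WINDOW}


def diff_score(
    osc_norm,
    rise_norm,
    window: str | tuple[float, float] = "late",
) -> float:
    """Summed pointwise relative difference between normalized trajectories.

    Both inputs are FoldChangeSeries (or objects with .grid/.values) already
    normalized to their t=0 value.
    """
    win = _WINDOWS[window] if isinstance(window, str) else window
    if osc_norm.grid.times != rise_norm.grid.times:
        raise ValueError("trajectories must share one grid")
    mask = osc_norm.grid.window_mask(*win)
    if not mask.any():
        raise ValueError(f"no grid points in window {win}")
    osc = np.asarray(osc_norm.values, float)[mask]
    rise = np.asarray(rise_norm.values, float)[mask]
    if np.any(rise <= 0):
        raise ValueError("zero rising normalized level inside the window")
    return float(np.sum(1.0 - osc / rise))


@dataclass
class DiffStats:
    species: str
    diff: float
    diff_early: float


def diff_stats(record: GeneRecord, modality: str = "protein") -> DiffStats:
    """diff and diff_early for one gene, on replicate-mean normalized traces."""
    fc_osc = fold_change(record.replicates(modality, OSCILLATORY))
    fc_rise = fold_change(record.replicates(modality, RISING))
    return DiffStats(
        species=record.gene_id,
        diff=diff_score(fc_osc, fc_rise, "late"),
        diff_early=diff_score(fc_osc, fc_rise, "early"),
    )


def rank_by_diff(diffs: dict[str, float]) -> list[str]:
    """Stable descending ordering by diff, ties broken by gene identifier."""
    return [g for g, _ in sorted(diffs.items(), key=lambda kv: (-kv[1], kv[0]))]


def read_annotation(path: str | Path) -> dict[str, str]:
    """Two-column delimited gene -> functional-class table."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError(f"{path}: annotation needs gene_id and class columns")
    return {str(r[cols[0]]): str(r[cols[1]]) for _, r in df.iterrows()}


@dataclass
class ClassComparison:
    condition: str
    n_class: int
    n_other: int
    mean_class: float
    mean_other: float
    t_statistic: float
    p_value: float


def class_comparison(
    fc_at_24h: dict[str, float],
    annotation: dict[str, str],
    condition: str,
    target_class: str = "antiproliferative",
) -> ClassComparison:
    """Two-sided two-sample t-test of 24 h fold changes between gene classes."""
    in_class, other = [], []
    for gene, fc in fc_at_24h.items():
        (in_class if annotation.get(gene) == target_class else other).append(fc)
    if len(in_class) < 2 or len(other) < 2:
        raise ValueError("each class needs at least two genes for the t-test")
    a, b = np.asarray(in_class), np.asarray(other)
    if np.std(a) < 1e-15 and np.std(b) < 1e-15 and np.isclose(a.mean(), b.mean()):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b)
    return ClassComparison(condition, len(in_class), len(other),
                           float(a.mean()), float(b.mean()), float(t), float(p))
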