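"""Selection of differentially expressed mRNAs and proteins.

A species is *detected* when it is measured at every time point; it is
*induced* when, at one or more time points in the 1-9 h window, it clears all
of: fold change above the modality threshold (1.5 for mRNA, 1.15 for
protein), BH-adjusted t-test FDR below the threshold, replicate Pearson
correlation above the threshold, and - for proteins only - the early
between-condition area diff_early below 1.  *Repressed* mirrors the fold
change criterion (FC < 1/threshold).

Two published protein threshold pairs exist; the stricter pair
(FDR 0.05, PCC 0.7) is the default and the looser one (0.2, 0.5) is
available as ``PROTEIN_FIG2_CRITERIA``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import OSCILLATORY, RISING, GeneRecord
from .comparative_stats import diff_stats
from .expression_io import (MAX_FC_WINDOW, fold_change, max_fold_change,
                            min_fold_change, replicate_correlation)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DECriteria:
    fc_threshold: float = 1.5
    fdr_threshold: float = 0.2
    pcc_threshold: float = 0.5
    diff_early_max: float | None = None  # protein-only filter
    fc_window: tuple[float, float] = MAX_FC_WINDOW

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must exceed 1")
        if not 0 < self.fdr_threshold <= 1:
            raise ValueError("fdr_threshold must be in (0, 1]")
        if not -1 <= self.pcc_threshold <= 1:
            raise ValueError("pcc_threshold must be a correlation")


MRNA_CRITERIA = DECriteria(fc_threshold=1.5, fdr_threshold=0.2, pcc_threshold=0.5)
PROTEIN_CRITERIA = DECriteria(fc_threshold=1.15, fdr_threshold=0.05,
                              pcc_threshold=0.7, diff_early_max=1.0)
PROTEIN_FIG2_CRITERIA = DECriteria(fc_threshold=1.15, fdr_threshold=0.2,
                                   pcc_threshold=0.5, diff_early_max=1.0)


def default_criteria(modality: str, preset: str = "paper-defaults") -> DECriteria:
    if modality == "mRNA":
        return MRNA_CRITERIA
    if modality == "protein":
        return PROTEIN_FIG2_CRITERIA if preset == "fig2-protein-thresholds" else PROTEIN_CRITERIA
    raise ValueError(f"unknown modality {modality!r}")


def ttest_vs_basal(levels_at_t: Sequence[float], levels_at_0: Sequence[float]) -> float:
    """Two-sided two-sample t-test p-value of replicate levels at t vs t=0.

    Groups with zero pooled variance (including identical groups) return
    p = 1.0 - a conservative treatment for the n=2 design - rather than nan.
    """
    a = np.asarray(levels_at_t, float)
    b = np.asarray(levels_at_0, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 replicates per group")
    if np.var(a) + np.var(b) < 1e-24:
        return 1.0
    t, p = stats.ttest_ind(a, b)
    return float(p) if np.isfinite(p) else 1.0


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


@dataclass
class DEResult:
    species: str
    condition: str
    modality: str
    pvalues: np.ndarray
    qvalues: np.ndarray
    max_fc: float
    min_fc: float
    pcc: float
    diff_early: float | None
    status: str  # induced | repressed | unchanged
    detected: bool = True

    @property
    def min_q(self) -> float:
        return float(np.min(self.qvalues)) if self.qvalues.size else 1.0


def _gene_pvalues(record: GeneRecord, condition: str, modality: str) -> np.ndarray:
    reps = record.replicates(modality, condition)
    grid = reps[0].grid
    basal = [tc.levels[0] for tc in reps]
    return np.array([
        ttest_vs_basal([tc.levels[i] for tc in reps], basal)
        for i in range(1, len(grid))
    ])


def classify_de(
    record: GeneRecord,
    condition: str,
    criteria: DECriteria,
    modality: str,
    qvalues: np.ndarray | None = None,
) -> DEResult:
    """Classify one gene as induced / repressed / unchanged under one condition.

    ``qvalues`` may be supplied when BH was applied across a whole cohort
    (the default family in :func:`select_de`); otherwise BH is applied across
    this gene's own time points.
    """
    reps = record.replicates(modality, condition)
    if len(reps) < 2:
        raise ValueError(f"{record.gene_id}: need two replicates")
    pvalues = _gene_pvalues(record, condition, modality)
    if qvalues is None:
        qvalues = bh_adjust(pvalues)
    fc = fold_change(reps)
    mx = max_fold_change(fc, criteria.fc_window)
    mn = min_fold_change(fc, criteria.fc_window)
    try:
        pcc = replicate_correlation(reps[0], reps[1])
    except ValueError:
        # a perfectly flat replicate carries no reproducibility evidence
        pcc = float("nan")
    de = None
    if criteria.diff_early_max is not None:
        de = diff_stats(record, modality).diff_early

    sig = (float(np.min(qvalues)) < criteria.fdr_threshold) and (pcc > criteria.pcc_threshold)
    early_ok = de is None or de < criteria.diff_early_max
    if sig and early_ok and mx > criteria.fc_threshold:
        status = "induced"
    elif sig and mn < 1.0 / criteria.fc_threshold:
        status = "repressed"
    else:
        status = "unchanged"
    return DEResult(record.gene_id, condition, modality, pvalues, qvalues,
                    mx, mn, pcc, de, status)


def select_de(
    cohort: Iterable[GeneRecord],
    condition: str,
    criteria: DECriteria,
    modality: str,
    family: str = "pooled",
) -> tuple[set[str], dict[str, int], dict[str, DEResult]]:
    """Run DE classification over a cohort.

    family="pooled" (default) applies BH across all gene x time-point tests
    within the modality/condition; family="per-gene" corrects each gene's
    time points separately.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    results: dict[str, DEResult] = {}
    if family == "pooled":
        pmat = np.array([_gene_pvalues(r, condition, modality) for r in cohort])
        qmat = bh_adjust(pmat.ravel()).reshape(pmat.shape)
        for rec, q in zip(cohort, qmat):
            results[rec.gene_id] = classify_de(rec, condition, criteria, modality, qvalues=q)
    elif family == "per-gene":
        for rec in cohort:
            results[rec.gene_id] = classify_de(rec, condition, criteria, modality)
    else:
        raise ValueError(f"unknown BH family {family!r}")
    induced = {g for g, r in results.items() if r.status == "induced"}
    counts = {
        "induced": len(induced),
        "repressed": sum(r.status == "repressed" for r in results.values()),
        "unchanged": sum(r.status == "unchanged" for r in results.values()),
    }
    log.info("%s/%s DE: %s", modality, condition, counts)
    return induced, counts, results
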