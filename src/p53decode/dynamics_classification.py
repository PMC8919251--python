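"""Assign each gene an (mRNA class, protein class) pair, a category letter,
and the decoding-mechanism annotation implied by that category.

mRNA classes (4): osc_induced_both, nonosc_induced_both, rising_only,
osc_only.  Protein classes (6): oscillatory, rise_both, rise_and_decrease,
rising_only, osc_only, not_induced.  The (4 x 6) lookup to letters a-k ships
as a versioned JSON data file; cells never produced without extra feedback
independent of the p53 input map to "unobserved*".  The whole not_induced
column is one category (k), so 10 lettered cells + k = 11 categories.

Classification rules (the published grouping is defined only by example, so
the cutoffs here are explicit operationalizations):

* a trace is *oscillatory* when its maximum lagged correlation (lags 0-3 h)
  with the oscillatory p53 reference is >= 0.7 AND, after its first peak, it
  rebounds from the intervening trough by at least 1.1 z-score units within
  0-9 h (low-turnover targets low-pass the pulses into a single hump and
  fail the rebound requirement even though they lag-correlate well);
* a protein induced under both conditions shows *rise_and_decrease* when, on
  the oscillatory-condition fold-change trace, the level at 9 h has given
  back at least half of the peak excess over basal (the drop is measured
  relative to the induction amplitude, not in z units, so weakly induced
  slow risers are not mistaken for declining profiles);
* otherwise it is *rise_both*.

Mechanism annotation is category-driven (simple regulation for a/b/e,
activation thresholds for c/f/g/i/k, coherent FFLs for d/j, incoherent FFL
for h); it is an annotation with the evidence fields used, not causal proof.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .containers import OSCILLATORY, RISING, GeneRecord, TimeCourse, FitResult
from .differential_expression import DEResult
from .expression_io import zscore
from .kinetic_model import count_interior_maxima, lagged_correlation

log = logging.getLogger(__name__)

OSC_SCORE_CUTOFF = 0.7
OSC_REBOUND_MIN = 1.1  # z units, trough-to-rebound after the first peak
RISE_DECREASE_FRACTION = 0.5  # fraction of the peak excess given back by 9 h

MRNA_CLASSES = ("osc_induced_both", "nonosc_induced_both", "rising_only", "osc_only")
PROT_CLASSES = ("oscillatory", "rise_both", "rise_and_decrease",
                "rising_only", "osc_only", "not_induced")


def _load_table() -> dict:
    with resources.files("p53decode.data").joinpath("category_table.json").open() as fh:
        return json.load(fh)


_TABLE = _load_table()
CATEGORY_TABLE: dict[tuple[str, str], str] = {
    (m, p): _TABLE["table"][m][p] for m in MRNA_CLASSES for p in PROT_CLASSES
}
MECHANISM_BY_CATEGORY: dict[str, str] = _TABLE["mechanism_by_category"]

#: collapse the annotation vocabulary onto the generator's mechanism labels
MECHANISM_FAMILY = {
    "simple_regulation": "simple",
    "activation_threshold_low": "threshold",
    "activation_threshold_medium": "threshold",
    "activation_threshold_high": "threshold",
    "cffl_transcriptional": "cffl_transcriptional",
    "cffl_posttranscriptional": "cffl_posttranscriptional",
    "iffl": "iffl",
    "undetermined": "undetermined",
}


@dataclass
class DynCategory:
    letter: str
    mechanism: str

    @property
    def starred(self) -> bool:
        return self.letter == "unobserved*"


def oscillation_score(
    tc: TimeCourse,
    reference_p53: TimeCourse,
    window: tuple[float, float] = (0.0, 9.0),
) -> tuple[float, int]:
    """Oscillation score of a trace against the oscillatory p53 reference.

    Returns the maximum lagged Pearson correlation (lags 0-3 h on the hourly
    window grid) between the z-scored trace and reference, and the count of
    interior local maxima of the trace inside the window.  Constant traces
    score 0.
    """
    mask = tc.grid.window_mask(*window)
    x = tc.levels[mask]
    ref_mask = reference_p53.grid.window_mask(*window)
    ref = reference_p53.levels[ref_mask]
    peaks = count_interior_maxima(x)
    if np.std(x) < 1e-12:
        return 0.0, peaks
    score = lagged_correlation(x, ref, max_lag_steps=3)
    return float(np.clip(score, -1.0, 1.0)), peaks


def post_peak_rebound(z: np.ndarray) -> float:
    """Trough-to-rebound amplitude after the first (global) peak, in z units.

    The second pulse of a target lagging the p53 input may enter right at the
    window edge, so the rebound is measured to the window end rather than
    requiring an interior second maximum.
    """
    z = np.asarray(z, float)
    i_pk = int(np.argmax(z))
    if i_pk >= z.size - 1:
        return 0.0
    after = z[i_pk:]
    i_tr = int(np.argmin(after))
    return float(after[i_tr:].max() - after[i_tr])


def _is_oscillatory(tc: TimeCourse, reference: TimeCourse) -> bool:
    score, _ = oscillation_score(tc, reference)
    if score < OSC_SCORE_CUTOFF:
        return False
    z = zscore(tc)  # 0-9 h window
    return post_peak_rebound(z) >= OSC_REBOUND_MIN


def _rise_and_decrease(tc: TimeCourse) -> bool:
    mask = tc.grid.window_mask(0.0, 9.0)
    fc = tc.levels[mask] / tc.levels[0]
    peak = float(fc.max())
    if peak <= 1.0 or int(np.argmax(fc)) == fc.size - 1:
        return False
    return bool((peak - fc[-1]) / (peak - 1.0) >= RISE_DECREASE_FRACTION)


def classify_gene(
    record: GeneRecord,
    de_mrna: dict[str, DEResult],
    de_prot: dict[str, DEResult],
    p53_reference: TimeCourse,
) -> tuple[str, str] | None:
    """Deterministic (mRNA class, protein class) rule table for one gene.

    ``de_mrna``/``de_prot`` map condition -> DEResult for this gene.  Genes
    whose mRNA is induced under neither condition are outside the category
    table and return None (with a log entry).
    """
    m_osc = de_mrna[OSCILLATORY].status == "induced"
    m_rise = de_mrna[RISING].status == "induced"
    if not (m_osc or m_rise):
        log.info("%s: mRNA induced under neither condition, excluded", record.gene_id)
        return None
    mrna_osc_trace = record.replicate_mean("mRNA", OSCILLATORY)
    if m_osc and m_rise:
        mrna_class = ("osc_induced_both" if _is_oscillatory(mrna_osc_trace, p53_reference)
                      else "nonosc_induced_both")
    elif m_rise:
        mrna_class = "rising_only"
    else:
        mrna_class = "osc_only"

    p_osc = de_prot[OSCILLATORY].status == "induced"
    p_rise = de_prot[RISING].status == "induced"
    if not (p_osc or p_rise):
        prot_class = "not_induced"
    elif p_osc and not p_rise:
        prot_class = "osc_only"
    elif p_rise and not p_osc:
        prot_class = "rising_only"
    else:
        prot_osc_trace = record.replicate_mean("protein", OSCILLATORY)
        if _is_oscillatory(prot_osc_trace, p53_reference):
            prot_class = "oscillatory"
        elif _rise_and_decrease(prot_osc_trace):
            prot_class = "rise_and_decrease"
        else:
            prot_class = "rise_both"
    return mrna_class, prot_class


def assign_category(mrna_class: str, prot_class: str,
                    fits: dict[str, FitResult] | None = None,
                    prediction_r2: float | None = None) -> DynCategory:
    """Total lookup from the class pair to the category letter + mechanism."""
    if mrna_class not in MRNA_CLASSES:
        raise ValueError(f"unknown mRNA class {mrna_class!r}")
    if prot_class not in PROT_CLASSES:
        raise ValueError(f"unknown protein class {prot_class!r}")
    letter = CATEGORY_TABLE[(mrna_class, prot_class)]
    return DynCategory(letter, infer_mechanism(letter, fits, prediction_r2))


def infer_mechanism(
    letter: str,
    fits: dict[str, FitResult] | None = None,
    prediction_r2: float | None = None,
) -> str:
    """Rule-based decoding-mechanism annotation for a category letter.

    When fit results are available they refine the call: a category-a/b/e gene
    whose protein fit failed outright is reported undetermined rather than
    simple regulation.
    """
    mech = MECHANISM_BY_CATEGORY.get(letter, "undetermined")
    if mech == "simple_regulation" and fits is not None:
        prot_fit = fits.get("protein")
        if prot_fit is None or (prot_fit.flagged and prot_fit.r2 < 0.25):
            return "undetermined"
    return mech


@dataclass
class ExclusivitySummary:
    per_gene: dict[str, str]            # gene -> none | osc_only | rising_only
    fraction: float                     # exclusively induced / eligible denominator
    n_exclusive: int
    n_eligible: int


def exclusive_induction(
    de_by_condition: dict[str, dict[str, DEResult]],
    eligible: set[str] | None = None,
) -> ExclusivitySummary:
    """Per-gene exclusive-induction labels and the cohort fraction.

    ``de_by_condition`` maps condition -> {gene -> DEResult} for one modality.
    The denominator is ``eligible`` when given (e.g. the detected-under-both,
    induced-at-least-once set for mRNA), otherwise all genes induced under at
    least one condition.
    """
    genes = sorted(set(de_by_condition[OSCILLATORY]) & set(de_by_condition[RISING]))
    per_gene: dict[str, str] = {}
    for g in genes:
        osc = de_by_condition[OSCILLATORY][g].status == "induced"
        rise = de_by_condition[RISING][g].status == "induced"
        if osc and not rise:
            per_gene[g] = "osc_only"
        elif rise and not osc:
            per_gene[g] = "rising_only"
        else:
            per_gene[g] = "none"
    if eligible is None:
        eligible = {g for g in genes
                    if de_by_condition[OSCILLATORY][g].status == "induced"
                    or de_by_condition[RISING][g].status == "induced"}
    n_excl = sum(1 for g in eligible if per_gene.get(g, "none") != "none")
    frac = n_excl / len(eligible) if eligible else 0.0
    return ExclusivitySummary(per_gene, frac, n_excl, len(eligible))
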