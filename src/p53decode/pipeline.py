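"""End-to-end orchestration: simulate/load -> filter -> cluster -> fit ->
predict -> classify -> compare.

Every stage writes one delimited table into the output directory, and a
manifest (config hash, seed, per-stage counts) records the run.  Rerunning
with the same config and seed reproduces identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import assign_clusters, fuzzy_cmeans, select_induced_clusters
from .comparative_stats import class_comparison, diff_stats, rank_by_diff, read_annotation
from .config import PipelineConfig
from .containers import CONDITIONS, OSCILLATORY, RISING, GeneRecord, TimeGrid
from .differential_expression import select_de
from .dynamics_classification import (assign_category, classify_gene,
                                      exclusive_induction, oscillation_score)
from .expression_io import fold_change, read_table, table_to_records, zscore
from .kinetic_model import fit_mrna, fit_protein, predict_protein, sample_at
from .synthetic import (OSC_P53_SPEC, RISING_P53_SPEC, gen_annotation,
                        gen_cohort, hourly_p53, write_cohort)

log = logging.getLogger(__name__)

STAGES = ("simulate", "filter", "cluster", "fit", "predict", "classify", "compare")


@dataclass
class PipelineState:
    config: PipelineConfig
    cohort: list[GeneRecord] = field(default_factory=list)
    p53_reference: object = None
    de: dict = field(default_factory=dict)            # (modality, condition) -> results
    induced: dict = field(default_factory=dict)       # (modality, condition) -> set
    clusters: dict = field(default_factory=dict)
    fits: dict = field(default_factory=dict)          # gene -> {"mrna":, "protein":}
    predictions: dict = field(default_factory=dict)   # gene -> r2
    categories: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)

    @property
    def outdir(self) -> Path:
        return Path(self.config.outdir)


def stage_simulate(state: PipelineState) -> None:
    cfg = state.config
    if cfg.mrna_table is not None:
        mrna = read_table(cfg.mrna_table, "mRNA")
        protein = read_table(cfg.protein_table, "protein")
        state.cohort = table_to_records(mrna, protein)
    else:
        state.cohort = gen_cohort(cfg.synthetic.n_genes,
                                  cfg.synthetic.mechanism_mix,
                                  seed=cfg.seed, cv=cfg.synthetic.cv,
                                  n_replicates=cfg.synthetic.n_replicates)
        write_cohort(state.cohort, state.outdir)
    if not state.cohort:
        raise ValueError("no genes to analyze")
    grid = state.cohort[0].grid
    state.p53_reference = sample_at(hourly_p53(OSC_P53_SPEC), grid)
    state.counts["simulate"] = {"n_genes": len(state.cohort)}


def stage_filter(state: PipelineState) -> None:
    cfg = state.config
    rows = []
    for modality, criteria in (("mRNA", cfg.de_mrna), ("protein", cfg.de_protein)):
        for condition in CONDITIONS:
            induced, counts, results = select_de(state.cohort, condition,
                                                 criteria, modality)
            state.de[(modality, condition)] = results
            state.induced[(modality, condition)] = induced
            state.counts.setdefault("filter", {})[f"{modality}_{condition}"] = counts
            for g, r in sorted(results.items()):
                rows.append({"gene_id": g, "condition": condition, "modality": modality,
                             "max_fc": r.max_fc, "min_q": r.min_q, "pcc": r.pcc,
                             "diff_early": r.diff_early, "status": r.status})
    pd.DataFrame(rows).to_csv(state.outdir / "de_summary.csv", index=False)


def stage_cluster(state: PipelineState) -> None:
    cfg = state.config
    rows = []
    protein_pool: dict[str, set] = {}
    for condition in CONDITIONS:
        genes = sorted(state.induced[("mRNA", condition)])
        if len(genes) >= cfg.cluster_mrna.n_clusters:
            by_id = {r.gene_id: r for r in state.cohort}
            Z = np.vstack([zscore(by_id[g].replicate_mean("mRNA", condition))
                           for g in genes])
            res = fuzzy_cmeans(Z, cfg.cluster_mrna)
            assigns = assign_clusters(genes, res)
            induced_set = select_induced_clusters(assigns)
            state.clusters[("mRNA", condition)] = assigns
            for a in assigns:
                rows.append({"gene_id": a.species, "condition": condition,
                             "modality": "mRNA", "cluster": a.cluster,
                             "membership_max": float(a.memberships.max()),
                             "direction": a.direction})
        else:
            induced_set = set(genes)
            log.warning("too few induced mRNAs under %s to cluster", condition)
        protein_pool[condition] = induced_set
        # proteins corresponding to induced-cluster mRNAs are clustered in turn
        prots = sorted(protein_pool[condition] & state.induced[("protein", condition)])
        if len(prots) >= cfg.cluster_protein.n_clusters:
            by_id = {r.gene_id: r for r in state.cohort}
            Z = np.vstack([zscore(by_id[g].replicate_mean("protein", condition))
                           for g in prots])
            res = fuzzy_cmeans(Z, cfg.cluster_protein)
            assigns = assign_clusters(prots, res)
            state.clusters[("protein", condition)] = assigns
            for a in assigns:
                rows.append({"gene_id": a.species, "condition": condition,
                             "modality": "protein", "cluster": a.cluster,
                             "membership_max": float(a.memberships.max()),
                             "direction": a.direction})
        state.counts.setdefault("cluster", {})[condition] = {
            "mrna_in_induced_clusters": len(induced_set),
            "proteins_clustered": len(prots),
        }
    pd.DataFrame(rows).to_csv(state.outdir / "clusters.csv", index=False)


def stage_fit(state: PipelineState) -> None:
    cfg = state.config
    fit_genes = sorted(state.induced[("mRNA", OSCILLATORY)])
    by_id = {r.gene_id: r for r in state.cohort}
    rows = []
    for g in fit_genes:
        rec = by_id[g]
        m_obs = rec.replicate_mean("mRNA", OSCILLATORY)
        p_obs = rec.replicate_mean("protein", OSCILLATORY)
        fm = fit_mrna(state.p53_reference, m_obs, window=cfg.fit.window)
        fp = fit_protein(m_obs, p_obs, tdel_max=cfg.fit.tdel_max, window=cfg.fit.window)
        state.fits[g] = {"mrna": fm, "protein": fp}
        rows.append({"gene_id": g, "kp_mrna": fm.params.kp_mrna,
                     "kd_mrna": fm.params.kd_mrna, "kp_prot": fp.params.kp_prot,
                     "kd_prot": fp.params.kd_prot, "tdel": fp.params.tdel,
                     "r2_mrna": fm.r2, "r2_prot": fp.r2})
    state.counts["fit"] = {"n_fitted": len(rows)}
    state._fit_rows = rows  # completed by stage_predict
    pd.DataFrame(rows).to_csv(state.outdir / "fits.csv", index=False)


def stage_predict(state: PipelineState) -> None:
    cfg = state.config
    by_id = {r.gene_id: r for r in state.cohort}
    rows = []
    for g, fits in sorted(state.fits.items()):
        rec = by_id[g]
        m_rise = rec.replicate_mean("mRNA", RISING)
        p_rise = rec.replicate_mean("protein", RISING)
        _, r2 = predict_protein(fits["protein"].params, m_rise, p_rise,
                                window=cfg.fit.window)
        state.predictions[g] = r2
        rows.append({"gene_id": g, "r2_pred": r2})
    state.counts["predict"] = {"n_predicted": len(rows)}
    pd.DataFrame(rows).to_csv(state.outdir / "predictions.csv", index=False)


def stage_classify(state: PipelineState) -> None:
    by_id = {r.gene_id: r for r in state.cohort}
    rows = []
    letters: dict[str, int] = {}
    for g in sorted(by_id):
        rec = by_id[g]
        de_m = {c: state.de[("mRNA", c)][g] for c in CONDITIONS}
        de_p = {c: state.de[("protein", c)][g] for c in CONDITIONS}
        cls = classify_gene(rec, de_m, de_p, state.p53_reference)
        if cls is None:
            continue
        cat = assign_category(*cls, fits=state.fits.get(g),
                              prediction_r2=state.predictions.get(g))
        score, peaks = oscillation_score(rec.replicate_mean("mRNA", OSCILLATORY),
                                         state.p53_reference)
        letters[cat.letter] = letters.get(cat.letter, 0) + 1
        rows.append({"gene_id": g, "mrna_class": cls[0], "prot_class": cls[1],
                     "letter": cat.letter, "mechanism": cat.mechanism,
                     "osc_score_mrna": score, "osc_peaks_mrna": peaks,
                     "true_mechanism": rec.mechanism})
        state.categories[g] = cat
    excl_m = exclusive_induction({c: state.de[("mRNA", c)] for c in CONDITIONS})
    excl_p = exclusive_induction(
        {c: state.de[("protein", c)] for c in CONDITIONS},
        eligible={g for c in CONDITIONS for g in state.induced[("protein", c)]})
    state.counts["classify"] = {
        "letters": letters,
        "exclusive_mrna_fraction": excl_m.fraction,
        "exclusive_protein_fraction": excl_p.fraction,
    }
    pd.DataFrame(rows).to_csv(state.outdir / "categories.csv", index=False)


def stage_compare(state: PipelineState) -> None:
    cfg = state.config
    by_id = {r.gene_id: r for r in state.cohort}
    diffs = {}
    fc24 = {c: {} for c in CONDITIONS}
    rows = []
    for g in sorted(by_id):
        rec = by_id[g]
        try:
            d = diff_stats(rec)
        except ValueError:
            continue
        diffs[g] = d.diff
        rows.append({"gene_id": g, "diff": d.diff, "diff_early": d.diff_early})
        for c in CONDITIONS:
            fc = fold_change(rec.replicates("protein", c))
            if 24.0 in fc.grid.times:
                fc24[c][g] = float(fc.values[fc.grid.index_of(24.0)])
    order = rank_by_diff(diffs)
    df = pd.DataFrame(rows).set_index("gene_id").loc[order].reset_index()
    df.to_csv(state.outdir / "diff_stats.csv", index=False)

    if cfg.annotation_table is not None:
        annotation = read_annotation(cfg.annotation_table)
    else:
        annotation = gen_annotation(state.cohort, seed=cfg.seed)
    comp_rows = []
    for c in CONDITIONS:
        try:
            comp = class_comparison(fc24[c], annotation, c)
        except ValueError as exc:
            log.warning("class comparison skipped under %s: %s", c, exc)
            continue
        comp_rows.append(vars(comp))
    pd.DataFrame(comp_rows).to_csv(state.outdir / "class_comparison.csv", index=False)
    state.counts["compare"] = {"n_diff": len(diffs),
                               "n_class_tests": len(comp_rows)}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "filter": stage_filter,
    "cluster": stage_cluster,
    "fit": stage_fit,
    "predict": stage_predict,
    "classify": stage_classify,
    "compare": stage_compare,
}


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] = STAGES) -> PipelineState:
    """Execute the pipeline stages in order and write the run manifest."""
    state = PipelineState(config=config)
    state.outdir.mkdir(parents=True, exist_ok=True)
    for name in stages:
        try:
            _STAGE_FUNCS[name](state)
        except Exception:
            log.error("stage %r failed", name)
            raise
        log.info("stage %s done: %s", name, state.counts.get(name, {}))
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "config": config.to_dict(),
        "counts": state.counts,
    }
    with open(state.outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return state
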