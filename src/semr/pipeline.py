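"""End-to-end orchestration and planted-truth recovery metrics.

``run_all`` executes the full chain on a simulated landscape: per-sample
SE calling, cross-sample consolidation, ubiquity classification, gene
association, identity-gene enrichment, regulon activity scoring per
subtype contrast, and candidate intersection.  The evaluation helpers
compare each stage against the generator's truth table; they power both
the test suite and the acceptance report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score, roc_auc_score

from . import activity, association, integrate, landscape
from .calling import SECallSet, call_superenhancers
from .intervals import GenomicInterval
from .simulate import ExpressionData, Landscape, SimConfig, TruthTable, \
    generate_expression, generate_landscape


@dataclass
class PipelineResult:
    landscape: Landscape
    call_sets: list[SECallSet]
    consensus: list[landscape.ConsensusSE]
    presence: landscape.PresenceMatrix
    categories: pd.Series
    links: pd.DataFrame
    identity_enrichment: association.EnrichmentResult
    expression: ExpressionData
    mr_scores: pd.DataFrame
    candidates: pd.DataFrame
    report: dict


def run_all(config: SimConfig,
            nes_threshold: float = integrate.DEFAULT_NES_THRESHOLD) -> PipelineResult:
    """Simulate one study and run every stage of the pipeline on it."""
    sim = generate_landscape(config)
    tss_list = [(g.interval.chrom, g.tss) for g in sim.annotation]

    call_sets = [
        call_superenhancers(peaks, sample=sample, d_stitch=config.d_stitch,
                            tss_list=tss_list)
        for sample, peaks in sim.peaks.items()
    ]
    manifest_map = dict(zip(sim.manifest["sample"], sim.manifest["line"]))
    consensus, pm = landscape.consolidate(call_sets, manifest_map)
    categories = landscape.categorize(consensus, pm)
    links = association.associate_genes(consensus, sim.annotation)

    ubiq_ids = set(categories[categories == "ubiquitous"].index)
    ubiq_links = links[links["se_id"].isin(ubiq_ids)]
    universe = {g.gene_id for g in sim.annotation}
    enr = association.gene_set_enrichment_fisher(
        set(ubiq_links["gene_id"]), set(sim.truth.identity_genes), universe
    )

    expr = generate_expression(config, sim.truth)
    mr_scores = activity.score_all(expr.expression, expr.subtype_labels, expr.regulons)
    candidates = integrate.select_candidates(mr_scores, ubiq_links, nes_threshold)

    report = integrate.summarize_run(
        {
            "call_sets": call_sets,
            "consensus": consensus,
            "categories": categories,
            "links": links,
            "mr_scores": mr_scores,
            "candidates": candidates,
        },
        parameters={"seed": config.seed, "nes_threshold": nes_threshold,
                    "d_stitch": config.d_stitch},
    )
    return PipelineResult(sim, call_sets, consensus, pm, categories, links, enr,
                          expr, mr_scores, candidates, report)


# --------------------------------------------------------------- metrics

def _overlaps_any(iv: GenomicInterval,
                  sorted_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]]) -> bool:
    arr = sorted_by_chrom.get(iv.chrom)
    if arr is None:
        return False
    starts, ends = arr
    j = np.searchsorted(starts, iv.end, side="left")
    # any interval among the first j (start < iv.end) that ends after iv.start
    return bool(j > 0 and np.max(ends[:j]) > iv.start)


def _index_intervals(intervals: list[GenomicInterval]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        s = np.asarray([p[0] for p in pairs])
        e = np.asarray([p[1] for p in pairs])
        out[chrom] = (s, np.maximum.accumulate(e))
    return out


def se_recovery_per_sample(call_set: SECallSet, truth: TruthTable,
                           line: str) -> tuple[float, float]:
    """(recall, precision) of called SEs against planted SE regions.

    Planted-positive regions are the non-typical regions whose presence set
    includes the sample's line.  With ``dropout_rate`` 0 the expected
    values are exactly 1.0 under strong signal separation.
    """
    planted = [r.interval for r in truth.planted_regions
               if r.category != "typical" and line in r.lines_present]
    called = [r.interval for r in call_set.super_regions()]
    planted_idx = _index_intervals(planted)
    called_idx = _index_intervals(called)
    recall = (np.mean([_overlaps_any(iv, called_idx) for iv in planted])
              if planted else 1.0)
    precision = (np.mean([_overlaps_any(iv, planted_idx) for iv in called])
                 if called else 1.0)
    return float(recall), float(precision)


def ubiquity_recovery(consensus: list, categories: pd.Series,
                      truth: TruthTable) -> dict[str, float]:
    """Precision/recall of the ubiquitous call and line-specific recall."""
    out: dict[str, float] = {}
    for category in ("ubiquitous", "line_specific"):
        planted = [r.interval for r in truth.regions_by_category(category)]
        predicted = [c.interval for c in consensus
                     if categories[c.se_id] == category]
        planted_idx = _index_intervals(planted)
        predicted_idx = _index_intervals(predicted)
        recall = (np.mean([_overlaps_any(iv, predicted_idx) for iv in planted])
                  if planted else 1.0)
        precision = (np.mean([_overlaps_any(iv, planted_idx) for iv in predicted])
                     if predicted else 1.0)
        out[f"{category}_recall"] = float(recall)
        out[f"{category}_precision"] = float(precision)
    return out


def regulator_auroc(mr_scores: pd.DataFrame, truth: TruthTable) -> float:
    """AUROC of max-|NES|-per-regulator against planted activity truth."""
    score = mr_scores.assign(a=mr_scores["nes"].abs()).groupby("regulator")["a"].max()
    active = {reg for reg, _, _ in truth.planted_active_regulators}
    labels = [1 if r in active else 0 for r in score.index]
    if len(set(labels)) < 2:
        raise ValueError("need both active and inactive regulators for AUROC")
    return float(roc_auc_score(labels, score.to_numpy()))


def candidate_set_match(candidates: pd.DataFrame, truth: TruthTable) -> bool:
    """True iff recovered candidate regulators equal the planted set."""
    found = set(candidates["regulator"]) if len(candidates) else set()
    return found == set(truth.candidate_regulators)


def clustering_ari(signal: pd.DataFrame, line_subtypes: dict[str, str],
                   k_top: int = 200) -> float:
    """Adjusted Rand index of line clustering vs the true subtype partition."""
    k = min(k_top, signal.shape[0])
    top = landscape.top_variable_regions(signal, k)
    n_groups = len(set(line_subtypes.values()))
    _, labels = landscape.cluster_lines(top, n_groups=n_groups)
    lines = list(signal.columns)
    true = [line_subtypes[ln] for ln in lines]
    pred = [labels[ln] for ln in lines]
    return float(adjusted_rand_score(true, pred))
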