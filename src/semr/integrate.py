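"""Candidate master-regulator selection and run reporting.

The candidate table intersects two evidence streams: regulators with
differential activity of |NES| strictly above a threshold (default 2) in
at least one subtype contrast, and regulators whose own gene is
associated with a ubiquitous super-enhancer.  A regulator may appear in
several contrasts; rows are ordered by |NES| descending within contrast.
"""

from __future__ import annotations

import json
from typing import Any, Optional

import pandas as pd

DEFAULT_NES_THRESHOLD = 2.0


def select_candidates(
    mr_scores: pd.DataFrame,
    ubiquitous_links: pd.DataFrame,
    nes_threshold: float = DEFAULT_NES_THRESHOLD,
    id_map: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Intersect differentially active regulators with ubiquitous-SE genes.

    Parameters
    ----------
    mr_scores : DataFrame
        Columns (regulator, contrast, nes, log2fc, ...), one row per
        regulator x contrast.
    ubiquitous_links : DataFrame
        Columns (se_id, gene_id) restricted to ubiquitous consensus SEs.
    nes_threshold : float
        Strict cutoff: a row qualifies iff |NES| > threshold.
    id_map : dict, optional
        Regulator-id -> gene-id mapping when the two namespaces differ.

    Returns a CandidateTable DataFrame with columns (regulator, contrast,
    nes, log2fc, se_ids), sorted by contrast then |NES| descending.
    """
    regulators = set(mr_scores["regulator"])
    gene_namespace = set(ubiquitous_links["gene_id"])
    mapped = {r: (id_map or {}).get(r, r) for r in regulators}
    if regulators and gene_namespace and not (set(mapped.values()) & gene_namespace):
        raise ValueError(
            "no overlap between regulator ids and SE-associated gene ids; "
            "provide an identifier mapping file"
        )
    se_of_gene = ubiquitous_links.groupby("gene_id")["se_id"].apply(
        lambda s: ",".join(sorted(set(s)))
    )
    rows = []
    for rec in mr_scores.itertuples(index=False):
        if abs(rec.nes) <= nes_threshold:
            continue
        gene = mapped[rec.regulator]
        if gene not in se_of_gene.index:
            continue
        rows.append(
            (rec.regulator, rec.contrast, rec.nes, rec.log2fc, se_of_gene[gene])
        )
    table = pd.DataFrame(
        rows, columns=["regulator", "contrast", "nes", "log2fc", "se_ids"]
    )
    if len(table):
        table = (
            table.assign(_abs=table["nes"].abs())
            .sort_values(["contrast", "_abs", "regulator"],
                         ascending=[True, False, True])
            .drop(columns="_abs")
            .reset_index(drop=True)
        )
    return table


def summarize_run(stage_outputs: dict[str, Any],
                  parameters: Optional[dict[str, Any]] = None) -> dict[str, Any]:
    """Machine-readable run report: per-stage counts, parameters, gaps.

    ``stage_outputs`` may hold any of: ``call_sets`` (list of SECallSet),
    ``consensus`` (list), ``categories`` (Series), ``links`` (DataFrame),
    ``mr_scores`` (DataFrame), ``candidates`` (DataFrame).  Missing stages
    are reported explicitly under ``missing_stages``.
    """
    report: dict[str, Any] = {"counts": {}, "missing_stages": []}
    if parameters:
        report["parameters"] = parameters

    call_sets = stage_outputs.get("call_sets")
    if call_sets is not None:
        report["counts"]["se_per_sample"] = {
            cs.sample: cs.n_super for cs in call_sets
        }
    else:
        report["missing_stages"].append("se_calling")

    consensus = stage_outputs.get("consensus")
    if consensus is not None:
        report["counts"]["consensus_se"] = len(consensus)
    else:
        report["missing_stages"].append("consolidation")

    categories = stage_outputs.get("categories")
    if categories is not None:
        vc = categories.value_counts()
        for cat in ("ubiquitous", "line_specific", "shared"):
            report["counts"][f"{cat}_se"] = int(vc.get(cat, 0))
    else:
        report["missing_stages"].append("categorization")

    links = stage_outputs.get("links")
    if links is not None:
        report["counts"]["associated_genes"] = int(links["gene_id"].nunique())
        report["counts"]["se_gene_links"] = int(len(links))
    else:
        report["missing_stages"].append("gene_association")

    mr_scores = stage_outputs.get("mr_scores")
    if mr_scores is not None:
        report["counts"]["scored_regulators"] = int(mr_scores["regulator"].nunique())
    else:
        report["missing_stages"].append("regulon_activity")

    candidates = stage_outputs.get("candidates")
    if candidates is not None:
        report["counts"]["candidate_rows"] = int(len(candidates))
        report["counts"]["candidate_regulators"] = (
            int(candidates["regulator"].nunique()) if len(candidates) else 0
        )
    else:
        report["missing_stages"].append("integration")
    return report


def report_to_json(report: dict[str, Any]) -> str:
    return json.dumps(report, indent=2, sort_keys=True)
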