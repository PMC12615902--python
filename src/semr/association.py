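"""SE-to-gene association and Fisher gene-set enrichment.

A gene is associated with a consensus SE when the distance between the SE
interval and the gene body is at most a window W (default 10 kb; overlap
counts as distance 0).  Gene sets derived from SE categories are tested
for enrichment against a gene set of interest with a two-sided Fisher's
exact test, reporting the odds ratio with a 95% Wald confidence interval
(Haldane–Anscombe +0.5 correction when any cell is empty).
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval
from .landscape import ConsensusSE

DEFAULT_WINDOW = 10_000


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene body interval with a strand-aware TSS."""

    gene_id: str
    interval: GenomicInterval

    @property
    def tss(self) -> int:
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start


@dataclass
class EnrichmentResult:
    """2x2 Fisher test summary: counts, odds ratio, 95% CI, exact p."""

    a: int  # in query and in set
    b: int  # in query, not in set
    c: int  # not in query, in set
    d: int  # neither
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


def associate_genes(
    consensus: list[ConsensusSE],
    annotation: list[GeneAnnotation],
    window: int = DEFAULT_WINDOW,
    tss_only: bool = False,
) -> pd.DataFrame:
    """Link consensus SEs to genes within ``window`` bp (many-to-many).

    Distance is between the SE interval and the gene body (or the TSS
    point when ``tss_only``); overlap counts as 0.  Returns a DataFrame
    with columns (se_id, gene_id, distance).
    """
    if not annotation:
        raise ValueError("annotation is empty")
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in annotation:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    for genes in by_chrom.values():
        genes.sort(key=lambda g: g.interval.start)

    rows = []
    for se in consensus:
        genes = by_chrom.get(se.interval.chrom, [])
        for g in genes:
            if tss_only:
                t = g.tss
                d = max(se.interval.start - (t + 1), t - se.interval.end, 0)
            else:
                d = se.interval.gap_to(g.interval)
            if d <= window:
                rows.append((se.se_id, g.gene_id, int(d)))
    return pd.DataFrame(rows, columns=["se_id", "gene_id", "distance"])


def genes_by_category(links: pd.DataFrame, categories: pd.Series) -> dict[str, set[str]]:
    """Deduplicated associated-gene set per SE category."""
    out: dict[str, set[str]] = {}
    cat = links["se_id"].map(categories)
    for category, sub in links.groupby(cat):
        out[str(category)] = set(sub["gene_id"])
    return out


def gene_set_enrichment_fisher(
    query: set[str], gene_set: set[str], universe: set[str]
) -> EnrichmentResult:
    """Two-sided Fisher's exact test of ``query`` against ``gene_set``.

    The exact p sums hypergeometric probabilities of all tables with the
    observed margins no more likely than the observed one.  The odds ratio
    is the sample OR ``(a*d)/(b*c)`` and its 95% CI is the Wald interval
    ``exp(log OR +/- 1.96 * sqrt(sum 1/cell))``; when any cell is zero all
    four cells get the Haldane–Anscombe +0.5 before OR and CI.
    """
    if not universe:
        raise ValueError("universe is empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    gene_set = gene_set & universe
    a = len(query & gene_set)
    b = len(query - gene_set)
    c = len(gene_set - query)
    d = len(universe) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    cells = np.asarray([a, b, c, d], dtype=float)
    if np.any(cells == 0):
        cells = cells + 0.5
    log_or = math.log(cells[0]) + math.log(cells[3]) - math.log(cells[1]) - math.log(cells[2])
    se = math.sqrt(np.sum(1.0 / cells))
    return EnrichmentResult(
        a=a, b=b, c=c, d=d,
        odds_ratio=math.exp(log_or),
        ci_low=math.exp(log_or - 1.96 * se),
        ci_high=math.exp(log_or + 1.96 * se),
        p_value=float(min(p, 1.0)),
    )
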