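"""Master-regulator activity scoring from regulons and expression contrasts.

For each subtype-vs-rest contrast, a per-gene signature (Welch t-statistic
on log2(1 + expression)) is converted to normal quantile scores
``q_g = Phi^{-1}(r_g / (N + 1))`` through the per-gene ranks ``r_g``
(average ranks on ties).  A regulator's activity is the weighted,
mode-signed mean of its targets' quantile scores, normalised so that the
null over random target draws is standard normal:

    NES = sum_i w_i * m_i * q_{g_i} / sqrt(sum_i w_i^2)

This is the two-tailed core of the aREA statistic behind regulon-based
master-regulator inference.  A gene-label permutation null is provided as
an empirical cross-check, and a correlation-ranked, GSEA-style weighted
Kolmogorov–Smirnov enrichment supports anchor-gene analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MIN_REGULON_SIZE = 10


@dataclass(frozen=True)
class Regulon:
    """A regulator with its weighted, signed target list.

    ``modes`` are in [-1, 1] (sign/strength of regulation), ``weights``
    in (0, 1] (interaction confidence).
    """

    regulator: str
    targets: tuple[str, ...]
    modes: tuple[float, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(set(self.targets)) != len(self.targets):
            raise ValueError(f"duplicate targets in regulon {self.regulator}")
        if not (len(self.targets) == len(self.modes) == len(self.weights)):
            raise ValueError("targets, modes, weights must align")
        if any(not -1 <= m <= 1 for m in self.modes):
            raise ValueError("modes must lie in [-1, 1]")
        if any(not 0 < w <= 1 for w in self.weights):
            raise ValueError("weights must lie in (0, 1]")

    @property
    def size(self) -> int:
        return len(self.targets)


@dataclass
class Signature:
    """Per-gene differential statistic for one subtype-vs-rest contrast."""

    contrast: str
    stats: pd.Series  # index: gene, values: t-statistic

    @property
    def n_genes(self) -> int:
        return self.stats.size

    def quantile_scores(self) -> pd.Series:
        """Normal quantile score per gene: Phi^{-1}(rank / (N + 1))."""
        ranks = self.stats.rank(method="average")
        return pd.Series(
            stats.norm.ppf(ranks / (self.n_genes + 1)), index=self.stats.index
        )


@dataclass
class MRScore:
    regulator: str
    contrast: str
    nes: float
    log2fc: float  # regulator's own expression shift; NaN when unmeasured
    n_targets_used: int


def contrast_signature(
    expression: pd.DataFrame,
    subtype_labels: pd.Series,
    subtype: str,
    eps: float = 1e-6,
) -> Signature:
    """Welch t-statistic per gene for ``subtype`` vs all other samples.

    Expression (genes x samples) is transformed to log2(1 + x) first; the
    pooled standard error is epsilon-stabilised so constant genes yield a
    finite statistic.
    """
    labels = subtype_labels.reindex(expression.columns)
    in_group = (labels == subtype).to_numpy()
    if in_group.sum() == 0:
        raise ValueError(f"subtype {subtype!r} absent from labels")
    if in_group.sum() < 2 or (~in_group).sum() < 2:
        raise ValueError("need >= 2 samples on each side of the contrast")
    log_expr = np.log2(1.0 + expression.to_numpy(dtype=float))
    x, y = log_expr[:, in_group], log_expr[:, ~in_group]
    n1, n2 = x.shape[1], y.shape[1]
    num = x.mean(axis=1) - y.mean(axis=1)
    den = np.sqrt(x.var(axis=1, ddof=1) / n1 + y.var(axis=1, ddof=1) / n2 + eps)
    return Signature(contrast=subtype, stats=pd.Series(num / den, index=expression.index))


def area_nes(signature: Signature, regulon: Regulon,
             min_size: int = MIN_REGULON_SIZE) -> tuple[float, int]:
    """Analytic NES of one regulon against one signature.

    Targets absent from the signature universe are dropped; if fewer than
    ``min_size`` remain the score is undefined (ValueError).  Returns
    (NES, number of targets used).
    """
    q = signature.quantile_scores()
    keep = [i for i, t in enumerate(regulon.targets) if t in q.index]
    if len(keep) < min_size:
        raise ValueError(
            f"regulon {regulon.regulator}: {len(keep)} targets in universe "
            f"< min size {min_size}"
        )
    w = np.asarray([regulon.weights[i] for i in keep])
    m = np.asarray([regulon.modes[i] for i in keep])
    qv = q.loc[[regulon.targets[i] for i in keep]].to_numpy()
    return float(np.sum(w * m * qv) / np.sqrt(np.sum(w * w))), len(keep)


def permutation_nes(
    signature: Signature,
    regulon: Regulon,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = MIN_REGULON_SIZE,
) -> tuple[float, float]:
    """Empirical z and two-sided p of the regulon score under gene shuffles.

    The un-normalised score is recomputed on ``n_perm`` permutations of
    the signature's gene labels; z standardises the observed score by the
    permutation null, and p uses +1 smoothing.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    observed, n_used = area_nes(signature, regulon, min_size)
    rng = np.random.default_rng(seed)
    q = signature.quantile_scores().to_numpy()
    keep = [i for i, t in enumerate(regulon.targets) if t in signature.stats.index]
    w = np.asarray([regulon.weights[i] for i in keep])
    m = np.asarray([regulon.modes[i] for i in keep])
    norm = np.sqrt(np.sum(w * w))
    null = np.empty(n_perm)
    for b in range(n_perm):
        qs = rng.choice(q, size=len(keep), replace=False)
        null[b] = np.sum(w * m * qs) / norm
    z = (observed - null.mean()) / null.std(ddof=1)
    p = (np.sum(np.abs(null) >= abs(observed)) + 1) / (n_perm + 1)
    return float(z), float(p)


def score_all(
    expression: pd.DataFrame,
    subtype_labels: pd.Series,
    regulons: list[Regulon],
    min_size: int = MIN_REGULON_SIZE,
) -> pd.DataFrame:
    """MRScore table over every (regulator x subtype contrast).

    One row per regulator and contrast where the regulon meets the size
    rule; includes the regulator's own log2(1+x) expression shift for the
    contrast (NaN when the regulator has no expression row).  Regulons too
    small after universe intersection are recorded as warnings and skipped.
    """
    if not regulons:
        raise ValueError("empty regulon set")
    subtypes = sorted(subtype_labels.unique())
    log_expr = np.log2(1.0 + expression)
    rows: list[MRScore] = []
    for subtype in subtypes:
        sig = contrast_signature(expression, subtype_labels, subtype)
        in_group = (subtype_labels.reindex(expression.columns) == subtype).to_numpy()
        for reg in regulons:
            try:
                nes, n_used = area_nes(sig, reg, min_size)
            except ValueError as err:
                warnings.warn(str(err), stacklevel=2)
                continue
            if reg.regulator in log_expr.index:
                vals = log_expr.loc[reg.regulator].to_numpy()
                log2fc = float(vals[in_group].mean() - vals[~in_group].mean())
            else:
                log2fc = float("nan")
            rows.append(MRScore(reg.regulator, subtype, nes, log2fc, n_used))
    return pd.DataFrame(
        [(r.regulator, r.contrast, r.nes, r.log2fc, r.n_targets_used) for r in rows],
        columns=["regulator", "contrast", "nes", "log2fc", "n_targets"],
    )


def correlation_rank_enrichment(
    expression: pd.DataFrame,
    anchor: str,
    gene_set: set[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """GSEA-style enrichment of a gene set along anchor-correlation ranks.

    All genes other than the anchor are ranked by Spearman correlation
    with the anchor's expression (descending); the enrichment score is the
    extremum of the weighted Kolmogorov–Smirnov running sum with weight
    |correlation|; p is a two-sided gene-label permutation estimate with
    +1 smoothing.  Positive ES reports concentration at the positively
    correlated head of the ranking.
    """
    if anchor not in expression.index:
        raise KeyError(f"anchor gene {anchor!r} not in expression matrix")
    anchor_expr = expression.loc[anchor].to_numpy(dtype=float)
    if np.ptp(anchor_expr) == 0:
        raise ValueError(f"anchor {anchor!r} has constant expression")
    others = expression.drop(index=anchor)
    in_set = others.index.isin(gene_set)
    if in_set.sum() < 5:
        raise ValueError("gene set must share >= 5 genes with the universe")
    anchor_ranks = stats.rankdata(anchor_expr)
    gene_ranks = np.apply_along_axis(stats.rankdata, 1, others.to_numpy(dtype=float))
    n = anchor_expr.size
    # Spearman = Pearson on ranks, vectorised over genes
    ar = anchor_ranks - anchor_ranks.mean()
    gr = gene_ranks - gene_ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt(np.sum(ar**2) * np.sum(gr**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, gr @ ar / denom, 0.0)

    def es(corr_vec: np.ndarray, member: np.ndarray) -> float:
        order = np.argsort(-corr_vec, kind="stable")
        member_sorted = member[order]
        weights = np.abs(corr_vec[order])
        hit_w = np.where(member_sorted, weights, 0.0)
        total_hit = hit_w.sum()
        if total_hit == 0:
            return 0.0
        n_miss = (~member_sorted).sum()
        running = np.cumsum(hit_w / total_hit - (~member_sorted) / max(n_miss, 1))
        return float(running[np.argmax(np.abs(running))])

    observed = es(corr, in_set)
    rng = np.random.default_rng(seed)
    count = 0
    member = in_set.copy()
    for _ in range(n_perm):
        rng.shuffle(member)
        if abs(es(corr, member)) >= abs(observed):
            count += 1
    return observed, float((count + 1) / (n_perm + 1))
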