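"""Cross-sample consolidation of super-enhancer calls.

Per-sample SE calls are merged into a consensus set by single-linkage
merging of intervals overlapping by >= 1 bp; replicates collapse to the
cell-line level ("present in >= 1 replicate"); a boolean presence matrix
(consensus SE x cell line) supports the ubiquity classification: a
consensus SE present in more than two-thirds of the lines is ubiquitous,
one present in exactly one line is line-specific, the rest are shared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .calling import SECallSet
from .intervals import GenomicInterval

UBIQUITY_FRACTION = 2.0 / 3.0


@dataclass
class ConsensusSE:
    """A merged SE region with its per-sample members and per-line signal."""

    se_id: str
    interval: GenomicInterval
    members: list[tuple[str, GenomicInterval, float]]  # (sample, interval, S)
    presence: dict[str, bool]
    line_signal: dict[str, float]  # mean S over contributing samples, 0 if absent


@dataclass
class PresenceMatrix:
    """Boolean consensus-SE x cell-line table with the ubiquity threshold."""

    table: pd.DataFrame  # index: se_id, columns: lines, values: bool
    k_min: int
    f_ubiq: float = UBIQUITY_FRACTION

    @property
    def n_lines(self) -> int:
        return self.table.shape[1]

    def row_counts(self) -> pd.Series:
        return self.table.sum(axis=1)


def ubiquity_threshold(n_lines: int, f_ubiq: float = UBIQUITY_FRACTION) -> int:
    """Smallest line count strictly greater than ``f_ubiq * n_lines``.

    With 17 lines and f = 2/3 this is 12 — "present in more than
    two-thirds of the cell lines".
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    if not 0 < f_ubiq < 1:
        raise ValueError("f_ubiq must be in (0, 1)")
    return math.floor(f_ubiq * n_lines) + 1


def classify_ubiquity(count: int, k_min: int) -> str:
    """Partition a presence count into ubiquitous / line_specific / shared."""
    if count < 1:
        raise ValueError("a consensus SE must be present in at least one line")
    if count == 1:
        return "line_specific"
    if count >= k_min:
        return "ubiquitous"
    return "shared"


def consolidate(
    call_sets: list[SECallSet],
    manifest: dict[str, str],
    f_ubiq: float = UBIQUITY_FRACTION,
) -> tuple[list[ConsensusSE], PresenceMatrix]:
    """Merge per-sample SE calls into consensus regions and build presence.

    Parameters
    ----------
    call_sets : list of SECallSet
        Per-sample calls; only regions flagged super contribute.
    manifest : dict sample -> cell line
        Every sample id in ``call_sets`` must appear.
    """
    if not call_sets:
        raise ValueError("need at least one SECallSet")
    missing = [cs.sample for cs in call_sets if cs.sample not in manifest]
    if missing:
        raise KeyError(f"samples missing from manifest: {missing}")
    lines = sorted(set(manifest[cs.sample] for cs in call_sets))

    members: list[tuple[str, GenomicInterval, float]] = []
    for cs in call_sets:
        for region in cs.super_regions():
            members.append((cs.sample, region.interval, region.signal))
    members.sort(key=lambda m: (m[1].chrom, m[1].start, m[1].end, m[0]))

    consensus: list[ConsensusSE] = []
    cur: list[tuple[str, GenomicInterval, float]] = []
    cur_iv: GenomicInterval | None = None
    def _flush() -> None:
        nonlocal cur, cur_iv
        if cur_iv is None:
            return
        line_vals: dict[str, list[float]] = {}
        for sample, _, s in cur:
            line_vals.setdefault(manifest[sample], []).append(s)
        presence = {ln: ln in line_vals for ln in lines}
        line_signal = {
            ln: float(np.mean(line_vals[ln])) if ln in line_vals else 0.0
            for ln in lines
        }
        consensus.append(
            ConsensusSE("", cur_iv, list(cur), presence, line_signal)
        )
        cur, cur_iv = [], None

    for m in members:
        iv = m[1]
        if cur_iv is not None and cur_iv.chrom == iv.chrom and iv.start < cur_iv.end:
            cur_iv = cur_iv.span(iv)
            cur.append(m)
        else:
            _flush()
            cur_iv = iv
            cur = [m]
    _flush()

    consensus.sort(key=lambda c: (c.interval.chrom, c.interval.start))
    width = len(str(max(len(consensus), 1)))
    for i, c in enumerate(consensus, 1):
        c.se_id = f"SE{i:0{width}d}"

    table = pd.DataFrame(
        [[c.presence[ln] for ln in lines] for c in consensus],
        index=[c.se_id for c in consensus],
        columns=lines,
        dtype=bool,
    )
    k_min = ubiquity_threshold(len(lines), f_ubiq)
    return consensus, PresenceMatrix(table, k_min, f_ubiq)


def categorize(consensus: list[ConsensusSE], pm: PresenceMatrix) -> pd.Series:
    """Category per consensus SE id, from the presence row counts."""
    counts = pm.row_counts()
    return counts.map(lambda c: classify_ubiquity(int(c), pm.k_min))


def line_signal_matrix(consensus: list[ConsensusSE]) -> pd.DataFrame:
    """Consensus-SE x line matrix of mean member signal (0 where absent)."""
    if not consensus:
        return pd.DataFrame()
    lines = sorted(consensus[0].line_signal)
    return pd.DataFrame(
        [[c.line_signal[ln] for ln in lines] for c in consensus],
        index=[c.se_id for c in consensus],
        columns=lines,
    )


def top_variable_regions(signal: pd.DataFrame, k: int) -> pd.DataFrame:
    """The k consensus SEs most variable across lines.

    Variance is computed on log2(1 + signal) per region; ties broken by
    genomic order (the row order of the input, which consolidate emits
    sorted by coordinate).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > signal.shape[0]:
        raise ValueError(f"k={k} exceeds {signal.shape[0]} regions")
    logsig = np.log2(1.0 + signal)
    var = logsig.var(axis=1, ddof=1)
    order = np.argsort(-var.to_numpy(), kind="stable")[:k]
    return signal.iloc[np.sort(order)]


def cluster_lines(
    signal: pd.DataFrame, n_groups: int | None = None
) -> tuple[np.ndarray, dict[str, int] | None]:
    """Hierarchically cluster cell lines on their SE-signal profiles.

    Distance is 1 - Pearson correlation between line profiles (columns of
    log2(1 + signal)); linkage is average.  Returns the scipy linkage
    matrix and, when ``n_groups`` is given, flat labels per line.
    """
    if signal.shape[1] < 2 or signal.shape[0] < 2:
        raise ValueError("need >= 2 lines and >= 2 regions")
    logsig = np.log2(1.0 + signal)
    sds = logsig.std(axis=0, ddof=0)
    flat = sds[sds == 0].index.tolist()
    if flat:
        raise ValueError(
            f"constant signal profile, correlation undefined for line(s): {flat}"
        )
    corr = np.corrcoef(logsig.to_numpy().T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    linkage = hierarchy.average(squareform(dist, checks=False))
    labels = None
    if n_groups is not None:
        flat_labels = hierarchy.fcluster(linkage, t=n_groups, criterion="maxclust")
        labels = dict(zip(signal.columns, (int(v) for v in flat_labels)))
    return linkage, labels


def dendrogram_newick(linkage: np.ndarray, leaf_names: list[str]) -> str:
    """Render a scipy linkage as a newick string (branch lengths = heights)."""
    tree = hierarchy.to_tree(linkage)

    def rec(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"
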