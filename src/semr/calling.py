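"""ROSE-style super-enhancer calling for a single sample.

The procedure mirrors the classic H3K27ac super-enhancer definition:
constituent peaks closer than a stitching distance are merged into stitched
regions, each region is quantified as background-subtracted signal area
(ChIP minus matched input, floored at zero), regions are ranked by signal,
and the hockey-stick cutoff separates the exceptionally signal-rich tail
(super-enhancers) from typical enhancers.  The cutoff is the tangent point
of the rank-vs-signal curve with the line of overall slope
``(y_max - y_min) / (n - 1)``: the rank minimising ``y_i - slope * i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .intervals import GenomicInterval

DEFAULT_STITCH_DISTANCE = 12_500
DEFAULT_TSS_WINDOW = 2_500


@dataclass(frozen=True)
class Peak:
    """A constituent H3K27ac peak with ChIP and matched-input densities.

    Densities are mean signal per bp over the peak; both must be >= 0.
    """

    interval: GenomicInterval
    chip_density: float
    input_density: float = 0.0

    def __post_init__(self) -> None:
        if self.chip_density < 0 or self.input_density < 0:
            raise ValueError(
                f"negative density on peak {self.interval}: "
                f"chip={self.chip_density}, input={self.input_density}"
            )


@dataclass
class StitchedRegion:
    """A run of constituent peaks merged at the stitching distance."""

    interval: GenomicInterval
    constituents: list[Peak]
    signal: float = 0.0  # background-subtracted area, >= 0


@dataclass
class SECallSet:
    """Per-sample ranked stitched regions with the super/typical split.

    ``regions`` are sorted by ascending signal; ``ranks[i]`` is the
    1-based ascending rank of ``regions[i]``.  ``is_super[i]`` is True iff
    ``regions[i].signal > cutoff_value``.
    """

    sample: str
    regions: list[StitchedRegion]
    ranks: np.ndarray
    cutoff_value: float
    cutoff_index: int
    is_super: np.ndarray
    d_stitch: int = DEFAULT_STITCH_DISTANCE
    tss_window: int = DEFAULT_TSS_WINDOW

    @property
    def n_super(self) -> int:
        return int(self.is_super.sum())

    def super_regions(self) -> list[StitchedRegion]:
        return [r for r, s in zip(self.regions, self.is_super) if s]


def _check_sorted(peaks: Sequence[Peak]) -> None:
    for prev, nxt in zip(peaks, peaks[1:]):
        a, b = prev.interval, nxt.interval
        if a.chrom == b.chrom:
            if b.start < a.start:
                raise ValueError("peaks must be sorted by (chrom, start)")
            if b.start < a.end:
                raise ValueError(
                    f"overlapping peaks within sample at {a.chrom}:{a.start}"
                )


def _near_tss(peak: Peak, tss_sorted: np.ndarray, tss_window: int) -> bool:
    """True iff the peak lies fully inside +/- tss_window of some TSS."""
    iv = peak.interval
    chrom_tss = tss_sorted  # positions on the peak's chromosome, ascending
    if chrom_tss.size == 0:
        return False
    # peak in [t - w, t + w] <=> t in [end - w, start + w]
    lo, hi = iv.end - tss_window, iv.start + tss_window
    if lo > hi:
        return False
    j = np.searchsorted(chrom_tss, lo, side="left")
    return j < chrom_tss.size and chrom_tss[j] <= hi


def stitch_peaks(
    peaks: Sequence[Peak],
    d_stitch: int = DEFAULT_STITCH_DISTANCE,
    tss_list: Optional[Sequence[tuple[str, int]]] = None,
    tss_window: int = DEFAULT_TSS_WINDOW,
) -> list[StitchedRegion]:
    """Merge peaks on one chromosome whose gap is <= ``d_stitch``.

    Peaks must be sorted by (chrom, start) and non-overlapping within the
    sample.  When ``tss_list`` (pairs of chromosome, position) is given,
    peaks fully contained within +/- ``tss_window`` of any TSS are removed
    before stitching — the promoter-proximal exclusion of the ROSE recipe.
    """
    _check_sorted(peaks)
    if tss_list is not None:
        by_chrom: dict[str, list[int]] = {}
        for chrom, pos in tss_list:
            by_chrom.setdefault(chrom, []).append(pos)
        tss_arrays = {c: np.asarray(sorted(p)) for c, p in by_chrom.items()}
        empty = np.asarray([], dtype=int)
        peaks = [
            p
            for p in peaks
            if not _near_tss(p, tss_arrays.get(p.interval.chrom, empty), tss_window)
        ]
    regions: list[StitchedRegion] = []
    for peak in peaks:
        if regions:
            last = regions[-1]
            prev = last.constituents[-1].interval
            cur = peak.interval
            if prev.chrom == cur.chrom and cur.start - prev.end <= d_stitch:
                last.constituents.append(peak)
                last.interval = last.interval.span(cur)
                continue
        regions.append(StitchedRegion(peak.interval, [peak]))
    return regions


def quantify_region_signal(region: StitchedRegion) -> float:
    """Background-subtracted signal area of a stitched region.

    ``S = max(0, sum_constituents (chip - input) * length)``; the floor at
    zero keeps the rank curve and tangent geometry stable when input
    exceeds ChIP.
    """
    s = sum(
        (p.chip_density - p.input_density) * p.interval.length
        for p in region.constituents
    )
    return max(0.0, float(s))


def se_cutoff(signals: Sequence[float]) -> tuple[float, int]:
    """Hockey-stick cutoff on an ascending-sorted signal vector.

    Returns ``(y_star, i_star)`` where ``i_star`` is the 1-based rank
    minimising ``y_i - slope * i`` with ``slope = (y_n - y_1) / (n - 1)``,
    ties resolved to the largest rank (fewest super-enhancers), and
    ``y_star = y[i_star]``.  Regions with signal strictly above ``y_star``
    are super-enhancers.
    """
    y = np.asarray(signals, dtype=float)
    n = y.size
    if n < 2:
        raise ValueError("cutoff needs at least 2 regions")
    if np.any(np.diff(y) < 0):
        raise ValueError("signals must be sorted ascending")
    slope = (y[-1] - y[0]) / (n - 1)
    ranks = np.arange(1, n + 1)
    resid = y - slope * ranks
    # largest index among ties of the minimum
    i_star = int(n - 1 - np.argmin(resid[::-1]))  # 0-based
    return float(y[i_star]), i_star + 1


def call_superenhancers(
    peaks: Sequence[Peak],
    sample: str = "sample",
    d_stitch: int = DEFAULT_STITCH_DISTANCE,
    tss_list: Optional[Sequence[tuple[str, int]]] = None,
    tss_window: int = DEFAULT_TSS_WINDOW,
) -> SECallSet:
    """Full per-sample pipeline: stitch, quantify, rank, cutoff, flag."""
    regions = stitch_peaks(peaks, d_stitch, tss_list, tss_window)
    for r in regions:
        r.signal = quantify_region_signal(r)
    regions.sort(key=lambda r: (r.signal, r.interval.chrom, r.interval.start))
    n = len(regions)
    if n == 0:
        return SECallSet(
            sample, [], np.asarray([], dtype=int), float("nan"), 0,
            np.asarray([], dtype=bool), d_stitch, tss_window,
        )
    signals = np.asarray([r.signal for r in regions])
    if n == 1:
        # a single region cannot define a tangent; call it typical
        y_star, i_star = float(signals[0]), 1
    else:
        y_star, i_star = se_cutoff(signals)
    is_super = signals > y_star
    return SECallSet(
        sample=sample,
        regions=regions,
        ranks=np.arange(1, n + 1),
        cutoff_value=y_star,
        cutoff_index=i_star,
        is_super=is_super,
        d_stitch=d_stitch,
        tss_window=tss_window,
    )
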