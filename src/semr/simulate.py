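"""Synthetic chromatin-landscape and expression generator with planted truth.

The generator emulates a panel of breast-derived cell lines profiled for
H3K27ac: each line is measured in replicates, and its peak landscape
contains four planted region categories — ubiquitous super-enhancers
(present in every line), subtype-specific SEs (present in the lines of
one expression subtype), line-specific SEs (one line) and typical
enhancers (weak, single-peak, everywhere).  Super-enhancers are clusters
of constituent peaks whose per-bp ChIP density is drawn from a gamma
distribution around the category mean, with a matched input (background)
density; their summed background-subtracted signal therefore exceeds
typical enhancers by construction, producing the hockey-stick rank curve
downstream callers rely on.

Each planted region carries one adjacent gene (within the association
window), and a separate gene-only chromosome holds background genes.  A
matched expression matrix plants regulator activity: designated
regulators' targets shift coherently (mode x sign x effect) in the
samples of a designated subtype.  Active regulators anchored on
ubiquitous-SE genes are the intended end-to-end candidates; decoys are
either active but anchored on line-specific-SE genes, or inactive.

All randomness flows from the single integer seed in the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .calling import DEFAULT_STITCH_DISTANCE, Peak
from .association import GeneAnnotation
from .intervals import GenomicInterval

SUBTYPES = ("Nor", "Lum", "HER2", "TNBC")
_SUBTYPE_CYCLE = ("Lum", "TNBC", "HER2", "Nor")

_GENE_OFFSET = 4_000   # gap from a planted region's end to its gene
_GENE_LENGTH = 1_500
_BG_GENE_SPACING = 6_000


class GenomeTooSmallError(ValueError):
    """Raised when planted regions cannot be placed without collisions."""


@dataclass
class SimConfig:
    """Study conditions for one synthetic run.

    Signal densities are arbitrary units per bp; expression effects and
    noise are on the log2 scale.  ``noise_sd`` is both the gamma standard
    deviation of per-constituent ChIP densities and the additive Gaussian
    noise of log2 expression.
    """

    n_lines: int = 10
    replicates_per_line: int = 2
    subtype_of_line: Optional[dict[str, str]] = None
    genome: tuple[tuple[str, int], ...] = (
        ("chr1", 25_000_000),
        ("chr2", 25_000_000),
        ("chr3", 25_000_000),
        ("chrBG", 20_000_000),  # gene-only background chromosome (last)
    )
    n_ubiquitous_se: int = 40
    n_subtype_se: int = 40
    n_line_se: int = 100
    n_typical: int = 1000
    se_signal_mean: float = 6.0
    typical_signal_mean: float = 0.6
    input_signal_mean: float = 0.2
    noise_sd: float = 0.3
    peak_len_range: tuple[int, int] = (500, 2000)
    peaks_per_se_range: tuple[int, int] = (4, 8)
    d_stitch: int = DEFAULT_STITCH_DISTANCE
    dropout_rate: float = 0.05
    n_genes: int = 1600
    n_regulators: int = 6
    targets_per_regulator: int = 50
    n_active_regulators: int = 3
    n_line_decoys: int = 1  # active regulators anchored on line-specific-SE genes
    activity_effect: float = 3.0
    expression_baseline: tuple[float, float] = (3.0, 8.0)
    seed: int = 0

    def validate(self) -> None:
        counts = dict(
            n_lines=self.n_lines,
            replicates_per_line=self.replicates_per_line,
            n_ubiquitous_se=self.n_ubiquitous_se,
            n_subtype_se=self.n_subtype_se,
            n_line_se=self.n_line_se,
            n_typical=self.n_typical,
            n_genes=self.n_genes,
            n_regulators=self.n_regulators,
            targets_per_regulator=self.targets_per_regulator,
            n_active_regulators=self.n_active_regulators,
            n_line_decoys=self.n_line_decoys,
        )
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.n_lines < 1 or self.replicates_per_line < 1:
            raise ValueError("need at least one line and one replicate")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.activity_effect < 0:
            raise ValueError("activity_effect must be >= 0")
        if self.n_active_regulators + self.n_line_decoys > self.n_regulators:
            raise ValueError("active + line-decoy regulators exceed n_regulators")
        n_regions = self.total_regions
        if self.n_genes < n_regions + self.n_regulators * self.targets_per_regulator:
            raise ValueError(
                "n_genes must cover one gene per planted region plus "
                "disjoint regulon targets: need >= "
                f"{n_regions + self.n_regulators * self.targets_per_regulator}"
            )
        for line, st in self.line_subtypes().items():
            if st not in SUBTYPES:
                raise ValueError(f"line {line}: unknown subtype {st!r}")
        if self.n_active_regulators > 0 and self.n_ubiquitous_se == 0:
            raise ValueError("active regulators need ubiquitous SEs to anchor on")
        if self.n_regulators > self.n_active_regulators and self.n_line_se == 0 \
                and self.n_regulators - self.n_active_regulators > 0:
            raise ValueError("decoy regulators need line-specific SEs to anchor on")

    @property
    def total_regions(self) -> int:
        return self.n_ubiquitous_se + self.n_subtype_se + self.n_line_se + self.n_typical

    def line_names(self) -> list[str]:
        return [f"L{i:02d}" for i in range(1, self.n_lines + 1)]

    def line_subtypes(self) -> dict[str, str]:
        if self.subtype_of_line is not None:
            return dict(self.subtype_of_line)
        names = self.line_names()
        return {ln: _SUBTYPE_CYCLE[i % len(_SUBTYPE_CYCLE)] for i, ln in enumerate(names)}

    def manifest(self) -> pd.DataFrame:
        """Sample sheet: one row per (line, replicate)."""
        subtypes = self.line_subtypes()
        rows = [
            (f"{ln}_r{rep}", ln, subtypes[ln], rep)
            for ln in self.line_names()
            for rep in range(1, self.replicates_per_line + 1)
        ]
        return pd.DataFrame(rows, columns=["sample", "line", "subtype", "replicate"])


@dataclass
class PlantedRegion:
    region_id: str
    interval: GenomicInterval  # span of constituent peaks
    category: str  # ubiquitous | subtype_specific | line_specific | typical
    lines_present: tuple[str, ...]
    gene_id: str
    peak_intervals: tuple[GenomicInterval, ...] = ()
    subtype: Optional[str] = None  # for subtype_specific regions


@dataclass
class TruthTable:
    """Planted ground truth for recovery tests."""

    planted_regions: list[PlantedRegion]
    planted_active_regulators: list[tuple[str, str, int]]  # (regulator, subtype, sign)
    candidate_regulators: list[str]  # active AND ubiquitous-SE-anchored
    decoy_regulators: list[str]
    identity_genes: list[str]
    n_lines: int

    def regions_by_category(self, category: str) -> list[PlantedRegion]:
        return [r for r in self.planted_regions if r.category == category]

    def presence_counts(self) -> dict[str, int]:
        return {r.region_id: len(r.lines_present) for r in self.planted_regions}


@dataclass
class Landscape:
    """Per-sample peak sets plus annotation, manifest and planted truth."""

    peaks: dict[str, list[Peak]]  # sample -> sorted peaks
    annotation: list[GeneAnnotation]
    manifest: pd.DataFrame
    truth: TruthTable
    config: SimConfig


def _gamma_draws(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size)
    if sd <= 0:
        return np.full(size, mean)
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return rng.gamma(shape, scale, size=size)


def _blueprints(config: SimConfig, rng: np.random.Generator) -> list[PlantedRegion]:
    """Category, presence and constituent geometry for every planted region."""
    lines = config.line_names()
    subtypes = config.line_subtypes()
    by_subtype: dict[str, list[str]] = {}
    for ln in lines:
        by_subtype.setdefault(subtypes[ln], []).append(ln)
    subtype_order = [s for s in _SUBTYPE_CYCLE if s in by_subtype]

    specs: list[tuple[str, tuple[str, ...], Optional[str]]] = []
    for _ in range(config.n_ubiquitous_se):
        specs.append(("ubiquitous", tuple(lines), None))
    for i in range(config.n_subtype_se):
        st = subtype_order[i % len(subtype_order)]
        specs.append(("subtype_specific", tuple(by_subtype[st]), st))
    for i in range(config.n_line_se):
        specs.append(("line_specific", (lines[i % len(lines)],), None))
    for _ in range(config.n_typical):
        specs.append(("typical", tuple(lines), None))

    counters = {"ubiquitous": 0, "subtype_specific": 0, "line_specific": 0, "typical": 0}
    prefix = {"ubiquitous": "UB", "subtype_specific": "SUB",
              "line_specific": "LINE", "typical": "TYP"}
    regions: list[PlantedRegion] = []
    lo_len, hi_len = config.peak_len_range
    lo_k, hi_k = config.peaks_per_se_range
    for category, present, st in specs:
        counters[category] += 1
        rid = f"{prefix[category]}{counters[category]:04d}"
        n_peaks = 1 if category == "typical" else int(rng.integers(lo_k, hi_k + 1))
        lengths = rng.integers(lo_len, hi_len + 1, size=n_peaks)
        gaps = rng.integers(200, min(3000, config.d_stitch), size=max(n_peaks - 1, 0))
        offsets = []
        pos = 0
        for i, length in enumerate(lengths):
            offsets.append((pos, pos + int(length)))
            pos += int(length)
            if i < len(gaps):
                pos += int(gaps[i])
        regions.append(
            PlantedRegion(
                region_id=rid,
                interval=GenomicInterval("placeholder", 0, pos),
                category=category,
                lines_present=present,
                gene_id=f"G_{rid}",
                peak_intervals=tuple(
                    GenomicInterval("placeholder", s, e) for s, e in offsets
                ),
                subtype=st,
            )
        )
    return regions


def _place(config: SimConfig, regions: list[PlantedRegion],
           rng: np.random.Generator) -> list[PlantedRegion]:
    """Lay regions out along the peak chromosomes with anti-merge padding.

    Consecutive regions are separated by at least d_stitch + 20 kb so that
    categories can never stitch or consensus-merge across regions, and each
    region's adjacent gene stays > 10 kb from every other region.
    """
    peak_chroms = list(config.genome[:-1]) if len(config.genome) > 1 else list(config.genome)
    order = rng.permutation(len(regions))
    placed: list[PlantedRegion] = []
    chrom_idx, cursor = 0, 10_000
    for idx in order:
        region = regions[idx]
        span = region.interval.end
        placed_ok = False
        while chrom_idx < len(peak_chroms):
            chrom, length = peak_chroms[chrom_idx]
            gene_end = cursor + span + _GENE_OFFSET + _GENE_LENGTH
            if gene_end < length:
                start = cursor
                new_interval = GenomicInterval(chrom, start, start + span)
                new_peaks = tuple(
                    GenomicInterval(chrom, start + p.start, start + p.end)
                    for p in region.peak_intervals
                )
                placed.append(
                    PlantedRegion(
                        region.region_id, new_interval, region.category,
                        region.lines_present, region.gene_id, new_peaks,
                        region.subtype,
                    )
                )
                cursor = start + span + config.d_stitch + int(rng.integers(20_000, 30_000))
                placed_ok = True
                break
            chrom_idx += 1
            cursor = 10_000
        if not placed_ok:
            raise GenomeTooSmallError(
                "genome too small to place all planted regions with the "
                "required anti-merge padding"
            )
    placed.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return placed


def _annotation(config: SimConfig, regions: list[PlantedRegion],
                rng: np.random.Generator) -> list[GeneAnnotation]:
    genes: list[GeneAnnotation] = []
    for region in regions:
        start = region.interval.end + _GENE_OFFSET
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneAnnotation(
                region.gene_id,
                GenomicInterval(region.interval.chrom, start, start + _GENE_LENGTH, strand),
            )
        )
    n_background = config.n_genes - len(regions)
    bg_chrom, bg_len = config.genome[-1]
    needed = n_background * _BG_GENE_SPACING + 10_000
    if needed > bg_len:
        raise GenomeTooSmallError(
            f"background chromosome {bg_chrom} too small for {n_background} genes"
        )
    for i in range(n_background):
        start = 5_000 + i * _BG_GENE_SPACING
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneAnnotation(
                f"G_BG{i + 1:04d}",
                GenomicInterval(bg_chrom, start, start + _GENE_LENGTH, strand),
            )
        )
    return genes


def _pick_regulators(config: SimConfig, regions: list[PlantedRegion],
                     rng: np.random.Generator) -> TruthTable:
    ub_genes = [r.gene_id for r in regions if r.category == "ubiquitous"]
    line_genes = [r.gene_id for r in regions if r.category == "line_specific"]
    rng.shuffle(ub_genes)
    rng.shuffle(line_genes)

    n_active = config.n_active_regulators
    n_line_decoys = config.n_line_decoys
    n_inactive = config.n_regulators - n_active - n_line_decoys
    if n_active > len(ub_genes):
        raise ValueError("not enough ubiquitous-SE genes for active regulators")
    if n_line_decoys + n_inactive > len(line_genes):
        raise ValueError("not enough line-specific-SE genes for decoy regulators")

    subtypes_present = sorted(set(config.line_subtypes().values()),
                              key=_SUBTYPE_CYCLE.index)
    active: list[tuple[str, str, int]] = []
    candidates: list[str] = []
    decoys: list[str] = []
    for i in range(n_active):
        reg = ub_genes[i]
        subtype = subtypes_present[i % len(subtypes_present)]
        sign = 1 if i % 2 == 0 else -1
        active.append((reg, subtype, sign))
        candidates.append(reg)
    for i in range(n_line_decoys):
        reg = line_genes[i]
        subtype = subtypes_present[(n_active + i) % len(subtypes_present)]
        sign = 1 if (n_active + i) % 2 == 0 else -1
        active.append((reg, subtype, sign))
        decoys.append(reg)
    for i in range(n_inactive):
        decoys.append(line_genes[n_line_decoys + i])

    # identity gene set for enrichment checks: every ubiquitous-SE gene plus
    # a sprinkling of background genes, mimicking an external identity list
    n_bg_extra = min(50, config.n_genes - len(regions))
    bg_pool = [f"G_BG{i + 1:04d}" for i in range(config.n_genes - len(regions))]
    extra = list(rng.choice(bg_pool, size=n_bg_extra, replace=False)) if bg_pool else []
    identity = sorted(set(g for g in
                          [r.gene_id for r in regions if r.category == "ubiquitous"]
                          ) | set(extra))
    return TruthTable(
        planted_regions=regions,
        planted_active_regulators=active,
        candidate_regulators=sorted(candidates),
        decoy_regulators=sorted(decoys),
        identity_genes=identity,
        n_lines=config.n_lines,
    )


def generate_landscape(config: SimConfig) -> Landscape:
    """Generate per-sample peak sets, gene annotation and the truth table.

    Identical config + seed reproduces byte-identical output.  Raises
    GenomeTooSmallError when the planted regions cannot be placed.
    """
    config.validate()
    ss = np.random.SeedSequence([config.seed, 0])
    rng = np.random.default_rng(ss)

    regions = _place(config, _blueprints(config, rng), rng)
    annotation = _annotation(config, regions, rng)
    truth = _pick_regulators(config, regions, rng)
    manifest = config.manifest()

    cat_mean = {
        "ubiquitous": config.se_signal_mean,
        "subtype_specific": config.se_signal_mean,
        "line_specific": config.se_signal_mean,
        "typical": config.typical_signal_mean,
    }
    input_sd = config.input_signal_mean / 2.0

    peaks: dict[str, list[Peak]] = {}
    for row in manifest.itertuples(index=False):
        sample_peaks: list[Peak] = []
        for region in regions:
            if row.line not in region.lines_present:
                continue
            if region.category != "typical" and config.dropout_rate > 0:
                if rng.random() < config.dropout_rate:
                    continue
            n = len(region.peak_intervals)
            chip = _gamma_draws(rng, cat_mean[region.category], config.noise_sd, n)
            inp = _gamma_draws(rng, config.input_signal_mean, input_sd, n)
            for iv, cd, bd in zip(region.peak_intervals, chip, inp):
                sample_peaks.append(Peak(iv, float(cd), float(bd)))
        sample_peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
        peaks[row.sample] = sample_peaks
    return Landscape(peaks, annotation, manifest, truth, config)


@dataclass
class ExpressionData:
    """Expression matrix (genes x samples), labels and the regulon set."""

    expression: pd.DataFrame
    subtype_labels: pd.Series  # index: sample
    regulons: list["Regulon"]  # imported lazily to avoid a cycle
    target_map: dict[str, list[str]]


def generate_expression(config: SimConfig, truth: TruthTable) -> ExpressionData:
    """Expression matrix with planted regulator activity, plus regulons.

    Targets of a planted-active regulator shift by mode x sign x
    activity_effect (log2 scale) in the samples of the designated subtype;
    all other genes are exchangeable across subtypes.  The matrix is
    emitted on the linear scale as ``2**L - 1`` so that a downstream
    log2(1 + x) transform recovers the simulated log values exactly.
    """
    from .activity import Regulon

    config.validate()
    ss = np.random.SeedSequence([config.seed, 1])
    rng = np.random.default_rng(ss)

    manifest = config.manifest()
    samples = manifest["sample"].tolist()
    subtype_of_sample = pd.Series(
        manifest["subtype"].to_numpy(), index=manifest["sample"]
    )

    planted_gene_ids = [r.gene_id for r in truth.planted_regions]
    n_background = config.n_genes - len(planted_gene_ids)
    genes = planted_gene_ids + [f"G_BG{i + 1:04d}" for i in range(n_background)]

    lo, hi = config.expression_baseline
    base = rng.uniform(lo, hi, size=len(genes))
    log_expr = base[:, None] + rng.normal(
        0.0, config.noise_sd, size=(len(genes), len(samples))
    )
    log_expr = pd.DataFrame(log_expr, index=genes, columns=samples)

    # disjoint target pools drawn from background genes
    bg_pool = [g for g in genes if g.startswith("G_BG")]
    rng.shuffle(bg_pool)
    regulator_ids = [reg for reg, _, _ in truth.planted_active_regulators]
    regulator_ids += [d for d in truth.decoy_regulators if d not in regulator_ids]
    regulator_ids = regulator_ids[: config.n_regulators]

    regulons: list[Regulon] = []
    target_map: dict[str, list[str]] = {}
    offset = 0
    active_lookup = {reg: (st, sign) for reg, st, sign in truth.planted_active_regulators}
    for reg in regulator_ids:
        targets = bg_pool[offset: offset + config.targets_per_regulator]
        offset += config.targets_per_regulator
        modes = tuple(1.0 if rng.random() < 0.7 else -1.0 for _ in targets)
        weights = tuple(float(w) for w in rng.uniform(0.5, 1.0, size=len(targets)))
        regulons.append(Regulon(reg, tuple(targets), modes, weights))
        target_map[reg] = list(targets)
        if reg in active_lookup and config.activity_effect > 0:
            subtype, sign = active_lookup[reg]
            cols = (subtype_of_sample == subtype).to_numpy()
            for t, m in zip(targets, modes):
                log_expr.loc[t, log_expr.columns[cols]] += m * sign * config.activity_effect
            if reg in log_expr.index:
                log_expr.loc[reg, log_expr.columns[cols]] += sign * config.activity_effect

    expression = np.power(2.0, log_expr) - 1.0
    return ExpressionData(expression, subtype_of_sample, regulons, target_map)
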