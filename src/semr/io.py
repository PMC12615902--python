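"""Readers and writers for the plain-text formats the pipeline exchanges.

Coordinates are BED-dialect throughout: 0-based, half-open.  Peaks travel
as narrowPeak-style BED (chrom, start, end, name, score, strand,
signalValue = ChIP density per bp) with a two-column sidecar TSV carrying
the matched input density per peak name.  bedGraph tracks are accepted as
an alternative density source, reduced to a length-weighted mean over
each peak.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .association import GeneAnnotation
from .calling import Peak, SECallSet
from .intervals import GenomicInterval
from .landscape import ConsensusSE, PresenceMatrix


# ---------------------------------------------------------------- peaks

def write_narrowpeak(path: Path | str, peaks: Iterable[Peak],
                     sidecar_path: Path | str | None = None) -> None:
    """Write peaks as BED6+1 (signalValue = ChIP density) plus input sidecar."""
    path = Path(path)
    lines = []
    sidecar = []
    for i, p in enumerate(peaks, 1):
        name = f"peak_{i:06d}"
        iv = p.interval
        lines.append(
            f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}"
            f"\t{p.chip_density:.6g}"
        )
        sidecar.append(f"{name}\t{p.input_density:.6g}")
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    if sidecar_path is not None:
        Path(sidecar_path).write_text("\n".join(sidecar) + ("\n" if sidecar else ""))


def read_peaks(path: Path | str,
               sidecar_path: Path | str | None = None) -> list[Peak]:
    """Read narrowPeak-style BED; signalValue column is the ChIP density.

    The optional sidecar TSV (name, input density) supplies the matched
    input; absent entries default to 0.
    """
    input_of: dict[str, float] = {}
    if sidecar_path is not None:
        for ln, line in enumerate(Path(sidecar_path).read_text().splitlines(), 1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{sidecar_path}:{ln}: expected 2 columns")
            input_of[parts[0]] = float(parts[1])
    peaks = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 7:
            raise ValueError(f"{path}:{ln}: need >= 7 columns (signalValue)")
        chrom, start, end, name, _score, strand = parts[:6]
        iv = GenomicInterval(chrom, int(start), int(end), strand)
        peaks.append(Peak(iv, float(parts[6]), input_of.get(name, 0.0)))
    return peaks


def mean_density_from_bedgraph(path: Path | str,
                               intervals: list[GenomicInterval]) -> np.ndarray:
    """Length-weighted mean bedGraph value over each query interval.

    Bases not covered by any bedGraph record count as 0.
    """
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValueError(f"{path}:{ln}: bedGraph needs 4 columns")
        by_chrom.setdefault(parts[0], []).append(
            (int(parts[1]), int(parts[2]), float(parts[3]))
        )
    for recs in by_chrom.values():
        recs.sort()
    out = np.zeros(len(intervals))
    for i, iv in enumerate(intervals):
        total = 0.0
        for s, e, v in by_chrom.get(iv.chrom, []):
            lo, hi = max(s, iv.start), min(e, iv.end)
            if lo < hi:
                total += v * (hi - lo)
        out[i] = total / iv.length
    return out


# ----------------------------------------------------------- annotation

def write_gene_bed(path: Path | str, genes: Iterable[GeneAnnotation]) -> None:
    lines = [
        f"{g.interval.chrom}\t{g.interval.start}\t{g.interval.end}"
        f"\t{g.gene_id}\t0\t{g.interval.strand}"
        for g in genes
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_gene_bed(path: Path | str) -> list[GeneAnnotation]:
    genes = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        if len(parts) < 6:
            raise ValueError(f"{path}:{ln}: BED6 needs 6 columns")
        try:
            iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]), parts[5])
        except ValueError as err:
            raise ValueError(f"{path}:{ln}: {err}") from err
        genes.append(GeneAnnotation(parts[3], iv))
    return genes


# ------------------------------------------------------- manifest & expr

def write_manifest(path: Path | str, manifest: pd.DataFrame) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def read_manifest(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"replicate": int})
    required = {"sample", "line", "subtype"}
    if not required <= set(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    return df


def write_expression(path: Path | str, expression: pd.DataFrame) -> None:
    expression.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")


def read_expression(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


# -------------------------------------------------------------- regulons

def write_regulons(path: Path | str, regulons) -> None:
    lines = ["regulator\ttarget\tmode\tlikelihood"]
    for reg in regulons:
        for t, m, w in zip(reg.targets, reg.modes, reg.weights):
            lines.append(f"{reg.regulator}\t{t}\t{m:g}\t{w:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_regulons(path: Path | str):
    """Read regulon TSV; the 3-column variant gets weight 1 per target."""
    from .activity import Regulon

    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    if len(cols) < 3:
        raise ValueError("regulon table needs >= 3 columns (regulator, target, mode)")
    if "likelihood" not in df.columns:
        df["likelihood"] = 1.0
    regulons = []
    for reg, sub in df.groupby(df.columns[0], sort=True):
        regulons.append(
            Regulon(
                str(reg),
                tuple(sub.iloc[:, 1].astype(str)),
                tuple(sub["mode"].astype(float)),
                tuple(sub["likelihood"].astype(float)),
            )
        )
    return regulons


# ------------------------------------------------------------ SE calls

def write_se_calls(call_set: SECallSet, tsv_path: Path | str,
                   bed_path: Path | str | None = None,
                   meta_path: Path | str | None = None) -> None:
    rows = []
    for region, rank, flag in zip(call_set.regions, call_set.ranks, call_set.is_super):
        iv = region.interval
        rows.append(
            f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rank}\t{region.signal:.6g}"
            f"\t{int(flag)}"
        )
    header = "chrom\tstart\tend\trank\tsignal\tis_super"
    Path(tsv_path).write_text("\n".join([header] + rows) + "\n")
    if bed_path is not None:
        bed = [
            f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}"
            f"\tSE_{i}\t0\t."
            for i, r in enumerate(call_set.super_regions(), 1)
        ]
        Path(bed_path).write_text("\n".join(bed) + ("\n" if bed else ""))
    if meta_path is not None:
        meta = {
            "sample": call_set.sample,
            "n_regions": len(call_set.regions),
            "n_super": call_set.n_super,
            "cutoff_value": call_set.cutoff_value,
            "cutoff_index": call_set.cutoff_index,
            "d_stitch": call_set.d_stitch,
            "tss_window": call_set.tss_window,
        }
        Path(meta_path).write_text(json.dumps(meta, indent=2) + "\n")


def read_se_calls(tsv_path: Path | str, sample: str) -> SECallSet:
    """Rebuild a call set (regions, signal, flags) from a written TSV.

    Constituent peaks are not stored in the TSV, so the returned regions
    carry empty constituent lists; consolidation only needs intervals,
    signal and the super flag.
    """
    from .calling import StitchedRegion

    df = pd.read_csv(tsv_path, sep="\t")
    regions = [
        StitchedRegion(GenomicInterval(r.chrom, int(r.start), int(r.end)), [],
                       float(r.signal))
        for r in df.itertuples(index=False)
    ]
    is_super = df["is_super"].astype(bool).to_numpy()
    supers = df.loc[df["is_super"] == 1, "signal"]
    cutoff = float(supers.min()) if len(supers) else float("nan")
    return SECallSet(sample, regions, df["rank"].to_numpy(), cutoff,
                     int(len(df) - is_super.sum()), is_super)


# ----------------------------------------------------------- landscape

def write_consensus(consensus: list[ConsensusSE], pm: PresenceMatrix,
                    categories: pd.Series, outdir: Path | str) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bed = [
        f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}\t{c.se_id}\t0\t."
        for c in consensus
    ]
    (outdir / "consensus_se.bed").write_text("\n".join(bed) + ("\n" if bed else ""))
    pm.table.astype(int).to_csv(outdir / "presence_matrix.tsv", sep="\t",
                                index_label="se_id")
    categories.rename("category").to_csv(outdir / "se_categories.tsv", sep="\t",
                                         index_label="se_id")


def write_truth(path: Path | str, truth) -> None:
    payload = {
        "n_lines": truth.n_lines,
        "planted_regions": [
            {
                "region_id": r.region_id,
                "chrom": r.interval.chrom,
                "start": r.interval.start,
                "end": r.interval.end,
                "category": r.category,
                "lines_present": list(r.lines_present),
                "gene_id": r.gene_id,
                "subtype": r.subtype,
            }
            for r in truth.planted_regions
        ],
        "planted_active_regulators": [
            {"regulator": reg, "subtype": st, "sign": sign}
            for reg, st, sign in truth.planted_active_regulators
        ],
        "candidate_regulators": truth.candidate_regulators,
        "decoy_regulators": truth.decoy_regulators,
        "identity_genes": truth.identity_genes,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
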