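"""Call super-enhancers per sample: stitch H3K27ac peaks at 12.5 kb,
exclude promoter-proximal peaks (+/- 2.5 kb of a TSS), quantify
background-subtracted signal, rank, and apply the hockey-stick tangent
cutoff.  Writes one ranked table + SE BED + cutoff metadata per sample
under results/se_calls/.
"""

from pathlib import Path

from semr import io as io_mod
from semr.calling import call_superenhancers

ROOT = Path(__file__).resolve().parents[1] / "results"
DATASET, OUT = ROOT / "dataset", ROOT / "se_calls"


def main() -> None:
    genes = io_mod.read_gene_bed(DATASET / "genes.bed")
    tss_list = [(g.interval.chrom, g.tss) for g in genes]
    OUT.mkdir(parents=True, exist_ok=True)
    for peak_file in sorted((DATASET / "peaks").glob("*.narrowPeak")):
        sample = peak_file.stem
        peaks = io_mod.read_peaks(peak_file,
                                  DATASET / "peaks" / f"{sample}.input.tsv")
        cs = call_superenhancers(peaks, sample=sample, tss_list=tss_list)
        io_mod.write_se_calls(cs, OUT / f"{sample}.calls.tsv",
                              OUT / f"{sample}.se.bed",
                              OUT / f"{sample}.cutoff.json")
        print(f"{sample}: {len(cs.regions)} stitched regions, "
              f"{cs.n_super} super (cutoff {cs.cutoff_value:.0f})")


if __name__ == "__main__":
    main()
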