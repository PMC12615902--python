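"""Generate the synthetic study: 10 cell lines x 2 replicates of H3K27ac
peak landscapes with planted super-enhancer structure (40 ubiquitous, 40
subtype-specific, 100 line-specific, 1000 typical enhancers), a matched
expression matrix with 3 planted-active regulators anchored on
ubiquitous-SE genes plus 3 decoys, and the truth table.

Writes per-sample peak files and all pipeline inputs under
results/dataset/.
"""

from pathlib import Path

from semr import io as io_mod
from semr.simulate import SimConfig, generate_expression, generate_landscape

OUT = Path(__file__).resolve().parents[1] / "results" / "dataset"


def main(seed: int = 1) -> None:
    config = SimConfig(seed=seed)
    sim = generate_landscape(config)
    expr = generate_expression(config, sim.truth)

    (OUT / "peaks").mkdir(parents=True, exist_ok=True)
    for sample, peaks in sim.peaks.items():
        io_mod.write_narrowpeak(OUT / "peaks" / f"{sample}.narrowPeak", peaks,
                                OUT / "peaks" / f"{sample}.input.tsv")
    io_mod.write_gene_bed(OUT / "genes.bed", sim.annotation)
    io_mod.write_manifest(OUT / "manifest.tsv", sim.manifest)
    io_mod.write_expression(OUT / "expression.tsv", expr.expression)
    io_mod.write_regulons(OUT / "regulons.tsv", expr.regulons)
    io_mod.write_truth(OUT / "truth.json", sim.truth)

    n_peaks = sum(len(p) for p in sim.peaks.values())
    print(f"wrote {len(sim.peaks)} samples ({n_peaks} peaks total) to {OUT}")
    print(f"planted: {len(sim.truth.planted_regions)} regions, "
          f"{len(sim.truth.planted_active_regulators)} active regulators, "
          f"candidates = {sim.truth.candidate_regulators}")


if __name__ == "__main__":
    main()
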