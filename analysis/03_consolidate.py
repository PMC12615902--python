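"""Consolidate per-sample SE calls into the consensus landscape: merge
overlapping SEs across samples (single-linkage, >= 1 bp), collapse
replicates to cell-line presence, classify each consensus SE as
ubiquitous (> 2/3 of lines), line-specific (exactly 1) or shared, and
cluster the lines on the 200 most variable SE regions.

Writes the consensus BED, presence matrix, categories, per-line signal
and line dendrogram under results/consensus/.
"""

from pathlib import Path

from semr import io as io_mod, landscape

ROOT = Path(__file__).resolve().parents[1] / "results"
CALLS, OUT = ROOT / "se_calls", ROOT / "consensus"


def main() -> None:
    manifest = io_mod.read_manifest(ROOT / "dataset" / "manifest.tsv")
    call_sets = [
        io_mod.read_se_calls(p, p.name.removesuffix(".calls.tsv"))
        for p in sorted(CALLS.glob("*.calls.tsv"))
    ]
    consensus, pm = landscape.consolidate(
        call_sets, dict(zip(manifest["sample"], manifest["line"]))
    )
    categories = landscape.categorize(consensus, pm)
    io_mod.write_consensus(consensus, pm, categories, OUT)

    signal = landscape.line_signal_matrix(consensus)
    signal.to_csv(OUT / "line_signal.tsv", sep="\t", index_label="se_id")
    top = landscape.top_variable_regions(signal, min(200, signal.shape[0]))
    linkage, _ = landscape.cluster_lines(top)
    (OUT / "line_dendrogram.nwk").write_text(
        landscape.dendrogram_newick(linkage, list(top.columns)) + "\n"
    )

    counts = categories.value_counts().to_dict()
    print(f"{len(consensus)} consensus SEs across {pm.n_lines} lines "
          f"(ubiquity threshold k_min = {pm.k_min})")
    print(f"categories: {counts}")


if __name__ == "__main__":
    main()
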