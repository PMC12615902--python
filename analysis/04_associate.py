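"""Associate consensus SEs with genes within +/- 10 kb of the gene body
and test whether ubiquitous-SE-associated genes are enriched in the
planted identity gene set (Fisher's exact test with odds ratio and 95%
CI), with line-specific SEs as the contrast.

Writes the link table and enrichment results under results/association/.
"""

import json
from pathlib import Path

import pandas as pd

from semr import association, io as io_mod
from semr.intervals import GenomicInterval
from semr.landscape import ConsensusSE

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "association"


def main() -> None:
    consensus = []
    for line in (ROOT / "consensus" / "consensus_se.bed").read_text().splitlines():
        parts = line.split("\t")
        consensus.append(ConsensusSE(
            parts[3], GenomicInterval(parts[0], int(parts[1]), int(parts[2])),
            [], {}, {},
        ))
    genes = io_mod.read_gene_bed(ROOT / "dataset" / "genes.bed")
    categories = pd.read_csv(ROOT / "consensus" / "se_categories.tsv",
                             sep="\t", index_col="se_id")["category"]
    truth = json.loads((ROOT / "dataset" / "truth.json").read_text())

    links = association.associate_genes(consensus, genes)
    links["category"] = links["se_id"].map(categories)
    OUT.mkdir(parents=True, exist_ok=True)
    links.to_csv(OUT / "links.tsv", sep="\t", index=False)

    universe = {g.gene_id for g in genes}
    identity = set(truth["identity_genes"])
    results = {}
    for category in ("ubiquitous", "line_specific"):
        query = set(links.loc[links["category"] == category, "gene_id"])
        enr = association.gene_set_enrichment_fisher(query, identity, universe)
        results[category] = {
            "table": [enr.a, enr.b, enr.c, enr.d],
            "odds_ratio": enr.odds_ratio,
            "ci": [enr.ci_low, enr.ci_high],
            "p": enr.p_value,
        }
        print(f"{category}: {len(query)} genes, OR = {enr.odds_ratio:.2f} "
              f"[{enr.ci_low:.2f}, {enr.ci_high:.2f}], p = {enr.p_value:.3g}")
    (OUT / "identity_enrichment.json").write_text(
        json.dumps(results, indent=2) + "\n"
    )
    print(f"{len(links)} SE-gene links, "
          f"{links['gene_id'].nunique()} distinct genes")


if __name__ == "__main__":
    main()
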