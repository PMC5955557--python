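"""RPKM-normalize the count matrix and run the differential screen.

Retains genes with |fold change| > 1.5 and Welch p < 0.01
(treatment vs. control) and compares the retained set against the
planted differential-expression truth.
"""

import json

import pandas as pd

from kinomevo import expression, structure

from common import RESULTS, SIM_DIR


def main() -> None:
    counts = pd.read_csv(SIM_DIR / "counts.tsv", sep="\t", index_col=0)
    groups = pd.read_csv(SIM_DIR / "samples.tsv", sep="\t")
    lengths = structure.gene_table_from_gff(
        str(SIM_DIR / "genome.gff3")
    ).set_index("gene_id")["cds_length"]
    norm = expression.rpkm(counts, lengths)
    norm.to_csv(RESULTS / "rpkm.tsv", sep="\t")
    res = expression.differential_screen(norm, groups)
    res.to_csv(RESULTS / "de_results.tsv", sep="\t", index=False)

    truth = json.loads((SIM_DIR / "truth.json").read_text())
    planted = set(truth["de_genes"])
    retained = set(res.loc[res["retained"], "gene_id"])
    print(
        f"{len(retained)} of {len(res)} genes retained "
        f"(|FC| > 1.5 and p < 0.01); "
        f"{len(planted & retained)} of {len(planted)} planted DE genes recovered"
    )
    top = res[res["retained"]].reindex(
        res[res["retained"]]["log2fc"].abs().sort_values(ascending=False).index
    )
    for row in top.head(5).itertuples(index=False):
        print(f"  {row.gene_id}  log2FC {row.log2fc:+.2f}  p {row.p_value:.2e}")


if __name__ == "__main__":
    main()
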