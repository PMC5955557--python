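"""Classify the simulated kinome from domain-hit and HMM-score evidence.

Gates typical kinases (E < 0.01 and model coverage > 50%), assigns each
to its best-scoring subfamily and group, counts multi-domain proteins,
and writes results/classification.tsv.
"""

from kinomevo import identify

from common import RESULTS, SIM_DIR


def main() -> None:
    hits = identify.read_hits(str(SIM_DIR / "hits.tsv"))
    scores = identify.read_scores(str(SIM_DIR / "scores.tsv"))
    table = identify.classify_kinome(hits, scores)
    table.to_csv(RESULTS / "classification.tsv", sep="\t", index=False)
    typical = table[table["status"] == "typical"]
    print(
        f"{len(typical)} typical PKs, "
        f"{(table['status'] == 'atypical').sum()} atypical, "
        f"{(table['status'] == 'non_kinase').sum()} hit-bearing non-kinases"
    )
    print("typical PKs per group:")
    for group, n in typical.groupby("group").size().items():
        print(f"  {group:6s} {n}")
    multi = typical[typical["n_kinase_domains"] >= 2]
    print(f"{len(multi)} PKs carry 2-4 kinase domains")


if __name__ == "__main__":
    main()
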