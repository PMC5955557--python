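"""Generate the two synthetic genomes and every downstream input table.

Writes protein/CDS FASTA, GFF3, hit/score/homology/count tables and the
ground-truth record under results/sim (primary species) and
results/sim_b (second species, used for cross-species structure
conservation).
"""

from kinomevo import simulate

from common import SIM_B_DIR, SIM_DIR, demo_config


def main() -> None:
    cfg = demo_config()
    genome = simulate.simulate_all(cfg.sim, SIM_DIR)
    genome_b = simulate.simulate_all(cfg.second_species, SIM_B_DIR)
    for name, g in ((cfg.sim.species, genome), (cfg.second_species.species, genome_b)):
        counts = {"typical": 0, "atypical": 0, "non_kinase": 0}
        for d in g.truth.genes.values():
            counts[d["typicality"]] += 1
        print(
            f"{name}: {len(g.genes)} genes "
            f"({counts['typical']} typical PK, {counts['atypical']} atypical, "
            f"{counts['non_kinase']} non-kinase); "
            f"{len(g.truth.tandem_clusters)} tandem arrays, "
            f"{len(g.truth.collinear_blocks)} collinear blocks planted"
        )
    print(f"inputs written under {SIM_DIR} and {SIM_B_DIR}")


if __name__ == "__main__":
    main()
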