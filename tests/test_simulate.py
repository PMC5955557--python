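"""Generator contracts: bookkeeping, determinism, coding integrity, Ks targets."""

import filecmp

import numpy as np
import pytest
from Bio.Seq import Seq

from kinomevo import duplication, simulate


def test_gene_counts_and_unique_ids(demo_genome, demo_config):
    genes = demo_genome.genes
    assert len(genes) == demo_config.n_chromosomes * demo_config.genes_per_chromosome
    assert len({g.gene_id for g in genes}) == len(genes)


def test_every_cds_translates_without_internal_stops(demo_genome):
    for g in demo_genome.genes:
        assert len(g.cds) % 3 == 0
        protein = str(Seq(g.cds).translate())
        assert "*" not in protein
        assert protein == g.protein
        assert sum(g.exon_coding_lengths) == len(g.cds)


def test_coordinates_sorted_and_non_overlapping(demo_genome):
    by_chrom: dict[str, list] = {}
    for g in demo_genome.genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for genes in by_chrom.values():
        for a, b in zip(genes, genes[1:]):
            assert a.end < b.start
        for g in genes:
            segs = g.cds_segments
            assert segs == sorted(segs)
            assert all(e1 < s2 for (_, e1), (s2, _) in zip(segs, segs[1:]))


def test_same_seed_gives_identical_output_bytes(demo_config, tmp_path):
    simulate.simulate_all(demo_config, tmp_path / "a")
    simulate.simulate_all(demo_config, tmp_path / "b")
    for f in (tmp_path / "a").iterdir():
        assert filecmp.cmp(f, tmp_path / "b" / f.name, shallow=False), f.name


def test_tandem_array_occupies_consecutive_ranks(demo_genome, demo_config):
    spec = demo_config.tandem_arrays[0]
    cluster = demo_genome.truth.tandem_clusters[0]
    members = cluster["members"]
    assert len(members) == spec.size
    ranks = [demo_genome.truth.genes[m]["rank"] for m in members]
    assert ranks == list(range(spec.start_rank, spec.start_rank + spec.size))
    for m in members:
        assert demo_genome.truth.genes[m]["subfamily"] == spec.subfamily


def test_collinear_duplicates_preserve_exon_structure(demo_genome):
    by_id = {g.gene_id: g for g in demo_genome.genes}
    for block in demo_genome.truth.collinear_blocks:
        for a, b in block["anchors"]:
            assert by_id[a].exon_coding_lengths == by_id[b].exon_coding_lengths
            assert by_id[a].domain_spans == by_id[b].domain_spans


def test_overlapping_planted_structures_rejected():
    cfg = simulate.SimConfig(
        seed=0,
        tandem_arrays=[
            simulate.TandemArraySpec(1, 5, 3, "CAMK_CDPK"),
            simulate.TandemArraySpec(1, 6, 2, "CMGC_MAPK"),
        ],
    )
    with pytest.raises(simulate.ConfigError, match="overlap"):
        simulate.simulate_genome(cfg)


def test_out_of_bounds_planted_structure_rejected():
    cfg = simulate.SimConfig(
        seed=0,
        genes_per_chromosome=10,
        tandem_arrays=[simulate.TandemArraySpec(1, 9, 3, "CAMK_CDPK")],
    )
    with pytest.raises(simulate.ConfigError):
        simulate.simulate_genome(cfg)


class TestEvolveDuplicate:
    @pytest.fixture(scope="class")
    @staticmethod
    def source():
        rng = np.random.default_rng(12)
        return "ATG" + "".join(rng.choice(duplication.NON_STOP_CODONS, size=499))

    def test_zero_target_returns_input(self, source):
        assert simulate.evolve_duplicate(source, 0.0, seed=1) == source

    @pytest.mark.parametrize(
        "target,lo,hi", [(0.5, 0.4, 0.6), (0.05, 0.0, 0.1)]
    )
    def test_measured_ks_hits_target_window(self, source, target, lo, hi):
        dup = simulate.evolve_duplicate(source, target, seed=99)
        r = duplication.kaks(source, dup)
        assert lo <= r.ks <= hi
        assert abs(r.ks - target) <= 0.1

    def test_nonsynonymous_changes_follow_configured_ratio(self, source):
        dup = simulate.evolve_duplicate(source, 0.5, seed=5, ka_ks_ratio=0.3)
        r = duplication.kaks(source, dup)
        assert r.ka > 0
        assert r.ka / r.ks == pytest.approx(0.3, abs=0.1)

    def test_saturating_target_raises(self, source):
        with pytest.raises(ValueError, match="saturation"):
            simulate.evolve_duplicate(source, 10.0, seed=1)

    def test_same_length_and_no_stops(self, source):
        dup = simulate.evolve_duplicate(source, 0.4, seed=3)
        assert len(dup) == len(source)
        assert "*" not in str(Seq(dup).translate())


class TestDomainHits:
    def test_atypical_fraction_is_exact(self):
        cfg = simulate.SimConfig(
            seed=8, n_chromosomes=2, genes_per_chromosome=50,
            atypical_fraction=0.1, nonkinase_fraction=0.0,
            multidomain_counts={},
        )
        genome = simulate.simulate_genome(cfg)
        hits, _ = simulate.simulate_domain_hits(genome)
        hits = hits.copy()
        hits["cov"] = (hits.model_end - hits.model_start + 1) / hits.model_length
        low = hits.groupby("gene_id")["cov"].max() <= 0.5
        assert int(low.sum()) == 10
        truth_atypical = {
            g for g, d in genome.truth.genes.items() if d["typicality"] == "atypical"
        }
        assert set(low.index[low]) == truth_atypical

    def test_multidomain_genes_get_nonoverlapping_qualifying_hits(self, demo_genome, demo_evidence):
        hits, _, _ = demo_evidence
        for gid, d in demo_genome.truth.genes.items():
            if d["n_domains"] < 2:
                continue
            sub = hits[hits.gene_id == gid].sort_values("seq_start")
            assert len(sub) == d["n_domains"]
            spans = list(zip(sub.seq_start, sub.seq_end))
            assert all(e < s2 for (_, e), (s2, _) in zip(spans, spans[1:]))
            cov = (sub.model_end - sub.model_start + 1) / sub.model_length
            assert (cov > 0.5).all() and (sub.evalue < 0.01).all()

    def test_score_table_argmax_equals_truth_subfamily(self, demo_genome, demo_evidence):
        _, scores, _ = demo_evidence
        best = scores.sort_values("bit_score").drop_duplicates("gene_id", keep="last")
        for gid, sub in zip(best.gene_id, best.subfamily):
            assert demo_genome.truth.genes[gid]["subfamily"] == sub


class TestCounts:
    def test_determinism(self, demo_genome):
        c1, _ = simulate.simulate_counts(demo_genome)
        c2, _ = simulate.simulate_counts(demo_genome)
        assert c1.equals(c2)

    def test_planted_fold_change_in_low_dispersion_limit(self):
        cfg = simulate.SimConfig(
            seed=21, n_chromosomes=1, genes_per_chromosome=50,
            nonkinase_fraction=0.0, atypical_fraction=0.0, multidomain_counts={},
            expression=simulate.ExpressionConfig(
                n_samples_per_group=50, planted_log2fc=2.0,
                dispersion=0.0, n_de_genes=10,
            ),
        )
        genome = simulate.simulate_genome(cfg)
        counts, groups = simulate.simulate_counts(genome)
        t = groups[groups.group == "treatment"]["sample"]
        c = groups[groups.group == "control"]["sample"]
        for gid, lfc in genome.truth.de_genes.items():
            ratio = counts.loc[gid, t].mean() / counts.loc[gid, c].mean()
            assert ratio == pytest.approx(2.0 ** lfc, rel=0.25)
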