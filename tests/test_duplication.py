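"""NG86 Ka/Ks, epochs, homology filtering, tandem and collinear detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinomevo import duplication, simulate

from .oracles import brute_counts, brute_sites

codons = st.sampled_from(duplication.NON_STOP_CODONS)


class TestNg86Sites:
    def test_phenylalanine(self):
        s, n = duplication.ng86_sites("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_methionine_has_no_synonymous_sites(self):
        assert duplication.ng86_sites("ATG") == (0.0, 3.0)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            duplication.ng86_sites("TAA")

    @given(codons)
    @settings(max_examples=61, deadline=None)
    def test_site_conservation_and_oracle_agreement(self, codon):
        s, n = duplication.ng86_sites(codon)
        assert s + n == pytest.approx(3.0)
        bs, bn = brute_sites(codon)
        assert s == pytest.approx(bs)
        assert n == pytest.approx(bn)


class TestNg86Counts:
    def test_single_synonymous_difference(self):
        assert duplication.ng86_counts("TTT", "TTC") == (1.0, 0.0)

    def test_two_step_pathway_average(self):
        sd, nd = duplication.ng86_counts("TTT", "GTA")
        assert (sd, nd) == (0.5, 1.5)

    def test_identity(self):
        assert duplication.ng86_counts("ACG", "ACG") == (0.0, 0.0)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a, b = rng.choice(duplication.NON_STOP_CODONS, size=2)
            ab = duplication.ng86_counts(str(a), str(b))
            ba = duplication.ng86_counts(str(b), str(a))
            assert ab == pytest.approx(ba)

    @given(codons, codons)
    @settings(max_examples=200, deadline=None)
    def test_matches_exhaustive_pathway_enumeration(self, a, b):
        expected = brute_counts(a, b)
        got = duplication.ng86_counts(a, b)
        if expected is not None:
            assert got[0] == pytest.approx(expected[0])
            assert got[1] == pytest.approx(expected[1])
        else:
            # all pathways stop-blocked: fallback counts every step
            n_diff = sum(x != y for x, y in zip(a, b))
            assert got[0] + got[1] == pytest.approx(n_diff)


class TestKaks:
    def test_identical_sequences(self):
        cds = "ATGTTTGGGCCCAAA"
        r = duplication.kaks(cds, cds)
        assert r.ks == 0.0 and r.ka == 0.0
        assert r.epoch == "tetraploid"  # Ks 0 falls in the [0, 0.1) bin

    def test_site_conservation_over_sequences(self):
        rng = np.random.default_rng(4)
        a = "".join(rng.choice(duplication.NON_STOP_CODONS, size=100))
        b = "".join(rng.choice(duplication.NON_STOP_CODONS, size=100))
        r = duplication.kaks(a, b)
        assert r.s_sites + r.n_sites == pytest.approx(3 * r.n_codons)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            duplication.kaks("ATGTTT", "ATG")

    def test_gap_codons_dropped_pairwise(self):
        r = duplication.kaks("ATG---TTT", "ATGAAATTC")
        assert r.n_codons == 2
        assert r.sd == 1.0 and r.nd == 0.0

    def test_saturated_pair_labeled(self):
        # maximally different codons everywhere → pS/pN beyond the JC limit
        a = "GGG" * 200
        b = "CCC" * 200
        r = duplication.kaks(a, b)
        assert r.epoch == "saturated"
        assert r.ks is None or r.ka is None

    def test_round_trip_with_generator(self):
        rng = np.random.default_rng(5)
        src = "ATG" + "".join(rng.choice(duplication.NON_STOP_CODONS, size=499))
        dup = simulate.evolve_duplicate(src, 0.5, seed=11)
        r = duplication.kaks(src, dup)
        assert 0.4 <= r.ks <= 0.6


class TestAssignEpoch:
    @pytest.mark.parametrize(
        "ks,label",
        [
            (0.05, "tetraploid"),
            (0.0, "tetraploid"),
            (0.5, "wgd_recent"),
            (0.4, "wgd_recent"),
            (0.6, "ancient"),
            (2.0, "ancient"),
            (0.2, "unassigned"),
            (3.5, "unassigned"),
            (None, "saturated"),
        ],
    )
    def test_bins(self, ks, label):
        assert duplication.assign_epoch(ks) == label

    @given(st.floats(0, 5, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_every_ks_maps_to_exactly_one_label(self, ks):
        label = duplication.assign_epoch(ks)
        in_bins = [lo <= ks < hi for lo, hi, _ in duplication.KS_EPOCH_BINS]
        assert sum(in_bins) == (0 if label == "unassigned" else 1)


class TestFilterHomology:
    def test_threshold_and_dedup(self):
        pairs = pd.DataFrame(
            {
                "gene_a": ["a", "b", "x", "c"],
                "gene_b": ["b", "a", "y", "c"],
                "evalue": [1e-120, 1e-150, 1e-50, 1e-200],
            }
        )
        out = duplication.filter_homology(pairs)
        assert len(out) == 1
        assert out.iloc[0]["gene_a"] == "a" and out.iloc[0]["gene_b"] == "b"
        assert out.iloc[0]["evalue"] == 1e-150

    def test_boundary_kept(self):
        pairs = pd.DataFrame({"gene_a": ["a"], "gene_b": ["b"], "evalue": [1e-100]})
        assert len(duplication.filter_homology(pairs)) == 1


def ranks_df(spec):
    """spec: {gene: (chrom, rank)}"""
    return pd.DataFrame(
        [{"gene_id": g, "chromosome": c, "rank": r} for g, (c, r) in spec.items()]
    )


def hompairs(*pairs):
    return pd.DataFrame(
        [{"gene_a": a, "gene_b": b, "evalue": 1e-150} for a, b in pairs]
    )


class TestTandemClusters:
    def test_chain_of_consecutive_homologs(self):
        ranks = ranks_df({"g5": ("chr01", 5), "g6": ("chr01", 6), "g7": ("chr01", 7)})
        clusters = duplication.tandem_clusters(
            ranks, hompairs(("g5", "g6"), ("g6", "g7"))
        )
        assert len(clusters) == 1
        assert clusters[0].members == ["g5", "g6", "g7"]

    def test_gap_exceeded(self):
        ranks = ranks_df({"g5": ("chr01", 5), "g9": ("chr01", 9)})
        assert duplication.tandem_clusters(ranks, hompairs(("g5", "g9"))) == []

    def test_cross_chromosome_pairs_ignored(self):
        ranks = ranks_df({"a": ("chr01", 5), "b": ("chr02", 6)})
        assert duplication.tandem_clusters(ranks, hompairs(("a", "b"))) == []

    def test_rank_gap_uses_all_genes_not_only_kinases(self, demo_genome, demo_evidence):
        _, _, homology = demo_evidence
        ranks = duplication.gene_ranks(demo_genome.gene_table())
        filtered = duplication.filter_homology(homology)
        clusters = duplication.tandem_clusters(ranks, filtered)
        truth = {
            tuple(c["members"]) for c in demo_genome.truth.tandem_clusters
        }
        assert {tuple(c.members) for c in clusters} == truth

    def test_clusters_never_span_chromosomes(self, demo_genome, demo_evidence):
        _, _, homology = demo_evidence
        ranks = duplication.gene_ranks(demo_genome.gene_table())
        pos = ranks.set_index("gene_id")["chromosome"]
        for c in duplication.tandem_clusters(ranks, duplication.filter_homology(homology)):
            assert len({pos[m] for m in c.members}) == 1


class TestCollinearBlocks:
    def make(self, coords, orientation="same"):
        ranks_a = {f"a{i}": ra for i, (ra, _) in enumerate(coords)}
        ranks_b = {f"b{i}": rb for i, (_, rb) in enumerate(coords)}
        pairs = hompairs(*[(f"a{i}", f"b{i}") for i in range(len(coords))])
        return ranks_a, ranks_b, pairs

    def test_planted_diagonal_recovered(self):
        ra, rb, pairs = self.make([(10 + i, 20 + i) for i in range(6)])
        blocks = duplication.collinear_blocks(ra, rb, pairs)
        assert len(blocks) == 1
        assert blocks[0].score == 6 and blocks[0].orientation == "same"

    def test_planted_antidiagonal_is_inverted(self):
        ra, rb, pairs = self.make([(10 + i, 40 - i) for i in range(6)])
        blocks = duplication.collinear_blocks(ra, rb, pairs)
        assert len(blocks) == 1
        assert blocks[0].orientation == "inverted"

    def test_short_chain_below_min_anchors_discarded(self):
        ra, rb, pairs = self.make([(10 + i, 20 + i) for i in range(4)])
        assert duplication.collinear_blocks(ra, rb, pairs, min_anchors=5) == []

    def test_rank_gap_limit_splits_chains(self):
        coords = [(10 + i, 20 + i) for i in range(5)]
        coords += [(100 + i, 110 + i) for i in range(5)]
        ra, rb, pairs = self.make(coords)
        blocks = duplication.collinear_blocks(ra, rb, pairs, max_rank_gap=25)
        assert len(blocks) == 2
        assert all(b.score == 5 for b in blocks)

    def test_recovery_with_decoys(self, demo_genome, demo_evidence):
        _, _, homology = demo_evidence
        ranks = duplication.gene_ranks(demo_genome.gene_table())
        rm = {
            c: dict(zip(sub["gene_id"], sub["rank"]))
            for c, sub in ranks.groupby("chromosome")
        }
        blocks = duplication.collinear_blocks(
            rm["chr01"], rm["chr02"], duplication.filter_homology(homology),
            "chr01", "chr02",
        )
        planted = [
            frozenset(map(tuple, b["anchors"]))
            for b in demo_genome.truth.collinear_blocks
        ]
        detected = [b.anchor_set for b in blocks]
        assert all(any(p <= d for d in detected) for p in planted)
        assert all(any(p <= d for p in planted) for d in detected)


class TestSingleCorrespondence:
    @pytest.mark.parametrize(
        "pairs,expected",
        [
            ([("a1", "b1"), ("a2", "b2")], 1.0),
            ([("a1", "b1"), ("a1", "b2")], 0.0),
            ([("a1", "b1"), ("a2", "b2"), ("a2", "b3")], 1 / 3),
        ],
    )
    def test_fraction(self, pairs, expected):
        df = pd.DataFrame(pairs, columns=["gene_a", "gene_b"])
        _, frac = duplication.single_correspondence(df)
        assert frac == pytest.approx(expected)


def test_ks_histogram_modes_on_planted_cohort():
    """Two planted epochs leave local histogram modes in their Ks windows."""
    rng = np.random.default_rng(9)
    ks_values = []
    for target, n in ((0.5, 40), (0.05, 40)):
        for _ in range(n):
            src = "ATG" + "".join(rng.choice(duplication.NON_STOP_CODONS, size=399))
            dup = simulate.evolve_duplicate(src, target, seed=int(rng.integers(2**31)))
            ks_values.append(duplication.kaks(src, dup).ks)
    hist = duplication.ks_histogram(ks_values)
    counts = hist.set_index("bin_left")["count"]
    assert counts.loc[0.0] == counts.max()
    assert counts.loc[[0.4, 0.5]].sum() == 40
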