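import pytest

from kinomevo import simulate


@pytest.fixture(scope="session")
def demo_config() -> simulate.SimConfig:
    """Small genome with every kind of planted structure."""
    return simulate.SimConfig(
        seed=101,
        species="testoid",
        n_chromosomes=2,
        genes_per_chromosome=60,
        tandem_arrays=[
            simulate.TandemArraySpec(1, 5, 3, "RLK-Pelle_LRR-XI-1"),
            simulate.TandemArraySpec(2, 30, 2, "CAMK_CDPK"),
        ],
        collinear_blocks=[
            simulate.CollinearBlockSpec(1, 2, 20, 12, 6, 0.5),
            simulate.CollinearBlockSpec(1, 2, 50, 45, 6, 0.05, "inverted"),
        ],
        decoy_homology_fraction=0.05,
    )


@pytest.fixture(scope="session")
def demo_genome(demo_config) -> simulate.SimulatedGenome:
    return simulate.simulate_genome(demo_config)


@pytest.fixture(scope="session")
def demo_evidence(demo_genome):
    hits, scores = simulate.simulate_domain_hits(demo_genome)
    homology = simulate.simulate_homology(demo_genome)
    return hits, scores, homology
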