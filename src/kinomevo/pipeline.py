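"""End-to-end pipeline over simulated (or user-supplied) inputs.

Wires the stages together — simulate → classify → tree → gene structure
→ duplication/Ka-Ks → expression — from one config, writes every stage
table under an output directory, and returns a machine-readable report
mirroring the quantities a kinome survey tabulates: kinase counts per
group, tandem clusters, collinearity events per Ks epoch, the
single-correspondence fraction, and differential-expression counts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import duplication, expression, identify, phylogeny, structure
from .simulate import (
    CollinearBlockSpec,
    ExpressionConfig,
    SimConfig,
    SimulatedGenome,
    TandemArraySpec,
    simulate_all,
    simulate_counts,
    simulate_domain_hits,
    simulate_homology,
    simulate_genome,
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Every stage parameter, with the survey's thresholds as defaults."""

    sim: SimConfig = field(default_factory=SimConfig)
    second_species: SimConfig | None = None
    outdir: str = "results/pipeline"
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "classify": True,
            "tree": True,
            "structure": True,
            "duplication": True,
            "expression": True,
        }
    )
    evalue_max: float = 0.01            # HMM hit gate
    coverage_min: float = 0.5           # model-coverage gate (strict >)
    homology_evalue_max: float = 1e-100
    tandem_max_gap: int = 1
    min_anchors: int = 5
    max_rank_gap: int = 25
    fc_threshold: float = 1.5
    p_threshold: float = 0.01
    bootstrap_replicates: int = 100
    tree_seed: int = 7

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim_raw = raw.pop("sim", {})
        sim = _sim_from_dict(sim_raw)
        second = raw.pop("second_species", None)
        cfg = cls(sim=sim, **raw)
        if second:
            cfg.second_species = _sim_from_dict(second)
        return cfg


def _sim_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    if "tandem_arrays" in d:
        d["tandem_arrays"] = [TandemArraySpec(*t) for t in d["tandem_arrays"]]
    if "collinear_blocks" in d:
        d["collinear_blocks"] = [CollinearBlockSpec(*b) for b in d["collinear_blocks"]]
    if "expression" in d:
        d["expression"] = ExpressionConfig(**d["expression"])
    if "multidomain_counts" in d:
        d["multidomain_counts"] = {
            int(k): v for k, v in d["multidomain_counts"].items()
        }
    return SimConfig(**d)


def default_config(seed: int = 0, outdir: str = "results/pipeline") -> PipelineConfig:
    """A self-contained demonstration config with planted structures."""
    sim = SimConfig(
        seed=seed,
        species="cottonoid_a",
        n_chromosomes=2,
        genes_per_chromosome=60,
        tandem_arrays=[
            TandemArraySpec(1, 5, 3, "RLK-Pelle_LRR-XI-1"),
            TandemArraySpec(2, 10, 3, "CAMK_CDPK"),
        ],
        collinear_blocks=[
            CollinearBlockSpec(1, 2, 20, 20, 6, 0.5),
            CollinearBlockSpec(1, 2, 52, 40, 6, 0.05),
        ],
        decoy_homology_fraction=0.05,
        expression=ExpressionConfig(n_de_genes=12),
    )
    second = dataclasses.replace(
        sim,
        seed=seed + 1,
        species="cottonoid_b",
        tandem_arrays=[TandemArraySpec(1, 5, 3, "RLK-Pelle_LRR-XI-1")],
        collinear_blocks=[],
    )
    return PipelineConfig(sim=sim, second_species=second, outdir=outdir)


def _domain_spans_from_hits(hits: pd.DataFrame) -> dict[str, tuple[int, int]]:
    """Best-E-value qualifying hit's protein span per gene."""
    df = hits.copy()
    df["coverage"] = (df["model_end"] - df["model_start"] + 1) / df["model_length"]
    df = df[(df["evalue"] < 0.01) & (df["coverage"] > 0.5)]
    best = df.sort_values("evalue").drop_duplicates("gene_id", keep="first")
    return {
        r.gene_id: (int(r.seq_start), int(r.seq_end))
        for r in best.itertuples(index=False)
    }


def _pseudo_alignment(seqs: dict[str, str]) -> dict[str, str]:
    """Pad domain sequences to a common length with gap characters."""
    width = max(len(s) for s in seqs.values())
    return {k: s.ljust(width, "-") for k, s in seqs.items()}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages; returns (and writes) the report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": [k for k, v in config.stages.items() if v]}

    try:
        genome = simulate_all(config.sim, outdir / "sim")
        hits, scores = simulate_domain_hits(genome)
        homology = simulate_homology(genome)
        genomes = {config.sim.species: genome}
        if config.second_species is not None:
            genomes[config.second_species.species] = simulate_genome(
                config.second_species
            )
        report["n_genes"] = len(genome.genes)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("simulate", e)

    classification = None
    if config.stages.get("classify"):
        try:
            classification = identify.classify_kinome(
                hits, scores, config.sim.catalog(),
                evalue_max=config.evalue_max, coverage_min=config.coverage_min,
            )
            classification.to_csv(outdir / "classification.tsv", sep="\t", index=False)
            n_typical = int((classification["status"] == "typical").sum())
            n_atypical = int((classification["status"] == "atypical").sum())
            report["classification"] = {
                "typical": n_typical,
                "atypical": n_atypical,
                "non_kinase": len(genome.genes) - n_typical - n_atypical,
                "groups": classification[classification["status"] == "typical"]
                .groupby("group").size().to_dict(),
                "multidomain": classification[
                    classification["n_kinase_domains"] >= 2
                ].set_index("gene_id")["n_kinase_domains"].to_dict(),
            }
        except Exception as e:  # noqa: BLE001
            raise PipelineError("classify", e)

    if config.stages.get("tree") and classification is not None:
        try:
            typical = classification[classification["status"] == "typical"]
            spans = _domain_spans_from_hits(hits)
            reps: list[str] = []
            rng = np.random.default_rng(config.tree_seed)
            for _, members in typical.groupby("subfamily"):
                reps.extend(
                    identify.select_representatives(
                        sorted(members["gene_id"]), seed=0, rng=rng
                    )
                )
            seqs = {}
            for gid in reps:
                if gid in spans:
                    s, e = spans[gid]
                    seqs[gid] = genome.proteins[gid][s - 1 : e]
            if len(seqs) >= 3:
                aln = _pseudo_alignment(seqs)
                tree = phylogeny.bootstrap_support(
                    aln, replicates=config.bootstrap_replicates,
                    seed=config.tree_seed,
                )
                phylogeny.write_newick(tree, str(outdir / "tree.nwk"))
                report["tree"] = {
                    "n_representatives": len(seqs),
                    "bootstrap_replicates": config.bootstrap_replicates,
                }
        except Exception as e:  # noqa: BLE001
            raise PipelineError("tree", e)

    if config.stages.get("structure"):
        try:
            frames = []
            for sp, gnm in genomes.items():
                models = structure.read_gff3(
                    str((outdir / "sim" / "genome.gff3")) if sp == config.sim.species
                    else _write_temp_gff(gnm, outdir / f"sim_{sp}"),
                    species=sp,
                )
                sp_hits, _ = simulate_domain_hits(gnm)
                spans = _domain_spans_from_hits(sp_hits)
                subs = {
                    g.gene_id: g.subfamily for g in gnm.genes if g.subfamily
                }
                frames.append(structure.fingerprint_table(models, spans, subs))
            fingerprints = pd.concat(frames, ignore_index=True)
            fingerprints.to_csv(outdir / "fingerprints.tsv", sep="\t", index=False)
            report["structure"] = {"n_fingerprints": len(fingerprints)}
            if fingerprints["species"].nunique() >= 2:
                groups_df = structure.conserved_structure_groups(fingerprints)
                groups_df.to_csv(
                    outdir / "conserved_groups.tsv", sep="\t", index=False
                )
                report["structure"].update(
                    {
                        "n_groups": len(groups_df),
                        "n_cross_species_groups": int(groups_df["cross_species"].sum()),
                    }
                )
        except Exception as e:  # noqa: BLE001
            raise PipelineError("structure", e)

    if config.stages.get("duplication"):
        try:
            gene_tab = genome.gene_table()
            ranks = duplication.gene_ranks(gene_tab)
            filtered = duplication.filter_homology(
                homology, config.homology_evalue_max
            )
            sub_of = {g.gene_id: g.subfamily or "unclassified" for g in genome.genes}
            clusters = duplication.tandem_clusters(
                ranks, filtered, max_gap=config.tandem_max_gap,
                subfamily_of=sub_of,
            )
            chroms = sorted(ranks["chromosome"].unique())
            rank_maps = {
                c: dict(
                    zip(
                        ranks[ranks["chromosome"] == c]["gene_id"],
                        ranks[ranks["chromosome"] == c]["rank"],
                    )
                )
                for c in chroms
            }
            blocks = []
            for i, ca in enumerate(chroms):
                for cb in chroms[i:]:
                    blocks.extend(
                        duplication.collinear_blocks(
                            rank_maps[ca], rank_maps[cb], filtered,
                            chrom_a=ca, chrom_b=cb,
                            min_anchors=config.min_anchors,
                            max_rank_gap=config.max_rank_gap,
                        )
                    )
            anchor_pairs = [(a, b) for blk in blocks for a, b in blk.anchors]
            cds = genome.cds
            kaks_rows = []
            for a, b in anchor_pairs:
                if len(cds[a]) == len(cds[b]):
                    r = duplication.kaks(cds[a], cds[b], a, b)
                    kaks_rows.append(
                        {
                            "gene_a": a, "gene_b": b, "ka": r.ka, "ks": r.ks,
                            "epoch": r.epoch,
                        }
                    )
            kaks_df = pd.DataFrame(
                kaks_rows, columns=["gene_a", "gene_b", "ka", "ks", "epoch"]
            )
            kaks_df.to_csv(outdir / "kaks.tsv", sep="\t", index=False)
            hist = duplication.ks_histogram(
                [k for k in kaks_df["ks"] if k is not None]
            )
            hist.to_csv(outdir / "ks_histogram.tsv", sep="\t", index=False)
            _write_clusters(clusters, outdir / "tandem_clusters.tsv")
            _write_blocks(blocks, outdir / "blocks.tsv")
            pair_df = pd.DataFrame(anchor_pairs, columns=["gene_a", "gene_b"])
            _, sc_fraction = duplication.single_correspondence(pair_df)
            report["duplication"] = {
                "n_tandem_clusters": len(clusters),
                "largest_cluster": max((len(c.members) for c in clusters), default=0),
                "n_blocks": len(blocks),
                "n_collinearity_events": len(anchor_pairs),
                "epoch_counts": kaks_df.groupby("epoch").size().to_dict(),
                "single_correspondence_fraction": sc_fraction,
            }
        except Exception as e:  # noqa: BLE001
            raise PipelineError("duplication", e)

    if config.stages.get("expression"):
        try:
            counts, groups = simulate_counts(genome)
            lengths = genome.gene_table().set_index("gene_id")["cds_length"]
            norm = expression.rpkm(counts, lengths)
            norm.to_csv(outdir / "rpkm.tsv", sep="\t")
            de = expression.differential_screen(
                norm, groups,
                fc_threshold=config.fc_threshold,
                p_threshold=config.p_threshold,
            )
            de.to_csv(outdir / "de_results.tsv", sep="\t", index=False)
            planted = set(genome.truth.de_genes)
            retained = set(de.loc[de["retained"], "gene_id"])
            report["expression"] = {
                "n_retained": len(retained),
                "n_planted": len(planted),
                "planted_recovered": len(planted & retained),
            }
        except Exception as e:  # noqa: BLE001
            raise PipelineError("expression", e)

    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def _write_temp_gff(genome: SimulatedGenome, outdir: Path) -> str:
    from .simulate import write_gff3

    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "genome.gff3"
    write_gff3(path, genome.genes)
    return str(path)


def _write_clusters(clusters, path: Path) -> None:
    rows = [
        {
            "cluster_id": i + 1,
            "chromosome": c.chromosome,
            "n_members": len(c.members),
            "members": ",".join(c.members),
            "subfamilies": ";".join(
                f"{k}:{v}" for k, v in sorted(c.subfamilies.items())
            ),
        }
        for i, c in enumerate(clusters)
    ]
    pd.DataFrame(
        rows, columns=["cluster_id", "chromosome", "n_members", "members", "subfamilies"]
    ).to_csv(path, sep="\t", index=False)


def _write_blocks(blocks, path: Path) -> None:
    rows = [
        {
            "block_id": i + 1,
            "chrom_a": b.chrom_a,
            "chrom_b": b.chrom_b,
            "orientation": b.orientation,
            "n_anchors": b.score,
            "anchors": ";".join(f"{a}|{g}" for a, g in b.anchors),
        }
        for i, b in enumerate(blocks)
    ]
    pd.DataFrame(
        rows,
        columns=["block_id", "chrom_a", "chrom_b", "orientation", "n_anchors", "anchors"],
    ).to_csv(path, sep="\t", index=False)
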