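"""Synthetic multi-chromosome genomes with known evolutionary ground truth.

The generator emulates the study design the downstream stages expect:
multi-chromosome gene orders with planted tandem arrays and collinear
blocks, coding sequences diverged to controlled synonymous distances
(Ks), kinase-domain hit tables with controlled model coverage,
per-subfamily HMM score tables, homology pairs, exon structures with
known intron phases, and negative-binomial count matrices with planted
fold changes.  Every output is a pure function of :class:`SimConfig`;
the accompanying :class:`GroundTruth` names every planted entity so
recovery can be scored exactly.

Gene structure is deterministic per subfamily (exon coding lengths and
the kinase-domain span are derived by hashing the subfamily name), so
members of one subfamily — within or across simulated species — share
an exon-phase fingerprint, mirroring the structural conservation the
pipeline is built to detect.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .duplication import NON_STOP_CODONS, STOP_CODONS, ng86_counts, ng86_sites
from .identify import load_group_catalog

_BASES = ("A", "C", "G", "T")
INTERGENIC_GAP = 2000   # fixed, keeps rank order equal to coordinate order
MODEL_LENGTHS = {"Pkinase": 264, "Pkinase_Tyr": 259}


class ConfigError(ValueError):
    """Raised when planted structures are inconsistent or out of bounds."""


@dataclass(frozen=True)
class TandemArraySpec:
    chromosome: int      # 1-based
    start_rank: int      # 1-based gene rank of the first member
    size: int
    subfamily: str


@dataclass(frozen=True)
class CollinearBlockSpec:
    chrom_a: int
    chrom_b: int
    start_rank_a: int
    start_rank_b: int
    n_anchors: int
    target_ks: float
    orientation: str = "same"    # "same" or "inverted"


@dataclass(frozen=True)
class ExpressionConfig:
    n_samples_per_group: int = 4
    planted_log2fc: float = 2.0
    dispersion: float = 0.05
    n_de_genes: int = 50


@dataclass
class SimConfig:
    seed: int = 0
    species: str = "cottonoid"
    n_chromosomes: int = 2
    genes_per_chromosome: int = 60
    subfamily_catalog: dict[str, str] | None = None   # None → packaged catalog
    atypical_fraction: float = 0.1
    nonkinase_fraction: float = 0.2
    tandem_arrays: list[TandemArraySpec] = field(default_factory=list)
    collinear_blocks: list[CollinearBlockSpec] = field(default_factory=list)
    multidomain_counts: dict[int, int] = field(
        default_factory=lambda: {2: 2, 3: 1, 4: 1}
    )
    tandem_ks: float = 0.05
    ka_ks_ratio: float = 0.3
    decoy_homology_fraction: float = 0.0
    weak_homology_fraction: float = 0.05
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)

    def catalog(self) -> dict[str, str]:
        return self.subfamily_catalog or load_group_catalog()


@dataclass
class SimGene:
    gene_id: str
    species: str
    chromosome: str
    rank: int
    strand: str
    start: int
    end: int
    cds_segments: list[tuple[int, int]]       # genomic order, 1-based inclusive
    exon_coding_lengths: list[int]            # translation order
    cds: str
    protein: str
    typicality: str                           # typical / atypical / non_kinase
    subfamily: str | None
    group: str | None
    domain_spans: list[tuple[int, int]]       # protein aa coords, 1-based


@dataclass
class GroundTruth:
    genes: dict[str, dict]
    tandem_clusters: list[dict]
    collinear_blocks: list[dict]
    de_genes: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(**d)


@dataclass
class SimulatedGenome:
    config: SimConfig
    genes: list[SimGene]
    truth: GroundTruth

    def gene_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": g.gene_id,
                    "chromosome": g.chromosome,
                    "start": g.start,
                    "end": g.end,
                    "strand": g.strand,
                    "cds_length": len(g.cds),
                }
                for g in self.genes
            ]
        )

    @property
    def cds(self) -> dict[str, str]:
        return {g.gene_id: g.cds for g in self.genes}

    @property
    def proteins(self) -> dict[str, str]:
        return {g.gene_id: g.protein for g in self.genes}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_fasta(outdir / "protein.fasta", self.proteins)
        _write_fasta(outdir / "cds.fasta", self.cds)
        write_gff3(outdir / "genome.gff3", self.genes)
        self.truth.to_json(outdir / "truth.json")


# ---------------------------------------------------------------------------
# Deterministic gene-structure templates
# ---------------------------------------------------------------------------

def _template_rng(key: str) -> np.random.Generator:
    return np.random.default_rng(zlib.crc32(key.encode("utf8")))


def subfamily_template(subfamily: str) -> tuple[list[int], list[tuple[int, int]]]:
    """Exon coding lengths (translation order) and domain span for a subfamily."""
    rng = _template_rng("subfamily:" + subfamily)
    n_codons = int(rng.integers(300, 650))
    n_exons = int(rng.integers(1, 7))
    total = 3 * n_codons
    cuts = sorted(rng.choice(np.arange(1, total), size=n_exons - 1, replace=False))
    bounds = [0, *map(int, cuts), total]
    exon_lens = [bounds[i + 1] - bounds[i] for i in range(n_exons)]
    dom_len = int(rng.integers(150, min(261, n_codons - 40)))
    dom_start = int(rng.integers(10, n_codons - dom_len - 4))
    return exon_lens, [(dom_start, dom_start + dom_len - 1)]


def multidomain_template(k: int) -> tuple[list[int], list[tuple[int, int]]]:
    """Template for a protein carrying k tandem kinase domains."""
    rng = _template_rng(f"multidomain:{k}")
    n_codons = 320 * k
    n_exons = int(rng.integers(2, 7))
    total = 3 * n_codons
    cuts = sorted(rng.choice(np.arange(1, total), size=n_exons - 1, replace=False))
    bounds = [0, *map(int, cuts), total]
    exon_lens = [bounds[i + 1] - bounds[i] for i in range(n_exons)]
    domains = [(i * 320 + 20, i * 320 + 300) for i in range(k)]
    return exon_lens, domains


def _nonkinase_template(rng: np.random.Generator) -> tuple[list[int], list]:
    n_codons = int(rng.integers(150, 500))
    n_exons = int(rng.integers(1, 6))
    total = 3 * n_codons
    cuts = sorted(rng.choice(np.arange(1, total), size=n_exons - 1, replace=False))
    bounds = [0, *map(int, cuts), total]
    return [bounds[i + 1] - bounds[i] for i in range(n_exons)], []


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    codons = rng.choice(NON_STOP_CODONS, size=n_codons - 1)
    return "ATG" + "".join(codons)


# ---------------------------------------------------------------------------
# Controlled coding-sequence divergence
# ---------------------------------------------------------------------------

def evolve_duplicate(
    cds: str, target_ks: float, seed: int, ka_ks_ratio: float = 0.3
) -> str:
    """Derive a duplicate whose NG86 Ks against ``cds`` is near ``target_ks``.

    Single-nucleotide substitutions are proposed at random and accepted
    when they move the pathway-averaged synonymous and nonsynonymous
    difference counts toward targets derived from ``target_ks`` (and a
    nonsynonymous rate of ``ka_ks_ratio × target_ks``) through the
    inverse Jukes-Cantor map on the source's NG86 site counts.  Using
    the same estimator that later measures the pair guarantees the
    target is expressed in measurable units.
    """
    if len(cds) % 3:
        raise ValueError("CDS length must be a multiple of 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if any(c in STOP_CODONS for c in codons):
        raise ValueError("CDS contains internal stop codons")
    if target_ks < 0:
        raise ValueError("target_ks must be non-negative")
    if target_ks == 0:
        return cds
    p_target = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * target_ks))
    ka_target = ka_ks_ratio * target_ks
    pn_target = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * ka_target))
    if p_target >= 0.73 or pn_target >= 0.73:
        raise ValueError(f"target_ks={target_ks} is beyond NG86/JC saturation")
    n = len(codons)
    s_sites = sum(ng86_sites(c)[0] for c in codons)
    n_sites = 3.0 * n - s_sites
    sd_target = p_target * s_sites
    nd_target = pn_target * n_sites

    rng = np.random.default_rng(seed)
    cur = list(codons)
    per_codon = [(0.0, 0.0)] * n
    sd_tot = nd_tot = 0.0
    max_proposals = 500 * n + 20000
    for _ in range(max_proposals):
        if sd_tot >= sd_target - 0.5 and nd_tot >= nd_target - 0.5:
            break
        i = int(rng.integers(n))
        pos = int(rng.integers(3))
        base = _BASES[int(rng.integers(4))]
        if base == cur[i][pos]:
            continue
        cand = cur[i][:pos] + base + cur[i][pos + 1 :]
        if cand in STOP_CODONS:
            continue
        new_sd, new_nd = ng86_counts(codons[i], cand)
        dsd = new_sd - per_codon[i][0]
        dnd = new_nd - per_codon[i][1]
        if dsd <= 0 and dnd <= 0:
            continue
        if sd_tot + dsd > sd_target + 0.5 or nd_tot + dnd > nd_target + 0.5:
            continue
        cur[i] = cand
        per_codon[i] = (new_sd, new_nd)
        sd_tot += dsd
        nd_tot += dnd
    else:
        raise ValueError(
            f"could not reach target_ks={target_ks}: substitution proposals "
            "exhausted (saturation)"
        )
    return "".join(cur)


# ---------------------------------------------------------------------------
# Genome assembly
# ---------------------------------------------------------------------------

def _chrom_name(i: int) -> str:
    return f"chr{i:02d}"


def _validate(config: SimConfig) -> dict[tuple[int, int], dict]:
    """Check planted structures and return the (chromosome, rank) → role map."""
    gpc = config.genes_per_chromosome
    planted: dict[tuple[int, int], dict] = {}

    def claim(chrom: int, rank: int, role: dict) -> None:
        if not 1 <= chrom <= config.n_chromosomes:
            raise ConfigError(f"chromosome {chrom} out of range")
        if not 1 <= rank <= gpc:
            raise ConfigError(f"rank {rank} out of range on chromosome {chrom}")
        if (chrom, rank) in planted:
            raise ConfigError(
                f"planted structures overlap at chromosome {chrom}, rank {rank}"
            )
        planted[(chrom, rank)] = role

    catalog = config.catalog()
    for t in config.tandem_arrays:
        if t.size < 2:
            raise ConfigError("tandem arrays need at least 2 members")
        if t.subfamily not in catalog:
            raise ConfigError(f"unknown subfamily {t.subfamily!r} in tandem array")
        for j in range(t.size):
            role = {"kind": "tandem", "spec": t, "member": j}
            if j:
                role["source"] = (t.chromosome, t.start_rank)
            claim(t.chromosome, t.start_rank + j, role)
    for b in config.collinear_blocks:
        if b.orientation not in ("same", "inverted"):
            raise ConfigError(f"unknown orientation {b.orientation!r}")
        for j in range(b.n_anchors):
            claim(b.chrom_a, b.start_rank_a + j, {"kind": "block_source", "spec": b})
        for j in range(b.n_anchors):
            tgt = (
                b.start_rank_b + j
                if b.orientation == "same"
                else b.start_rank_b + b.n_anchors - 1 - j
            )
            src = (b.chrom_a, b.start_rank_a + j)
            if (b.chrom_b, tgt) <= src:
                raise ConfigError(
                    "collinear duplicate must come after its source in "
                    "(chromosome, rank) generation order"
                )
            claim(b.chrom_b, tgt, {"kind": "block_dup", "spec": b, "source": src})
    return planted


def simulate_genome(config: SimConfig) -> SimulatedGenome:
    """Build a deterministic genome with all planted structures realized."""
    planted = _validate(config)
    catalog = config.catalog()
    subfamilies = sorted(catalog)
    rng = np.random.default_rng([config.seed, 1])
    gpc, n_chrom = config.genes_per_chromosome, config.n_chromosomes
    cells = [(c, r) for c in range(1, n_chrom + 1) for r in range(1, gpc + 1)]
    free = [cell for cell in cells if cell not in planted]
    n_total = len(cells)

    n_nonkinase = round(config.nonkinase_fraction * n_total)
    n_atypical = round(config.atypical_fraction * n_total)
    n_multi = sum(config.multidomain_counts.values())
    if n_nonkinase + n_atypical + n_multi > len(free):
        raise ConfigError("not enough unplanted genes for the requested fractions")
    picks = rng.permutation(len(free))
    special = [free[i] for i in picks]
    nonkinase_cells = set(special[:n_nonkinase])
    atypical_cells = set(special[n_nonkinase : n_nonkinase + n_atypical])
    multi_cells: dict[tuple[int, int], int] = {}
    cursor = n_nonkinase + n_atypical
    for k, count in sorted(config.multidomain_counts.items()):
        for _ in range(count):
            multi_cells[special[cursor]] = k
            cursor += 1

    genes: list[SimGene] = []
    by_cell: dict[tuple[int, int], SimGene] = {}
    truth_genes: dict[str, dict] = {}

    for chrom_i in range(1, n_chrom + 1):
        pos = 1
        for rank in range(1, gpc + 1):
            cell = (chrom_i, rank)
            gene_id = f"{config.species}_c{chrom_i:02d}g{rank:04d}"
            role = planted.get(cell)
            if cell in nonkinase_cells:
                typicality, subfamily = "non_kinase", None
                exon_lens, domains = _nonkinase_template(rng)
            elif cell in atypical_cells:
                typicality, subfamily = "atypical", None
                exon_lens, domains = subfamily_template(
                    subfamilies[int(rng.integers(len(subfamilies)))]
                )
                domains = [domains[0]]
            elif cell in multi_cells:
                typicality = "typical"
                subfamily = subfamilies[int(rng.integers(len(subfamilies)))]
                exon_lens, domains = multidomain_template(multi_cells[cell])
            elif role is not None and role["kind"] == "tandem":
                typicality, subfamily = "typical", role["spec"].subfamily
                exon_lens, domains = subfamily_template(subfamily)
            elif role is not None and role["kind"] == "block_dup":
                src = by_cell[role["source"]]
                typicality, subfamily = "typical", src.subfamily
                exon_lens = list(src.exon_coding_lengths)
                domains = list(src.domain_spans)
            else:
                typicality = "typical"
                subfamily = subfamilies[int(rng.integers(len(subfamilies)))]
                exon_lens, domains = subfamily_template(subfamily)
                if role is not None and role["kind"] == "block_source":
                    pass  # ordinary typical gene; duplicates copy it later

            n_codons = sum(exon_lens) // 3
            if role is not None and role.get("source"):
                src = by_cell[role["source"]]
                if role["kind"] == "tandem":
                    target = config.tandem_ks
                else:
                    target = role["spec"].target_ks
                child_seed = int(rng.integers(2**31))
                cds = evolve_duplicate(
                    src.cds, target, child_seed, config.ka_ks_ratio
                )
            else:
                cds = _random_cds(n_codons, rng)
            protein = str(Seq(cds).translate())

            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = len(exon_lens)
            introns = (
                rng.integers(100, 500, size=n_exons - 1).tolist() if n_exons > 1 else []
            )
            genomic_lens = exon_lens if strand == "+" else exon_lens[::-1]
            start = pos + INTERGENIC_GAP
            segments = []
            p = start
            for i, length in enumerate(genomic_lens):
                segments.append((p, p + length - 1))
                p += length
                if i < len(introns):
                    p += int(introns[i])
            end = segments[-1][1]
            pos = end

            gene = SimGene(
                gene_id,
                config.species,
                _chrom_name(chrom_i),
                rank,
                strand,
                start,
                end,
                segments,
                exon_lens,
                cds,
                protein,
                typicality,
                subfamily,
                catalog.get(subfamily) if subfamily else None,
                domains,
            )
            genes.append(gene)
            by_cell[cell] = gene

            phases = np.cumsum(exon_lens[:-1]) % 3
            phase_string = "".join(str(int(x)) for x in phases)
            truth_genes[gene_id] = {
                "typicality": typicality,
                "subfamily": subfamily,
                "group": gene.group,
                "n_domains": len(domains),
                "phase_string": phase_string,
                "domain_fingerprint": _truth_fingerprint(exon_lens, domains),
                "chromosome": gene.chromosome,
                "rank": rank,
            }

    tandem_truth = [
        {
            "chromosome": _chrom_name(t.chromosome),
            "members": [
                by_cell[(t.chromosome, t.start_rank + j)].gene_id
                for j in range(t.size)
            ],
            "subfamily": t.subfamily,
        }
        for t in config.tandem_arrays
    ]
    block_truth = []
    for b in config.collinear_blocks:
        anchors = []
        for j in range(b.n_anchors):
            tgt = (
                b.start_rank_b + j
                if b.orientation == "same"
                else b.start_rank_b + b.n_anchors - 1 - j
            )
            anchors.append(
                [
                    by_cell[(b.chrom_a, b.start_rank_a + j)].gene_id,
                    by_cell[(b.chrom_b, tgt)].gene_id,
                ]
            )
        block_truth.append(
            {
                "chrom_a": _chrom_name(b.chrom_a),
                "chrom_b": _chrom_name(b.chrom_b),
                "anchors": anchors,
                "target_ks": b.target_ks,
                "orientation": b.orientation,
            }
        )
    truth = GroundTruth(truth_genes, tandem_truth, block_truth, {})
    return SimulatedGenome(config, genes, truth)


def _truth_fingerprint(
    exon_lens: list[int], domains: list[tuple[int, int]]
) -> str:
    if not domains:
        return ""
    ds, de = domains[0]
    lo, hi = 3 * (ds - 1) + 1, 3 * de
    out = []
    cum = 0
    for length in exon_lens[:-1]:
        cum += length
        if lo <= cum <= hi:
            out.append(str(cum % 3))
    return "".join(out)


# ---------------------------------------------------------------------------
# Evidence tables
# ---------------------------------------------------------------------------

def simulate_domain_hits(
    genome: SimulatedGenome, config: SimConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Kinase-domain hit table and per-subfamily score table.

    Typical genes get one qualifying hit (E < 0.01, coverage > 0.5) per
    planted domain; atypical genes get only low-coverage hits; a share
    of non-kinase genes gets a high-coverage hit whose E-value fails the
    gate, so typicality requires both gates jointly.
    """
    config = config or genome.config
    rng = np.random.default_rng([config.seed, 2])
    catalog = config.catalog()
    subfamilies = sorted(catalog)
    hit_rows, score_rows = [], []
    for g in genome.genes:
        plen = len(g.protein)
        if g.typicality == "typical":
            for ds, de in g.domain_spans:
                model = "Pkinase" if rng.random() < 0.8 else "Pkinase_Tyr"
                mlen = MODEL_LENGTHS[model]
                span = int(np.floor(0.5 * mlen)) + 1 + int(rng.integers(0, mlen // 3))
                span = min(span, mlen)
                mstart = int(rng.integers(1, mlen - span + 2))
                hit_rows.append(
                    (
                        g.gene_id, model, mstart, mstart + span - 1, mlen,
                        ds, de, 10.0 ** rng.uniform(-120, -20),
                    )
                )
            score_rows.append(
                (g.gene_id, g.subfamily, 250.0 + 150.0 * rng.random())
            )
            for other in rng.choice(
                [s for s in subfamilies if s != g.subfamily], size=2, replace=False
            ):
                score_rows.append((g.gene_id, other, 40.0 + 140.0 * rng.random()))
        elif g.typicality == "atypical":
            for _ in range(int(rng.integers(1, 3))):
                model = "Pkinase" if rng.random() < 0.8 else "Pkinase_Tyr"
                mlen = MODEL_LENGTHS[model]
                span = max(1, int(rng.uniform(0.15, 0.5) * mlen))
                span = min(span, mlen // 2)  # coverage ≤ 0.5
                mstart = int(rng.integers(1, mlen - span + 2))
                sstart = int(rng.integers(1, max(2, plen - span)))
                hit_rows.append(
                    (
                        g.gene_id, model, mstart, mstart + span - 1, mlen,
                        sstart, min(plen, sstart + span - 1),
                        10.0 ** rng.uniform(-30, -3),
                    )
                )
        else:
            if rng.random() < 0.3:
                model = "Pkinase"
                mlen = MODEL_LENGTHS[model]
                span = int(rng.uniform(0.6, 0.9) * mlen)
                mstart = int(rng.integers(1, mlen - span + 2))
                sstart = int(rng.integers(1, max(2, plen - span)))
                hit_rows.append(
                    (
                        g.gene_id, model, mstart, mstart + span - 1, mlen,
                        sstart, min(plen, sstart + span - 1),
                        10.0 ** rng.uniform(-1.5, 0.5),
                    )
                )
    hits = pd.DataFrame(
        hit_rows,
        columns=[
            "gene_id", "model_name", "model_start", "model_end",
            "model_length", "seq_start", "seq_end", "evalue",
        ],
    )
    scores = pd.DataFrame(score_rows, columns=["gene_id", "subfamily", "bit_score"])
    return hits, scores


def simulate_homology(
    genome: SimulatedGenome, config: SimConfig | None = None
) -> pd.DataFrame:
    """All-vs-all homology pairs: planted truth, decoys, and weak pairs.

    Planted tandem/collinear pairs get E-values far below the 1e-100
    filter; decoy pairs (random gene pairs) also pass the filter and
    stress block detection; weak pairs sit above the filter and must be
    discarded by it.
    """
    config = config or genome.config
    rng = np.random.default_rng([config.seed, 3])
    true_pairs: list[tuple[str, str]] = []
    for cluster in genome.truth.tandem_clusters:
        members = cluster["members"]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                true_pairs.append((members[i], members[j]))
    for block in genome.truth.collinear_blocks:
        for a, b in block["anchors"]:
            true_pairs.append((a, b))
    rows = [(a, b, 1e-180) for a, b in true_pairs]
    true_set = {frozenset(p) for p in true_pairs}
    kinase_ids = [g.gene_id for g in genome.genes if g.typicality == "typical"]
    n_decoy = round(config.decoy_homology_fraction * len(true_pairs))
    n_weak = round(config.weak_homology_fraction * len(true_pairs))
    made = 0
    while made < n_decoy and len(kinase_ids) > 1:
        a, b = rng.choice(kinase_ids, size=2, replace=False)
        if frozenset((a, b)) in true_set:
            continue
        rows.append((str(a), str(b), 1e-150))
        true_set.add(frozenset((a, b)))
        made += 1
    for _ in range(n_weak):
        a, b = rng.choice(kinase_ids, size=2, replace=False)
        rows.append((str(a), str(b), 1e-50))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "evalue"])


def simulate_counts(
    genome: SimulatedGenome, config: SimConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count matrix with planted differential expression.

    Planted DE genes (chosen among typical kinases, alternating signs)
    have their treatment-group mean scaled by 2**planted_log2fc.
    Updates ``genome.truth.de_genes`` with the signed planted effects.
    """
    config = config or genome.config
    expr = config.expression
    if expr.n_samples_per_group < 2:
        raise ValueError("need at least 2 samples per group")
    rng = np.random.default_rng([config.seed, 4])
    gene_ids = [g.gene_id for g in genome.genes]
    typical = [g.gene_id for g in genome.genes if g.typicality == "typical"]
    n_de = min(expr.n_de_genes, len(typical))
    de_ids = rng.choice(typical, size=n_de, replace=False)
    de_signs = {str(g): (1.0 if i % 2 == 0 else -1.0) for i, g in enumerate(de_ids)}
    genome.truth.de_genes = {
        g: s * expr.planted_log2fc for g, s in de_signs.items()
    }

    base = rng.lognormal(mean=np.log(150.0), sigma=1.0, size=len(gene_ids))
    mu = np.tile(base[:, None], (1, 2 * expr.n_samples_per_group))
    for i, g in enumerate(gene_ids):
        if g in de_signs:
            mu[i, : expr.n_samples_per_group] *= 2.0 ** (
                de_signs[g] * expr.planted_log2fc
            )
    if expr.dispersion <= 1e-8:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / expr.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    samples = [f"T{i+1}" for i in range(expr.n_samples_per_group)] + [
        f"C{i+1}" for i in range(expr.n_samples_per_group)
    ]
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=samples)
    counts_df.index.name = "gene_id"
    groups = pd.DataFrame(
        {
            "sample": samples,
            "group": ["treatment"] * expr.n_samples_per_group
            + ["control"] * expr.n_samples_per_group,
        }
    )
    return counts_df, groups


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def _write_fasta(path: Path, seqs: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_gff3(path: str | Path, genes: list[SimGene]) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        attrs = f"ID={g.gene_id}"
        lines.append(
            "\t".join(
                [g.chromosome, "kinomevo", "gene", str(g.start), str(g.end), ".",
                 g.strand, ".", attrs]
            )
        )
        mrna = f"{g.gene_id}.t1"
        lines.append(
            "\t".join(
                [g.chromosome, "kinomevo", "mRNA", str(g.start), str(g.end), ".",
                 g.strand, ".", f"ID={mrna};Parent={g.gene_id}"]
            )
        )
        for s, e in g.cds_segments:
            lines.append(
                "\t".join(
                    [g.chromosome, "kinomevo", "CDS", str(s), str(e), ".",
                     g.strand, ".", f"Parent={mrna}"]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def simulate_all(config: SimConfig, outdir: str | Path) -> SimulatedGenome:
    """Generate a genome and write every pipeline input under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(config)
    hits, scores = simulate_domain_hits(genome, config)
    homology = simulate_homology(genome, config)
    counts, groups = simulate_counts(genome, config)
    genome.write(outdir)
    hits.to_csv(outdir / "hits.tsv", sep="\t", index=False)
    scores.to_csv(outdir / "scores.tsv", sep="\t", index=False)
    homology.to_csv(outdir / "homology.tsv", sep="\t", index=False)
    counts.to_csv(outdir / "counts.tsv", sep="\t")
    groups.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    genome.truth.to_json(outdir / "truth.json")
    return genome
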