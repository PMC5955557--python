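"""Exon-intron phase structure of kinase genes.

An intron's phase is the cumulative coding length of the exons upstream
of it modulo 3 (0 between codons, 1 after the first codon base, 2 after
the second).  Restricting the ordered phases to the introns falling
inside the kinase-domain span gives a compact fingerprint (e.g. "1000")
that is strongly conserved within subfamilies across species; genes
sharing (subfamily, fingerprint) across two or more species form
conserved-structure groups.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd


@dataclass
class GeneModel:
    """Minimal gene model: ordered CDS segments on a chromosome.

    Segments are 1-based inclusive genomic intervals sorted by position;
    for minus-strand genes translation order is the reverse of genomic
    order.
    """

    gene_id: str
    species: str
    chromosome: str
    strand: str
    cds_segments: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        segs = sorted(self.cds_segments)
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping CDS segments in {self.gene_id}")
        self.cds_segments = segs

    @property
    def coding_lengths(self) -> list[int]:
        """Exon coding lengths in translation order."""
        lens = [e - s + 1 for s, e in self.cds_segments]
        return lens[::-1] if self.strand == "-" else lens

    @property
    def coding_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)


@dataclass(frozen=True)
class PhaseFingerprint:
    gene_id: str
    phase_string: str                 # phases of in-domain introns, 5'→3'
    domain_span: tuple[int, int]      # protein aa coordinates used


class PhaseError(ValueError):
    pass


def intron_phases(gene: GeneModel) -> list[int]:
    """Ordered intron phases of a gene (empty for single-exon genes)."""
    lens = gene.coding_lengths
    if sum(lens) % 3:
        raise PhaseError(
            f"{gene.gene_id}: coding length {sum(lens)} not divisible by 3"
        )
    phases = []
    cum = 0
    for length in lens[:-1]:
        cum += length
        phases.append(cum % 3)
    return phases


def domain_fingerprint(
    gene: GeneModel, domain: tuple[int, int]
) -> PhaseFingerprint:
    """Phase string of the introns inside a protein-coordinate domain span.

    An intron sits after coding nucleotide ``c`` (cumulative coding
    length so far); it is in-domain when ``c`` lies in
    [3·(start−1)+1, 3·end], boundary inclusive on both ends.
    """
    ds, de = domain
    protein_len = gene.coding_length // 3
    if not 1 <= ds <= de <= protein_len:
        raise ValueError(
            f"domain {domain} outside protein of length {protein_len} "
            f"({gene.gene_id})"
        )
    lo, hi = 3 * (ds - 1) + 1, 3 * de
    chars = []
    cum = 0
    for length in gene.coding_lengths[:-1]:
        cum += length
        if lo <= cum <= hi:
            chars.append(str(cum % 3))
    return PhaseFingerprint(gene.gene_id, "".join(chars), (ds, de))


def conserved_structure_groups(
    fingerprints: pd.DataFrame,
    min_species: int = 2,
    allow_intronless: bool = False,
) -> pd.DataFrame:
    """Group genes sharing (subfamily, phase_string) across species.

    Expects columns gene_id, species, subfamily, phase_string.  Returns
    one row per group with the member genes, the species covered, and a
    flag marking groups spanning at least ``min_species`` species.
    Intron-less genes (empty phase string) are grouped only when
    ``allow_intronless`` is set.
    """
    species = fingerprints["species"].unique()
    if len(species) < 2:
        raise ValueError("need fingerprints from at least 2 species")
    df = fingerprints.copy()
    df["phase_string"] = df["phase_string"].fillna("").astype(str)
    if not allow_intronless:
        df = df[df["phase_string"] != ""]
    rows = []
    for (sub, phases), members in df.groupby(["subfamily", "phase_string"]):
        if len(members) < 2:
            continue
        sp = sorted(members["species"].unique())
        rows.append(
            {
                "subfamily": sub,
                "phase_string": phases,
                "n_genes": len(members),
                "genes": ",".join(sorted(members["gene_id"])),
                "species": ",".join(sp),
                "n_species": len(sp),
                "cross_species": len(sp) >= min_species,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "subfamily", "phase_string", "n_genes", "genes",
            "species", "n_species", "cross_species",
        ],
    ).sort_values(["subfamily", "phase_string"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# GFF3 (gene/mRNA/CDS subset)
# ---------------------------------------------------------------------------

_GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase",
    "attributes",
]


def _attr(attributes: str, key: str) -> str | None:
    m = re.search(rf"(?:^|;){key}=([^;]+)", attributes)
    return m.group(1) if m else None


def read_gff3(path: str, species: str = "unknown") -> list[GeneModel]:
    """Read gene models (gene/mRNA/CDS features) from a GFF3 file.

    One mRNA per gene is assumed; with several, the longest-CDS
    transcript is used.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=_GFF_COLUMNS,
        dtype={"start": int, "end": int},
    )
    mrna_parent = {
        _attr(a, "ID"): _attr(a, "Parent")
        for a in df.loc[df["type"] == "mRNA", "attributes"]
    }
    segments: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    for row in df[df["type"] == "CDS"].itertuples(index=False):
        mrna = _attr(row.attributes, "Parent")
        segments.setdefault(mrna, []).append((row.start, row.end))
        meta[mrna] = (row.seqid, row.strand)
    by_gene: dict[str, list[str]] = {}
    for mrna, gene in mrna_parent.items():
        if mrna in segments:
            by_gene.setdefault(gene, []).append(mrna)
    models = []
    for gene, mrnas in by_gene.items():
        best = max(
            mrnas, key=lambda m: sum(e - s + 1 for s, e in segments[m])
        )
        chrom, strand = meta[best]
        models.append(GeneModel(gene, species, chrom, strand, segments[best]))
    models.sort(key=lambda g: (g.chromosome, g.cds_segments[0][0]))
    return models


def gene_table_from_gff(path: str) -> pd.DataFrame:
    """Gene coordinate table (gene_id, chromosome, start, end, cds_length)."""
    models = read_gff3(path)
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in models],
            "chromosome": [g.chromosome for g in models],
            "start": [g.cds_segments[0][0] for g in models],
            "end": [g.cds_segments[-1][1] for g in models],
            "strand": [g.strand for g in models],
            "cds_length": [g.coding_length for g in models],
        }
    )


def fingerprint_table(
    models: list[GeneModel],
    domain_spans: dict[str, tuple[int, int]],
    subfamily_of: dict[str, str],
    skip_bad_length: bool = True,
) -> pd.DataFrame:
    """Fingerprints for every gene with a known domain span.

    Genes whose coding length is not a multiple of 3 are skipped with
    the fingerprint left out (mirrors a warning-and-skip policy).
    """
    rows = []
    for g in models:
        if g.gene_id not in domain_spans:
            continue
        if g.coding_length % 3:
            if skip_bad_length:
                continue
            raise PhaseError(f"{g.gene_id}: bad coding length")
        fp = domain_fingerprint(g, domain_spans[g.gene_id])
        rows.append(
            {
                "gene_id": g.gene_id,
                "species": g.species,
                "subfamily": subfamily_of.get(g.gene_id, "unclassified"),
                "phase_string": fp.phase_string,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "species", "subfamily", "phase_string"]
    )
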