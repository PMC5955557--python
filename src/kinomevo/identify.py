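"""Identification and classification of protein kinases from domain-hit evidence.

A protein is a *typical* kinase when at least one Pkinase/Pkinase_Tyr
domain hit passes the E-value gate (< 0.01) and covers more than half of
the HMM model; proteins with qualifying-E-value hits but no such
coverage are *atypical*; everything else is non-kinase.  Typical kinases
are assigned to a subfamily by the best per-subfamily HMM bit score, and
subfamilies map to one of the seven canonical groups (RLK, AGC, CAMK,
CMGC, STE, TKL, other) through an editable catalog shipped with the
package.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

GROUPS = ("RLK", "AGC", "CAMK", "CMGC", "STE", "TKL", "other")

#: label used for genes that cannot be placed in a subfamily
UNCLASSIFIED = "unclassified"

HIT_COLUMNS = [
    "gene_id",
    "model_name",
    "model_start",
    "model_end",
    "model_length",
    "seq_start",
    "seq_end",
    "evalue",
]

#: column order of HMMER 3 ``--domtblout`` fields that map onto HIT_COLUMNS
DOMTBLOUT_MAP = {
    "target name": "gene_id",
    "query name": "model_name",
    "hmm from": "model_start",
    "hmm to": "model_end",
    "qlen": "model_length",
    "ali from": "seq_start",
    "ali to": "seq_end",
    "i-Evalue": "evalue",
}


@dataclass(frozen=True)
class DomainHit:
    """One alignment of a protein to a kinase HMM model.

    Coordinates are 1-based inclusive, on the model (``model_*``) and on
    the protein (``seq_*``).
    """

    gene_id: str
    model_name: str
    model_start: int
    model_end: int
    model_length: int
    seq_start: int
    seq_end: int
    evalue: float

    def __post_init__(self) -> None:
        if self.model_length <= 0:
            raise ValueError(f"model_length must be positive, got {self.model_length}")
        if not 1 <= self.model_start <= self.model_end <= self.model_length:
            raise ValueError(
                f"invalid model span {self.model_start}-{self.model_end} "
                f"for model of length {self.model_length}"
            )
        if self.seq_start > self.seq_end:
            raise ValueError("seq_start must not exceed seq_end")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")


@dataclass(frozen=True)
class KinaseRecord:
    gene_id: str
    typical: bool
    subfamily: str
    group: str
    n_kinase_domains: int


def load_group_catalog(path: str | None = None) -> dict[str, str]:
    """Load the subfamily → group mapping (package default or a user TSV)."""
    if path is None:
        ref = importlib.resources.files("kinomevo").joinpath("data/subfamily_groups.tsv")
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    catalog = dict(zip(df["subfamily"], df["group"]))
    bad = sorted(set(catalog.values()) - set(GROUPS))
    if bad:
        raise ValueError(f"catalog contains unknown groups: {bad}")
    return catalog


def coverage_fraction(hit: DomainHit) -> float:
    """Fraction of the HMM model covered by one domain alignment."""
    return (hit.model_end - hit.model_start + 1) / hit.model_length


def _hit_frame(hits: pd.DataFrame) -> pd.DataFrame:
    df = hits.copy()
    if (df["model_length"] <= 0).any():
        raise ValueError("model_length must be positive for every hit")
    df["coverage"] = (df["model_end"] - df["model_start"] + 1) / df["model_length"]
    return df


def gate_typical(
    hits: pd.DataFrame,
    evalue_max: float = 0.01,
    coverage_min: float = 0.5,
) -> dict[str, set[str]]:
    """Partition gene ids into typical / atypical / non-kinase.

    Both gates are applied jointly per hit: a hit only supports
    typicality when its E-value is strictly below ``evalue_max`` *and*
    its model coverage is strictly above ``coverage_min``.  Genes with
    E-value-qualifying hits but none above the coverage bar are
    atypical; genes with no E-value-qualifying hit at all are
    non-kinase.
    """
    if hits.empty:
        return {"typical": set(), "atypical": set(), "non_kinase": set()}
    df = _hit_frame(hits)
    df["pass_e"] = df["evalue"] < evalue_max
    df["pass_both"] = df["pass_e"] & (df["coverage"] > coverage_min)
    per_gene = df.groupby("gene_id")[["pass_e", "pass_both"]].any()
    typical = set(per_gene.index[per_gene["pass_both"]])
    atypical = set(per_gene.index[per_gene["pass_e"] & ~per_gene["pass_both"]])
    non_kinase = set(per_gene.index) - typical - atypical
    return {"typical": typical, "atypical": atypical, "non_kinase": non_kinase}


def count_kinase_domains(
    gene_hits: pd.DataFrame,
    evalue_max: float = 0.01,
    coverage_min: float = 0.5,
) -> int:
    """Number of distinct kinase domains on one typical protein.

    Qualifying hits (both gates) are resolved greedily by ascending
    E-value on protein coordinates; a hit is kept only if it overlaps no
    previously kept hit (zero overlap tolerance).
    """
    df = _hit_frame(gene_hits)
    df = df[(df["evalue"] < evalue_max) & (df["coverage"] > coverage_min)]
    kept: list[tuple[int, int]] = []
    for _, row in df.sort_values(["evalue", "seq_start"]).iterrows():
        s, e = int(row["seq_start"]), int(row["seq_end"])
        if all(e < ks or s > ke for ks, ke in kept):
            kept.append((s, e))
    return len(kept)


def assign_subfamily(
    gene_scores: pd.DataFrame, catalog: dict[str, str]
) -> tuple[str, str]:
    """Best-scoring subfamily and its group for one gene.

    Ties on bit score are broken by the lexicographically smaller
    subfamily name so the assignment is order-independent.
    """
    if gene_scores.empty:
        return UNCLASSIFIED, "other"
    ordered = gene_scores.sort_values(
        ["bit_score", "subfamily"], ascending=[False, True]
    )
    subfamily = str(ordered.iloc[0]["subfamily"])
    if subfamily not in catalog:
        raise KeyError(f"subfamily {subfamily!r} missing from group catalog")
    return subfamily, catalog[subfamily]


def select_representatives(
    members: list[str], seed: int, rng: np.random.Generator | None = None
) -> list[str]:
    """Sample 1–3 representative genes from a subfamily for tree building.

    Subfamilies with ≤ 6 members contribute 1 representative, 7–30
    members 2, and > 30 members 3, drawn uniformly without replacement.
    """
    if not members:
        raise ValueError("member list must be non-empty")
    n = len(members)
    k = 1 if n <= 6 else (2 if n <= 30 else 3)
    if rng is None:
        rng = np.random.default_rng(seed)
    return sorted(rng.choice(members, size=k, replace=False).tolist())


def classify_kinome(
    hits: pd.DataFrame,
    scores: pd.DataFrame,
    catalog: dict[str, str] | None = None,
    evalue_max: float = 0.01,
    coverage_min: float = 0.5,
) -> pd.DataFrame:
    """Full classification table for one genome's hit/score evidence.

    Returns one row per gene appearing in ``hits`` with columns
    gene_id, status (typical/atypical/non_kinase), subfamily, group and
    n_kinase_domains (0 for non-typical genes).
    """
    if catalog is None:
        catalog = load_group_catalog()
    parts = gate_typical(hits, evalue_max=evalue_max, coverage_min=coverage_min)
    score_groups = dict(tuple(scores.groupby("gene_id"))) if not scores.empty else {}
    hit_groups = dict(tuple(hits.groupby("gene_id"))) if not hits.empty else {}
    rows = []
    for status in ("typical", "atypical", "non_kinase"):
        for gene in sorted(parts[status]):
            if status == "typical":
                sub, group = assign_subfamily(
                    score_groups.get(gene, pd.DataFrame(columns=["subfamily", "bit_score"])),
                    catalog,
                )
                ndom = count_kinase_domains(
                    hit_groups[gene], evalue_max=evalue_max, coverage_min=coverage_min
                )
            else:
                sub, group, ndom = UNCLASSIFIED, "other", 0
            rows.append((gene, status, sub, group, ndom))
    return pd.DataFrame(
        rows, columns=["gene_id", "status", "subfamily", "group", "n_kinase_domains"]
    )


def read_hits(path: str, domtblout_order: bool = False) -> pd.DataFrame:
    """Read a hits table (package TSV layout, or HMMER domtblout column order)."""
    df = pd.read_csv(path, sep="\t")
    if domtblout_order:
        df = df.rename(columns=DOMTBLOUT_MAP)
    missing = set(HIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"hits table missing columns: {sorted(missing)}")
    return df[HIT_COLUMNS]


def read_scores(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
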