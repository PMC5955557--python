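"""Duplication detection and molecular-evolution dating.

Tandem clusters are connected components of homologous gene pairs at
adjacent chromosome ranks; collinear (syntenic) blocks are chains of
homologous pairs in conserved order between two chromosomes, found by
dynamic programming over gene ranks.  Per duplicate pair the
Nei-Gojobori (1986) method gives pathway-averaged synonymous and
nonsynonymous difference counts and site counts, converted to Ks and Ka
with the Jukes-Cantor correction; Ks then attributes each event to a
duplication epoch (tetraploidization Ks 0-0.1, the recent
whole-genome-duplication peak Ks 0.4-0.6, or older events Ks 0.6-3).

Gene ranks are always computed over *all* annotated genes on a
chromosome, not only kinases, mirroring how collinearity scanners see a
genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations

import networkx as nx
import numpy as np
import pandas as pd
from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
CODON_AA: dict[str, str] = dict(_STANDARD.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)
NON_STOP_CODONS: tuple[str, ...] = tuple(sorted(CODON_AA))
_BASES = ("A", "C", "G", "T")

SATURATION_LIMIT = 0.75  # pS or pN at/above 3/4 leaves the JC log undefined


# ---------------------------------------------------------------------------
# Nei-Gojobori 1986
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of one codon.

    Each position contributes (synonymous one-step changes)/3 to the
    synonymous count; changes that create a stop codon are counted as
    nonsynonymous, so s + n = 3 for every codon.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no defined site counts")
    if codon not in CODON_AA:
        raise ValueError(f"invalid codon {codon!r}")
    s = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant not in STOP_CODONS and CODON_AA[mutant] == CODON_AA[codon]:
                s += 1 / 3
    return s, 3.0 - s


@lru_cache(maxsize=None)
def ng86_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous differences between codons.

    All orderings of the differing positions (1, 2 or 6 pathways) are
    enumerated; pathways passing through a stop codon are skipped and
    the average renormalized over the remainder.  If every pathway is
    blocked by stops, all pathways are used with steps into or out of a
    stop counted as nonsynonymous.
    """
    a, b = codon_a.upper(), codon_b.upper()
    for c in (a, b):
        if c in STOP_CODONS or c not in CODON_AA:
            raise ValueError(f"invalid or stop codon {c!r}")
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool) -> tuple[float, float] | None:
        sd = nd = 0.0
        cur = a
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS or cur in STOP_CODONS:
                if not allow_stops:
                    return None
                nd += 1
            elif CODON_AA[cur] == CODON_AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    orders = list(permutations(diff))
    results = [r for o in orders if (r := walk(o, allow_stops=False)) is not None]
    if not results:
        results = [walk(o, allow_stops=True) for o in orders]
    sd = float(np.mean([r[0] for r in results]))
    nd = float(np.mean([r[1] for r in results]))
    return sd, nd


@dataclass
class KaKsResult:
    """NG86 estimate for one aligned coding-sequence pair."""

    gene_a: str | None
    gene_b: str | None
    n_codons: int
    sd: float
    nd: float
    s_sites: float
    n_sites: float
    ps: float
    pn: float
    ks: float | None
    ka: float | None
    epoch: str


def _jc_rate(p: float) -> float | None:
    if p >= SATURATION_LIMIT:
        return None
    return -0.75 * np.log(1.0 - (4.0 / 3.0) * p)


def kaks(
    cds_a: str,
    cds_b: str,
    gene_a: str | None = None,
    gene_b: str | None = None,
) -> KaKsResult:
    """NG86 Ka/Ks for an aligned pair of coding sequences.

    Sequences must be equal length and a multiple of 3; codon columns
    containing a gap or ambiguity character are dropped pairwise.  Site
    counts are averaged over the two sequences.  When pS (or pN) reaches
    the Jukes-Cantor saturation limit of 3/4, the rate is undefined and
    the pair is labeled ``saturated``.
    """
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise ValueError(f"sequence lengths differ: {len(a)} vs {len(b)}")
    if len(a) % 3:
        raise ValueError("aligned length must be a multiple of 3")
    sd = nd = s_a = n_a = s_b = n_b = 0.0
    n_codons = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if not (set(ca) <= set(_BASES) and set(cb) <= set(_BASES)):
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        n_codons += 1
        sa, na = ng86_sites(ca)
        sb, nb = ng86_sites(cb)
        s_a, n_a = s_a + sa, n_a + na
        s_b, n_b = s_b + sb, n_b + nb
        d_s, d_n = ng86_counts(ca, cb)
        sd, nd = sd + d_s, nd + d_n
    if n_codons == 0:
        raise ValueError("no comparable codons in the pair")
    s_sites = (s_a + s_b) / 2.0
    n_sites = (n_a + n_b) / 2.0
    ps = sd / s_sites if s_sites else 0.0
    pn = nd / n_sites if n_sites else 0.0
    ks = _jc_rate(ps)
    ka = _jc_rate(pn)
    epoch = "saturated" if (ks is None or ka is None) else assign_epoch(ks)
    return KaKsResult(
        gene_a, gene_b, n_codons, sd, nd, s_sites, n_sites, ps, pn, ks, ka, epoch
    )


KS_EPOCH_BINS: tuple[tuple[float, float, str], ...] = (
    (0.0, 0.1, "tetraploid"),
    (0.4, 0.6, "wgd_recent"),
    (0.6, 3.0, "ancient"),
)


def assign_epoch(ks: float | None) -> str:
    """Map a Ks value onto a duplication epoch (half-open bins)."""
    if ks is None:
        return "saturated"
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    for lo, hi, label in KS_EPOCH_BINS:
        if lo <= ks < hi:
            return label
    return "unassigned"


# ---------------------------------------------------------------------------
# Homology filtering, gene ranks, tandem clusters
# ---------------------------------------------------------------------------

def filter_homology(pairs: pd.DataFrame, evalue_max: float = 1e-100) -> pd.DataFrame:
    """Keep pairs with evalue ≤ threshold, canonicalized and deduplicated.

    Duplicate rows (a, b) / (b, a) collapse to one canonical pair
    keeping the smallest E-value; self-pairs are dropped.
    """
    df = pairs[pairs["evalue"] <= evalue_max].copy()
    df = df[df["gene_a"] != df["gene_b"]]
    lo = df[["gene_a", "gene_b"]].min(axis=1)
    hi = df[["gene_a", "gene_b"]].max(axis=1)
    df["gene_a"], df["gene_b"] = lo, hi
    df = df.sort_values("evalue").drop_duplicates(["gene_a", "gene_b"], keep="first")
    return df.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)


def gene_ranks(genes: pd.DataFrame) -> pd.DataFrame:
    """1-based rank of every gene along its chromosome by start coordinate.

    Expects columns gene_id, chromosome, start; ranks are computed over
    all genes supplied, which must be the full annotation.
    """
    df = genes.sort_values(["chromosome", "start"]).copy()
    df["rank"] = df.groupby("chromosome").cumcount() + 1
    return df[["gene_id", "chromosome", "rank"]].reset_index(drop=True)


@dataclass
class TandemCluster:
    chromosome: str
    members: list[str]          # in rank order
    subfamilies: dict[str, int] = field(default_factory=dict)


def tandem_clusters(
    ranks: pd.DataFrame,
    pairs: pd.DataFrame,
    max_gap: int = 1,
    subfamily_of: dict[str, str] | None = None,
) -> list[TandemCluster]:
    """Clusters of tandemly duplicated genes.

    Two genes are tandem-linked when they are homologous, on the same
    chromosome, and their gene ranks differ by at most ``max_gap``
    (default 1: strictly consecutive).  Clusters are connected
    components of these links, reported in rank order.
    """
    pos = ranks.set_index("gene_id")[["chromosome", "rank"]]
    g = nx.Graph()
    for a, b in pairs[["gene_a", "gene_b"]].itertuples(index=False):
        if a not in pos.index or b not in pos.index:
            continue
        ca, ra = pos.loc[a]
        cb, rb = pos.loc[b]
        if ca == cb and abs(int(ra) - int(rb)) <= max_gap:
            g.add_edge(a, b)
    clusters = []
    for comp in nx.connected_components(g):
        members = sorted(comp, key=lambda x: int(pos.loc[x, "rank"]))
        chrom = str(pos.loc[members[0], "chromosome"])
        comp_subs: dict[str, int] = {}
        if subfamily_of:
            for m in members:
                sub = subfamily_of.get(m, "unclassified")
                comp_subs[sub] = comp_subs.get(sub, 0) + 1
        clusters.append(TandemCluster(chrom, members, comp_subs))
    clusters.sort(key=lambda c: (c.chromosome, int(pos.loc[c.members[0], "rank"])))
    return clusters


# ---------------------------------------------------------------------------
# Collinear blocks
# ---------------------------------------------------------------------------

@dataclass
class CollinearBlock:
    chrom_a: str
    chrom_b: str
    anchors: list[tuple[str, str]]   # ordered by rank on chromosome A
    orientation: str                 # "same" or "inverted"
    score: int
    rank_span: int

    @property
    def anchor_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.anchors)


def _best_chain(
    matches: list[tuple[int, int, str, str]], orientation: str, max_rank_gap: int
) -> list[int]:
    """Indices of the highest-scoring monotone chain (DP, O(m^2)).

    Ties on length are broken by the smaller total rank span.
    """
    m = len(matches)
    if m == 0:
        return []
    sign = 1 if orientation == "same" else -1
    order = sorted(range(m), key=lambda i: (matches[i][0], sign * matches[i][1]))
    best_len = [1] * m
    prev = [-1] * m
    for oi, i in enumerate(order):
        ra, rb = matches[i][0], matches[i][1]
        for j in (order[k] for k in range(oi)):
            qa, qb = matches[j][0], matches[j][1]
            if qa >= ra or ra - qa > max_rank_gap:
                continue
            step_b = (rb - qb) * sign
            if step_b <= 0 or step_b > max_rank_gap:
                continue
            if best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j

    def span(end: int) -> int:
        idx, lo_a, hi_a, lo_b, hi_b = end, *([matches[end][0]] * 2), *([matches[end][1]] * 2)
        while prev[idx] != -1:
            idx = prev[idx]
            ra, rb = matches[idx][0], matches[idx][1]
            lo_a, hi_a = min(lo_a, ra), max(hi_a, ra)
            lo_b, hi_b = min(lo_b, rb), max(hi_b, rb)
        return (hi_a - lo_a) + (hi_b - lo_b)

    end = min(range(m), key=lambda i: (-best_len[i], span(i)))
    chain = []
    while end != -1:
        chain.append(end)
        end = prev[end]
    return chain[::-1]


def collinear_blocks(
    ranks_a: dict[str, int],
    ranks_b: dict[str, int],
    pairs: pd.DataFrame,
    chrom_a: str = "A",
    chrom_b: str = "B",
    min_anchors: int = 5,
    max_rank_gap: int = 25,
) -> list[CollinearBlock]:
    """Collinear blocks between two chromosomes from filtered homology.

    Anchors are chained by dynamic programming over (rank_a, rank_b)
    match positions in either orientation; consecutive anchors must be
    strictly monotone and within ``max_rank_gap`` on both axes.  The
    best chain is extracted, its matches removed, and the scan repeated
    until no chain reaches ``min_anchors``.
    """
    matches: list[tuple[int, int, str, str]] = []
    for a, b in pairs[["gene_a", "gene_b"]].itertuples(index=False):
        if a in ranks_a and b in ranks_b:
            matches.append((ranks_a[a], ranks_b[b], a, b))
        elif b in ranks_a and a in ranks_b:
            matches.append((ranks_a[b], ranks_b[a], b, a))
    blocks: list[CollinearBlock] = []
    remaining = matches
    while remaining:
        candidates = []
        for orientation in ("same", "inverted"):
            chain = _best_chain(remaining, orientation, max_rank_gap)
            if chain:
                candidates.append((len(chain), orientation, chain))
        if not candidates:
            break
        n, orientation, chain = max(candidates, key=lambda c: c[0])
        if n < min_anchors:
            break
        used = [remaining[i] for i in chain]
        ranks_used_a = [u[0] for u in used]
        ranks_used_b = [u[1] for u in used]
        span = (max(ranks_used_a) - min(ranks_used_a)) + (
            max(ranks_used_b) - min(ranks_used_b)
        )
        blocks.append(
            CollinearBlock(
                chrom_a,
                chrom_b,
                [(u[2], u[3]) for u in used],
                orientation,
                n,
                span,
            )
        )
        chain_set = set(chain)
        remaining = [m for i, m in enumerate(remaining) if i not in chain_set]
    blocks.sort(key=lambda b: (-b.score, b.rank_span))
    return blocks


def single_correspondence(pairs: pd.DataFrame) -> tuple[set[tuple[str, str]], float]:
    """Pairs in which each member appears exactly once, and their fraction.

    A duplication event shows single gene correspondence when neither
    gene participates in any other retained pair.
    """
    if pairs.empty:
        return set(), 0.0
    counts: dict[str, int] = {}
    for a, b in pairs[["gene_a", "gene_b"]].itertuples(index=False):
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    single = {
        (a, b)
        for a, b in pairs[["gene_a", "gene_b"]].itertuples(index=False)
        if counts[a] == 1 and counts[b] == 1
    }
    return single, len(single) / len(pairs)


def ks_histogram(
    ks_values: list[float], bin_width: float = 0.1, max_ks: float = 3.0
) -> pd.DataFrame:
    """Histogram of defined Ks values on fixed-width bins over [0, max_ks)."""
    edges = np.arange(0.0, max_ks + bin_width / 2, bin_width)
    vals = [k for k in ks_values if k is not None and 0 <= k < max_ks]
    counts, _ = np.histogram(vals, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
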