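"""Neighbor-joining phylogenies under the p-distance model.

Distances are proportions of mismatched residues with pairwise deletion
of gap sites; trees are built by the Saitou-Nei agglomeration and
internal edges carry bootstrap supports (percentage of column-resampled
replicates containing the same bipartition).  Trees are held in
:class:`skbio.TreeNode` and written as Newick with supports as internal
node labels.
"""

from __future__ import annotations

import numpy as np
from Bio import SeqIO
from skbio import DistanceMatrix
from skbio.tree import TreeNode

Alignment = dict[str, str]

GAP_CHARS = frozenset("-.")


def read_alignment(path: str) -> Alignment:
    """Load an aligned FASTA into an ordered id → row mapping."""
    aln = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
    lengths = {len(s) for s in aln.values()}
    if len(lengths) > 1:
        raise ValueError("alignment rows differ in length")
    return aln


def p_distance(alignment: Alignment) -> DistanceMatrix:
    """Pairwise p-distances (mismatches / compared sites, pairwise deletion).

    Sites with a gap in either row of a pair are excluded from that
    pair's comparison; a pair left with zero comparable sites is an
    error naming the pair.
    """
    ids = list(alignment)
    if len(ids) < 2:
        raise ValueError("need at least 2 taxa")
    rows = np.array([list(alignment[i]) for i in ids])
    if rows.ndim != 2:
        raise ValueError("alignment rows differ in length")
    is_gap = np.isin(rows, list(GAP_CHARS))
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~is_gap[i] & ~is_gap[j]
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable sites between {ids[i]!r} and {ids[j]!r}"
                )
            d[i, j] = d[j, i] = np.count_nonzero(rows[i][ok] != rows[j][ok]) / m
    return DistanceMatrix(d, ids)


def _clamped(li: float, lj: float) -> tuple[float, float]:
    # negative branch length: clamp to 0, move the deficit to the sibling
    if li < 0:
        li, lj = 0.0, lj + li
    if lj < 0:
        lj, li = 0.0, li + lj
    return max(li, 0.0), max(lj, 0.0)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted (trifurcating) tree.

    Q-matrix ties are broken by the smallest current-index pair, and
    negative branch-length estimates are clamped to zero with the
    deficit transferred to the sibling edge, so the result is
    deterministic with non-negative lengths.  For an additive input the
    tree's leaf-to-leaf path lengths reproduce the input exactly.
    """
    ids = list(dm.ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 taxa")
    d = np.asarray(dm.data, dtype=float).copy()
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    while len(nodes) > 3:
        r = len(nodes)
        rowsum = d.sum(axis=1)
        q = (r - 2) * d - rowsum[:, None] - rowsum[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        i, j = min(
            (int(a), int(b))
            for a, b in zip(*np.where(np.isclose(q, qmin, rtol=0, atol=1e-12)))
            if a < b
        )
        li = d[i, j] / 2 + (rowsum[i] - rowsum[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        li, lj = _clamped(li, lj)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = float(li), float(lj)
        new = TreeNode(children=[child_i, child_j])
        du = (d[i, :] + d[j, :] - d[i, j]) / 2
        keep = [k for k in range(r) if k not in (i, j)]
        d_new = np.zeros((r - 1, r - 1))
        d_new[: r - 2, : r - 2] = d[np.ix_(keep, keep)]
        d_new[-1, : r - 2] = d_new[: r - 2, -1] = du[keep]
        d = d_new
        nodes = [nodes[k] for k in keep] + [new]
    # closed-form three-point lengths for the final trifurcation
    la = (d[0, 1] + d[0, 2] - d[1, 2]) / 2
    lb = (d[0, 1] + d[1, 2] - d[0, 2]) / 2
    lc = (d[0, 2] + d[1, 2] - d[0, 1]) / 2
    for node, length in zip(nodes, (la, lb, lc)):
        node.length = float(max(length, 0.0))
    return TreeNode(children=nodes)


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, canonicalized.

    Each internal edge splits the tips in two; the side not containing
    the lexicographically smallest tip name is reported.
    """
    tips = sorted(t.name for t in tree.tips())
    ref = tips[0]
    n = len(tips)
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > n - 2:
            continue
        if ref in side:
            side = frozenset(tips) - side
        out.add(side)
    return out


def robinson_foulds(t1: TreeNode, t2: TreeNode) -> int:
    """Unweighted Robinson-Foulds distance (symmetric bipartition difference)."""
    return len(bipartitions(t1) ^ bipartitions(t2))


def bootstrap_support(
    alignment: Alignment, replicates: int = 1000, seed: int = 0
) -> TreeNode:
    """NJ tree with per-internal-edge bootstrap supports.

    Columns are resampled with replacement to the original length; each
    replicate tree votes for the bipartitions it contains, and each
    internal edge of the tree from the full alignment is labeled with
    the percentage of replicates supporting it.
    """
    if replicates < 1:
        raise ValueError("replicates must be ≥ 1")
    tree = neighbor_joining(p_distance(alignment))
    ids = list(alignment)
    rows = np.array([list(alignment[i]) for i in ids])
    length = rows.shape[1]
    counts: dict[frozenset[str], int] = {b: 0 for b in bipartitions(tree)}
    rng = np.random.default_rng(seed)
    for _ in range(replicates):
        cols = rng.integers(0, length, size=length)
        rep_aln = {i: "".join(rows[k][cols]) for k, i in enumerate(ids)}
        try:
            rep_tree = neighbor_joining(p_distance(rep_aln))
        except ValueError:
            continue  # a replicate can lose all comparable sites for a pair
        for b in bipartitions(rep_tree):
            if b in counts:
                counts[b] += 1
    tips = sorted(alignment)
    ref = tips[0]
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(tips) - 2:
            continue
        if ref in side:
            side = frozenset(tips) - side
        support = 100.0 * counts.get(side, 0) / replicates
        node.support = support
        node.name = str(int(round(support)))
    return tree


def write_newick(tree: TreeNode, path: str) -> None:
    tree.write(path, format="newick")


def random_additive_tree(
    n_taxa: int, seed: int
) -> tuple[TreeNode, DistanceMatrix]:
    """Random unrooted tree with positive branch lengths and its path metric.

    Taxa are attached one by one to a uniformly chosen existing edge;
    the returned distance matrix is exactly additive on the tree, which
    makes it a reconstruction oracle for neighbor joining.
    """
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa for a non-trivial topology")
    rng = np.random.default_rng(seed)

    def blen() -> float:
        return float(rng.uniform(0.05, 1.0))

    names = [f"t{i+1}" for i in range(n_taxa)]
    root = TreeNode(
        children=[TreeNode(name=names[k], length=blen()) for k in range(3)]
    )
    for name in names[3:]:
        edges = [n for n in root.traverse(include_self=False)]
        host = edges[int(rng.integers(len(edges)))]
        parent = host.parent
        u = float(rng.uniform(0.2, 0.8))
        old_len = host.length
        parent.remove(host)
        host.length = old_len * (1 - u)
        inner = TreeNode(
            children=[host, TreeNode(name=name, length=blen())],
            length=old_len * u,
        )
        parent.append(inner)
    dm = root.tip_tip_distances()
    order = sorted(dm.ids)
    return root, dm.filter(order)
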