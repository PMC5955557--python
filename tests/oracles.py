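"""Independent brute-force oracles used only by the tests.

These re-derive NG86 quantities through Biopython translation and
explicit pathway enumeration, and evaluate four-taxon tree topologies
by ordinary least squares, deliberately sharing no code with the
package implementations they check.
"""

from itertools import permutations

import numpy as np
from Bio.Seq import Seq


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def brute_sites(codon: str) -> tuple[float, float]:
    syn = 0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if _aa(mutant) != "*" and _aa(mutant) == _aa(codon):
                syn += 1
    return syn / 3, 3 - syn / 3


def brute_counts(a: str, b: str) -> tuple[float, float] | None:
    """Pathway-averaged differences; None when stops block every pathway."""
    diffs = [i for i in range(3) if a[i] != b[i]]
    if not diffs:
        return 0.0, 0.0
    outcomes = []
    for order in permutations(diffs):
        cur, sd, nd, blocked = a, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if _aa(nxt) == "*":
                blocked = True
                break
            if _aa(nxt) == _aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            outcomes.append((sd, nd))
    if not outcomes:
        return None
    return (
        float(np.mean([o[0] for o in outcomes])),
        float(np.mean([o[1] for o in outcomes])),
    )


def least_squares_quartet(ids: list[str], dm: np.ndarray) -> frozenset[str]:
    """Best of the 3 unrooted four-taxon topologies by OLS branch fitting.

    Returns the cherry containing the first taxon, identifying the
    split.  For the split (ab|cd) the five branch lengths solve a linear
    system against the six pairwise distances.
    """
    assert len(ids) == 4
    best = None
    for (i, j, k, l) in ((0, 1, 2, 3), (0, 2, 1, 3), (0, 3, 1, 2)):
        # design matrix over branches (ei, ej, ek, el, middle)
        pairs = [(i, j), (i, k), (i, l), (j, k), (j, l), (k, l)]
        rows = []
        for a, b in pairs:
            row = [0.0] * 5
            for t, e in ((i, 0), (j, 1), (k, 2), (l, 3)):
                if t in (a, b):
                    row[e] = 1.0
            same_side = {a, b} in ({i, j}, {k, l})
            row[4] = 0.0 if same_side else 1.0
            rows.append(row)
        y = np.array([dm[a, b] for a, b in pairs])
        x, res, *_ = np.linalg.lstsq(np.array(rows), y, rcond=None)
        rss = float(((np.array(rows) @ x - y) ** 2).sum())
        if best is None or rss < best[0]:
            best = (rss, frozenset((ids[i], ids[j])))
    return best[1]
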