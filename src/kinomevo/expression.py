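"""Expression normalization and the differential screen.

Counts are normalized to RPKM (reads per kilobase of exon model per
million mapped reads, with the library size taken as the column sum),
fold changes are treatment-vs-control means on the normalized scale
with a pseudo-count of 1, and a gene is retained when |FC| > 1.5 on the
linear scale (|log2FC| > log2 1.5) and a two-sided Welch test on
log2(RPKM + 1) gives p < 0.01.  The Welch test replaces the
empirical-Bayes machinery of dedicated microarray/RNA-seq packages; the
screen itself (the two gates) is what the pipeline is specified to
apply.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

FC_THRESHOLD = 1.5
P_THRESHOLD = 0.01
PSEUDOCOUNT = 1.0


def rpkm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """RPKM-normalize a genes × samples count matrix.

    ``gene_lengths`` are exon-model (CDS) lengths in bases; the
    per-sample library size is the column sum of the supplied matrix.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()])[:5]
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    return counts.div(lengths / 1e3, axis=0).div(lib / 1e6, axis=1)


def log2_fold_change(
    normalized: pd.DataFrame,
    groups: pd.DataFrame,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.Series:
    """Per-gene log2((mean treatment + ε)/(mean control + ε))."""
    t_samples, c_samples = _split(normalized, groups)
    mt = normalized[t_samples].mean(axis=1)
    mc = normalized[c_samples].mean(axis=1)
    return np.log2((mt + pseudocount) / (mc + pseudocount)).rename("log2fc")


def _split(
    normalized: pd.DataFrame, groups: pd.DataFrame
) -> tuple[list[str], list[str]]:
    g = groups.set_index("sample")["group"]
    t = [s for s in normalized.columns if g.get(s) == "treatment"]
    c = [s for s in normalized.columns if g.get(s) == "control"]
    if not t or not c:
        raise ValueError("both treatment and control groups must be non-empty")
    return t, c


def differential_screen(
    normalized: pd.DataFrame,
    groups: pd.DataFrame,
    fc_threshold: float = FC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Welch-test screen: retain genes with |FC| > 1.5 and p < 0.01.

    The test is two-sided on log2(normalized + 1) with unequal
    variances; p-values are raw by default (``bh_adjust`` switches to
    Benjamini-Hochberg adjusted values before gating).
    """
    t_samples, c_samples = _split(normalized, groups)
    if len(t_samples) < 2 or len(c_samples) < 2:
        raise ValueError("need at least 2 samples per group")
    logm = np.log2(normalized + 1.0)
    res = stats.ttest_ind(
        logm[t_samples], logm[c_samples], axis=1, equal_var=False
    )
    pvals = pd.Series(res.pvalue, index=normalized.index).fillna(1.0)
    if bh_adjust:
        pvals = pd.Series(
            stats.false_discovery_control(pvals, method="bh"),
            index=pvals.index,
        )
    lfc = log2_fold_change(normalized, groups)
    retained = (lfc.abs() > np.log2(fc_threshold)) & (pvals < p_threshold)
    return pd.DataFrame(
        {"gene_id": normalized.index, "log2fc": lfc, "p_value": pvals,
         "retained": retained}
    ).reset_index(drop=True)
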