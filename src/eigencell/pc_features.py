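"""Class-informative PC selection by rank-sum testing with BH correction.

For each one-vs-all class split, every variance-filtered PC is tested with
a two-tailed Wilcoxon rank-sum (Mann-Whitney) test comparing its score
distribution between the class of interest and all remaining cells. The
p-values are Benjamini-Hochberg adjusted within that class's family, and
PCs with adjusted p below alpha are kept, ranked by adjusted p.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .containers import PcSelection, ScoreMatrix


def rank_sum_test(group_a, group_b) -> float:
    """Two-sided Mann-Whitney rank-sum p-value.

    Exact enumeration when both groups have at most 8 observations and no
    ties are present; otherwise the normal approximation with tie and
    continuity corrections.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (a.size <= 8 and b.size <= 8 and no_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(min(res.pvalue, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_informative_pcs(
    scores: ScoreMatrix,
    labels,
    class_name: str,
    alpha: float = 0.05,
) -> PcSelection:
    """One-vs-all rank-sum screen over PC score columns.

    Tests every column of ``scores`` (the variance-filtered set), adjusts
    within exactly that family, and keeps PCs with adjusted p < alpha
    ranked ascending by adjusted p (ties broken by PC index).
    """
    labels = np.asarray(labels)
    if class_name not in labels:
        raise ValueError(f"class {class_name!r} absent from labels")
    pos = labels == class_name
    if pos.sum() < 2 or (~pos).sum() < 2:
        raise ValueError("need at least 2 cells in both the class and its complement")

    X = np.asarray(scores.values, float)
    p_raw = np.array([rank_sum_test(X[pos, j], X[~pos, j]) for j in range(X.shape[1])])
    p_adj = bh_adjust(p_raw)

    hits = np.flatnonzero(p_adj < alpha)
    if hits.size == 0 and alpha <= 0:
        warnings.warn("alpha <= 0 selects no PCs", stacklevel=2)
    order = hits[np.lexsort((scores.pc_indices[hits], p_adj[hits]))]
    return PcSelection(
        class_name=class_name,
        pc_indices=scores.pc_indices[order],
        tested_pc_indices=scores.pc_indices.copy(),
        p_raw=p_raw,
        p_adj=p_adj,
        alpha=alpha,
    )
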