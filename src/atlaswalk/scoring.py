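"""Differential expression, preranked GSEA and per-cell signature scoring.

The comparison of two cell populations proceeds in four steps: (1) a
Wilcoxon rank-sum test per gene with a minimum expressed-fraction filter
(min.pct-style), reporting log2 fold changes of pseudocounted group means;
(2) ranking all reported genes by log2FC from most up- to most
down-regulated; (3) preranked gene-set enrichment with a weighted
Kolmogorov-Smirnov running statistic, whose core-enrichment ("leading
edge") genes are extracted; and (4) a per-cell signature score over those
core genes — each gene max-normalized over cells, scores averaged per cell
and rescaled to [0, 1] — whose distributions across conditions are compared
with a two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

logger = logging.getLogger(__name__)

#: combined group size at or below which exact rank-sum p-values are used
EXACT_WILCOXON_MAX_N = 25


@dataclass
class GeneSet:
    name: str
    genes: list[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene set must be nonempty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene set genes must be unique")


@dataclass
class GseaResult:
    """Enrichment of one gene set against one ranked list."""

    es: float
    p_value: float
    leading_edge: list[str]
    running_sum: np.ndarray

    def __post_init__(self) -> None:
        if not -1 - 1e-9 <= self.es <= 1 + 1e-9:
            raise ValueError("enrichment score must lie in [-1, 1]")


def _to_dense(normalized: ad.AnnData, cells) -> np.ndarray:
    X = normalized[list(cells), :].X
    return X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)


def wilcoxon_de(
    normalized: ad.AnnData,
    group1,
    group2,
    min_frac: float = 0.05,
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum test between two cell groups.

    Genes are reported only when expressed (count > 0) in at least
    ``min_frac`` of the cells of one of the two groups. P-values use the
    tie-corrected normal approximation, switching to the exact rank-sum
    distribution when the combined group size is at most
    ``EXACT_WILCOXON_MAX_N`` and the gene's values are tie-free. The log2
    fold change is ``log2(mean1 + 1) - log2(mean2 + 1)`` on the normalized
    expression means per group.

    Returns a DataFrame with columns gene, log2_fold_change, p_value,
    pct_expressed_group1, pct_expressed_group2.
    """
    g1 = pd.Index(group1)
    g2 = pd.Index(group2)
    if len(g1.intersection(g2)):
        raise ValueError("group1 and group2 must be disjoint")
    if len(g1) < 3 or len(g2) < 3:
        raise ValueError("each group needs at least 3 cells")
    x1 = _to_dense(normalized, g1)
    x2 = _to_dense(normalized, g2)
    pct1 = (x1 > 0).mean(axis=0)
    pct2 = (x2 > 0).mean(axis=0)
    keep = np.maximum(pct1, pct2) >= min_frac
    genes = np.asarray(normalized.var_names)[keep]
    x1, x2 = x1[:, keep], x2[:, keep]
    pct1, pct2 = pct1[keep], pct2[keep]

    mean1 = x1.mean(axis=0)
    mean2 = x2.mean(axis=0)
    log2fc = np.log2(mean1 + 1.0) - np.log2(mean2 + 1.0)

    n1, n2 = x1.shape[0], x2.shape[0]
    if x1.shape[1] == 0:
        pvals = np.array([])
    elif n1 + n2 <= EXACT_WILCOXON_MAX_N:
        pvals = np.empty(x1.shape[1])
        for j in range(x1.shape[1]):
            pooled = np.concatenate([x1[:, j], x2[:, j]])
            method = "exact" if len(np.unique(pooled)) == len(pooled) else "asymptotic"
            pvals[j] = stats.mannwhitneyu(
                x1[:, j], x2[:, j], alternative="two-sided", method=method
            ).pvalue
    else:
        res = stats.mannwhitneyu(
            x1, x2, alternative="two-sided", method="asymptotic", axis=0
        )
        pvals = np.atleast_1d(res.pvalue)
    return pd.DataFrame(
        {
            "gene": genes,
            "log2_fold_change": log2fc,
            "p_value": pvals,
            "pct_expressed_group1": pct1,
            "pct_expressed_group2": pct2,
        }
    ).reset_index(drop=True)


def rank_by_log2fc(de: pd.DataFrame) -> pd.DataFrame:
    """Order genes from most up- to most down-regulated.

    Sorted by log2 fold change descending; ties broken by ascending
    p-value, then gene name. The output is a permutation of the input.
    """
    if de.empty:
        raise ValueError("empty differential expression result")
    return de.sort_values(
        ["log2_fold_change", "p_value", "gene"],
        ascending=[False, True, True],
        kind="stable",
    ).reset_index(drop=True)


def _running_sum(scores: np.ndarray, hit: np.ndarray, weight: float) -> np.ndarray:
    """Weighted KS running statistic over a ranked list."""
    n = len(scores)
    nh = int(hit.sum())
    w = np.abs(scores) ** weight
    denom = w[hit].sum()
    incr = np.zeros(n)
    if denom > 0:
        incr[hit] = w[hit] / denom
    else:  # all in-set scores are zero: equal increments
        incr[hit] = 1.0 / nh
    incr[~hit] = -1.0 / (n - nh)
    return np.cumsum(incr)


def gsea_preranked(
    ranked: pd.DataFrame,
    gene_set: GeneSet,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> GseaResult:
    """Preranked GSEA with leading-edge extraction and a permutation p-value.

    ``ranked`` must have columns ``gene`` and a score column
    (``log2_fold_change``). Hits increment the running sum proportionally
    to |score|**weight normalized over in-set genes; misses decrement by
    1/(N - Nh). The enrichment score is the running-sum value of maximal
    absolute deviation; the leading edge contains the in-set genes at or
    before the peak for a positive score, at or after it for a negative
    one. The p-value permutes the gene labels (hit positions) ``n_perm``
    times, counting permutations with an equal-or-more-extreme score of the
    same sign, with an add-one correction.
    """
    genes = ranked["gene"].to_numpy(dtype=object)
    score_col = "log2_fold_change" if "log2_fold_change" in ranked else "score"
    scores = ranked[score_col].to_numpy(dtype=float)
    n = len(genes)
    in_set = np.isin(genes, list(gene_set.genes))
    nh = int(in_set.sum())
    if nh == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if nh == n:
        raise ValueError("gene set covers the entire ranked list")

    rs = _running_sum(scores, in_set, weight)
    peak = int(np.argmax(np.abs(rs)))
    es = float(np.clip(rs[peak], -1.0, 1.0))  # guard rounding at the extremes
    if es >= 0:
        le_mask = in_set & (np.arange(n) <= peak)
    else:
        le_mask = in_set & (np.arange(n) >= peak)
    leading_edge = list(genes[le_mask])

    rng = np.random.default_rng(seed)
    more_extreme = 0
    for _ in range(n_perm):
        perm_hit = np.zeros(n, dtype=bool)
        perm_hit[rng.choice(n, size=nh, replace=False)] = True
        prs = _running_sum(scores, perm_hit, weight)
        pes = prs[np.argmax(np.abs(prs))]
        if es >= 0:
            more_extreme += pes >= es
        else:
            more_extreme += pes <= es
    p = (1.0 + more_extreme) / (n_perm + 1.0)
    return GseaResult(es=es, p_value=float(p), leading_edge=leading_edge, running_sum=rs)


def score_cells(
    normalized: ad.AnnData,
    core_genes: list[str],
    name: str = "signature",
) -> pd.Series:
    """Per-cell signature score over a core gene set, rescaled to [0, 1].

    Each core gene is divided by its maximum over the scored population
    (genes never detected are dropped with a warning), the per-cell mean of
    these normalized values is taken, and the resulting vector is rescaled
    to [0, 1] by (x - min) / (max - min). If all per-cell means coincide
    the rescaling is undefined and all scores are set to 0 with a warning.
    """
    present = [g for g in core_genes if g in set(normalized.var_names)]
    if not present:
        raise ValueError("no core genes present in the expression matrix")
    X = normalized[:, present].X
    dense = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
    gmax = dense.max(axis=0)
    zero = gmax == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} core gene(s) undetected in all cells; dropped",
            stacklevel=2,
        )
        dense = dense[:, ~zero]
        gmax = gmax[~zero]
    if dense.shape[1] == 0:
        raise ValueError("all core genes are undetected in this population")
    per_cell = (dense / gmax).mean(axis=1)
    lo, hi = per_cell.min(), per_cell.max()
    if hi == lo:
        warnings.warn(
            "degenerate signature: all per-cell means equal; scores set to 0",
            stacklevel=2,
        )
        scaled = np.zeros_like(per_cell)
    else:
        scaled = (per_cell - lo) / (hi - lo)
    return pd.Series(scaled, index=normalized.obs_names, name=name)


def ks_compare(scores_a, scores_b, method: str = "asymp") -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of score distributions.

    Returns ``(D, p)`` where D is the supremum of the absolute difference
    of the two empirical CDFs. The p-value is asymptotic two-sided by
    default; ``method="exact"`` or ``"auto"`` selects scipy's exact
    small-sample computation.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
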