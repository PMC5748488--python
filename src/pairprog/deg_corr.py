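"""Differential expression and gene-set correlation profiling.

Differential expression between two sample groups uses Welch's unequal-
variance t test per gene with Benjamini-Hochberg FDR across all tested
genes.  Correlation profiling compares the Kendall-tau distribution of a
focal gene set against size-matched random control sets, summarized as
cumulative relative frequencies, medians, and a Mann-Whitney comparison p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import kendalltau, ttest_ind
from statsmodels.stats.multitest import multipletests

from .data_model import ExpressionMatrix, PipelineConfig
from .survival_stats import mann_whitney


def deg_table(matrix: ExpressionMatrix, group_a: list[str], group_b: list[str],
              cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Per-gene Welch t test of group A vs group B with BH-adjusted q.

    Columns: ``mean_diff`` (A - B, log2 units), ``t``, ``p``, ``q``,
    ``direction`` ("up"/"down" in group A).  Genes with zero variance in both
    groups and equal means get p = 1 by convention (p = 0 if means differ).
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    a = matrix.subset_samples(list(group_a)).values
    b = matrix.subset_samples(list(group_b)).values
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = ttest_ind(a, b, axis=1, equal_var=False)
    diff = a.mean(axis=1) - b.mean(axis=1)
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate & (diff == 0), 1.0, p)
    p = np.where(degenerate & (diff != 0), 0.0, p)
    t = np.where(np.isfinite(t), t, np.where(diff == 0, 0.0,
                                             np.sign(diff) * np.inf))
    q = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame({
        "mean_diff": diff, "t": t, "p": p, "q": q,
        "direction": np.where(diff > 0, "up", "down"),
    }, index=pd.Index(matrix.gene_ids, name="gene_id"))
    return table


def top_genes(table: pd.DataFrame, direction: str | None = None,
              n: int = 1000, q_max: float | None = None) -> list[str]:
    """Top-n genes by ascending p, optionally within one direction and under
    a q threshold (mirrors 'top 1000 most significant' selections)."""
    sub = table
    if direction is not None:
        sub = sub[sub["direction"] == direction]
    if q_max is not None:
        sub = sub[sub["q"] <= q_max]
    return list(sub.sort_values(["p", "mean_diff"]).index[:n])


def coexpression_module(matrix: ExpressionMatrix, genes: list[str] | set[str],
                        tau_min: float = 0.15, min_degree: int = 2,
                        min_size: int = 3) -> set[str]:
    """Largest mutually co-expressed subset of ``genes`` (survival-blind).

    Builds the graph with an edge where |Kendall tau| >= ``tau_min``, prunes
    nodes of degree < ``min_degree`` (2-core by default, so a single lucky
    correlation cannot attach a gene), and returns the largest connected
    component.  If that component is smaller than ``min_size`` the filter is
    considered uninformative and the input set is returned unchanged.

    A co-regulated block driven by a shared factor survives this filter
    almost surely while independent genes are pruned; it plays the role of a
    functional-module coherence step without using any survival data.
    """
    gene_list = sorted(set(genes))
    if len(gene_list) < min_size:
        return set(gene_list)
    missing = [g for g in gene_list if g not in matrix.gene_ids]
    if missing:
        raise KeyError(f"genes not in matrix: {missing[:5]}")
    V = matrix.subset_genes(gene_list).values
    k = len(gene_list)
    adj = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            tau = kendalltau(V[i], V[j])[0]
            if np.isfinite(tau) and abs(tau) >= tau_min:
                adj[i, j] = adj[j, i] = True
    # iterative degree pruning (k-core)
    alive = np.ones(k, dtype=bool)
    while True:
        deg = (adj & alive[None, :]).sum(axis=1)
        drop = alive & (deg < min_degree)
        if not drop.any():
            break
        alive[drop] = False
    # largest connected component among survivors
    best: list[int] = []
    seen = np.zeros(k, dtype=bool)
    for s in np.flatnonzero(alive):
        if seen[s]:
            continue
        stack, comp = [s], []
        while stack:
            u = stack.pop()
            if seen[u] or not alive[u]:
                continue
            seen[u] = True
            comp.append(u)
            stack.extend(np.flatnonzero(adj[u] & alive))
        if len(comp) > len(best):
            best = comp
    if len(best) < min_size:
        return set(gene_list)
    return {gene_list[i] for i in best}


@dataclass
class CorrelationProfile:
    target_gene: str
    focal_taus: pd.Series                  # gene -> tau with target
    control_taus: list[pd.Series]          # one per control set
    focal_median: float
    control_median: float
    comparison_p: float

    def pooled_control(self) -> np.ndarray:
        return np.concatenate([s.to_numpy() for s in self.control_taus])

    @staticmethod
    def cumulative(taus: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(sorted taus, cumulative relative frequency) for plotting."""
        x = np.sort(np.asarray(taus, dtype=float))
        return x, np.arange(1, x.size + 1) / x.size


def correlation_profile(matrix: ExpressionMatrix, target_gene: str,
                        focal_set: list[str], n_controls: int,
                        seed: int) -> CorrelationProfile:
    """Kendall-tau of focal vs random control genes against a target gene.

    Control sets are size-matched to the focal set and drawn (each without
    replacement, seeded) from genes outside the focal set and target.
    """
    if not focal_set:
        raise ValueError("empty focal set")
    if n_controls < 1:
        raise ValueError("n_controls must be >= 1")
    if target_gene not in matrix.gene_ids:
        raise KeyError(f"target gene {target_gene!r} not in matrix")
    missing = [g for g in focal_set if g not in matrix.gene_ids]
    if missing:
        raise KeyError(f"focal genes not in matrix: {missing[:5]}")
    target = matrix.row(target_gene)

    def taus(genes: list[str]) -> pd.Series:
        vals = [kendalltau(matrix.row(g), target)[0] for g in genes]
        return pd.Series(vals, index=genes, dtype=float)

    focal_taus = taus(list(focal_set))
    pool = [g for g in matrix.gene_ids
            if g not in set(focal_set) and g != target_gene]
    if len(pool) < len(focal_set):
        raise ValueError("not enough non-focal genes for control sets")
    rng = np.random.default_rng(seed)
    control_taus = []
    for _ in range(n_controls):
        picked = list(rng.choice(pool, size=len(focal_set), replace=False))
        control_taus.append(taus(picked))
    pooled = np.concatenate([s.to_numpy() for s in control_taus])
    return CorrelationProfile(
        target_gene=target_gene,
        focal_taus=focal_taus,
        control_taus=control_taus,
        focal_median=float(np.median(focal_taus)),
        control_median=float(np.median(pooled)),
        comparison_p=mann_whitney(focal_taus.to_numpy(), pooled),
    )
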