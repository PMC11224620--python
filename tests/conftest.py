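"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import statistics
from itertools import combinations
from math import comb, sqrt

import numpy as np
import pandas as pd
import pytest

from modhub import DEGTable, FunctionalNetwork, GeneModule


@pytest.fixture
def five_gene_net() -> FunctionalNetwork:
    """Gene A with weights {B:0.9, C:0.8, D:0.1, E:0.2}; other pairs 0."""
    genes = ("A", "B", "C", "D", "E")
    W = np.zeros((5, 5))
    for g, w in {"B": 0.9, "C": 0.8, "D": 0.1, "E": 0.2}.items():
        i = genes.index(g)
        W[0, i] = W[i, 0] = w
    return FunctionalNetwork(genes, W)


def random_network(rng: np.random.Generator, n: int) -> FunctionalNetwork:
    """Symmetric network with i.i.d. Uniform(0,1) off-diagonal weights."""
    W = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    W[iu] = rng.uniform(size=iu[0].size)
    W += W.T
    genes = tuple(f"g{i:03d}" for i in range(n))
    return FunctionalNetwork(genes, W)


def naive_connectivity_z(
    net: FunctionalNetwork,
    module: GeneModule,
    gene: str,
    z_denominator: str = "se",
) -> float:
    """Element-by-element recomputation of the connectivity z-score."""
    others = [h for h in net.genes if h != gene]
    vals = [net.weight(gene, h) for h in others]
    mu = statistics.fmean(vals)
    sigma = statistics.stdev(vals)
    members = sorted(m for m in module.members if m in net.genes and m != gene)
    xbar = statistics.fmean(net.weight(gene, m) for m in members)
    n = len(members)
    denom = sigma / sqrt(n) if z_denominator == "se" else sigma / n
    return (xbar - mu) / denom


def enumerate_ranksum_p_greater(x, y) -> float:
    """Exhaustive one-sided rank-sum permutation p-value (midranks)."""
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1 = len(x)
    obs = ranks[:n1].sum()
    hits = sum(
        1
        for idx in combinations(range(len(pooled)), n1)
        if ranks[list(idx)].sum() >= obs - 1e-9
    )
    return hits / comb(len(pooled), n1)


def hypergeom_tail_by_enumeration(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), by direct summation."""
    return sum(
        comb(K, i) * comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
        if n - i <= N - K
    ) / comb(N, n)


def deg_frame(genes, padj, log2fc=None, pvalue=None) -> DEGTable:
    """DEG table fixture with explicit padj values."""
    n = len(genes)
    return DEGTable(
        pd.DataFrame(
            {
                "gene": list(genes),
                "log2fc": log2fc if log2fc is not None else [1.0] * n,
                "pvalue": pvalue if pvalue is not None else list(padj),
                "padj": list(padj),
            }
        )
    )
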