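"""Perturbation-validation statistics for a candidate hub gene.

After silencing (or overexpressing) a putative hub, these tests ask
whether the transcriptomic response lines up with the network's
predictions:

* :func:`deg_connectivity_test` — are differentially expressed genes
  more strongly connected to the hub than unaffected genes?
  (one-sided Wilcoxon rank-sum on hub-edge weights)
* :func:`fisher_overlap` — does a gene set (e.g. the vulnerability
  module) overlap the DEG set more than chance?  (one-sided Fisher /
  hypergeometric tail)
* :func:`signed_overlap` — do two perturbation experiments (e.g.
  in vitro and in vivo) call the same genes in the same direction?
* :func:`rank_enrichment_curve` — cumulative DEG enrichment among
  genes ranked by connectivity to the hub, as fold over the random
  expectation.

DEG calls default to BH-adjusted p < 0.05; genes with a missing
adjusted p are excluded from the universe rather than treated as
non-significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .net_io import DEGTable, FunctionalNetwork

__all__ = [
    "bh_adjust",
    "deg_connectivity_test",
    "fisher_overlap",
    "signed_overlap",
    "rank_enrichment_curve",
    "RankSumResult",
    "OverlapTestResult",
    "SignedOverlapResult",
    "EnrichmentCurve",
]

#: Largest group size for which the exact rank-sum distribution is used.
EXACT_RANKSUM_MAX_GROUP = 20


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Each adjusted value lies in ``[p, 1]`` and the adjustment is
    monotone in the p-value ranks.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-dimensional")
    if p.size == 0:
        return np.array([])
    if np.isnan(p).any() or p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# rank-sum test of DEG connectivity


@dataclass(frozen=True)
class RankSumResult:
    """One-sided rank-sum comparison of hub connectivities (DEG > non-DEG)."""

    pvalue: float
    method: str  # "exact" | "normal_approx"
    n_deg: int
    n_nondeg: int
    median_deg: float
    median_nondeg: float
    statistic: float  # rank sum of the DEG group (midranks)
    threshold: str
    cutoff: float


def _exact_ranksum_p_greater(x: np.ndarray, y: np.ndarray) -> float:
    """Exact permutation p-value for the one-sided rank-sum test.

    Computes ``P(S >= s_obs)`` where ``S`` is the midrank sum of a
    uniformly random size-``len(x)`` subset of the pooled sample and
    ``s_obs`` the observed rank sum of ``x``.  Handles ties via
    midranks; uses a subset-sum counting recursion over the doubled
    (integer) ranks, so cost is ``O(N * n1 * N^2)`` rather than
    ``C(N, n1)`` enumeration.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r2 = np.rint(2 * ranks).astype(np.int64)  # midranks are multiples of 1/2
    n1 = len(x)
    s_obs = int(r2[:n1].sum())
    total = int(r2.sum())
    # counts[k, s] = number of k-subsets with doubled-rank sum s
    counts = np.zeros((n1 + 1, total + 1))
    counts[0, 0] = 1.0
    for r in r2:
        for k in range(n1, 0, -1):  # descending so each item is used once
            counts[k, r:] += counts[k - 1, : total + 1 - r]
    n_ge = counts[n1, s_obs:].sum()
    return float(n_ge / comb(len(pooled), n1))


def deg_connectivity_test(
    net: FunctionalNetwork,
    hub: str,
    degs: DEGTable,
    *,
    threshold: str = "padj",
    cutoff: float = 0.05,
    max_exact: int = EXACT_RANKSUM_MAX_GROUP,
) -> RankSumResult:
    """Test whether DEGs are more connected to the hub than non-DEGs.

    The universe is every gene present in both the network and the DEG
    table (with a non-missing threshold value), excluding the hub
    itself.  The one-sided alternative is "the DEG group has greater
    connectivity".  When both groups have at most ``max_exact`` members
    the exact (tie-aware) permutation distribution of the rank sum is
    used; otherwise the normal approximation with tie and continuity
    corrections.
    """
    hub_i = net.index_of(hub)
    tested = degs.tested(threshold)
    universe = [g for g in net.genes if g in tested and g != hub]
    if not universe:
        raise ValueError("no overlap between network and DEG table")
    sig = degs.significant(threshold, cutoff)
    is_deg = np.array([g in sig for g in universe])
    if is_deg.all():
        raise ValueError("empty comparison group: every universe gene is a DEG")
    if not is_deg.any():
        raise ValueError("empty comparison group: no DEGs in the universe")
    idx = np.array([net.index_of(g) for g in universe])
    w = net.weights[hub_i, idx]
    x, y = w[is_deg], w[~is_deg]

    ranks = stats.rankdata(w)
    statistic = float(ranks[is_deg].sum())
    if len(x) <= max_exact and len(y) <= max_exact:
        p = _exact_ranksum_p_greater(x, y)
        method = "exact"
    else:
        p = float(
            stats.mannwhitneyu(
                x, y, alternative="greater", method="asymptotic", use_continuity=True
            ).pvalue
        )
        method = "normal_approx"
    return RankSumResult(
        pvalue=p,
        method=method,
        n_deg=len(x),
        n_nondeg=len(y),
        median_deg=float(np.median(x)),
        median_nondeg=float(np.median(y)),
        statistic=statistic,
        threshold=threshold,
        cutoff=cutoff,
    )


# ---------------------------------------------------------------------------
# Fisher overlap tests


@dataclass(frozen=True)
class OverlapTestResult:
    """One-sided (enrichment) Fisher's exact test on a 2x2 overlap table."""

    in_both: int
    in_a_only: int
    in_b_only: int
    in_neither: int
    odds_ratio: float
    pvalue: float
    universe_size: int
    haldane: bool = False  # 0.5 added to every cell for the OR (a cell was 0)

    @property
    def table(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return ((self.in_both, self.in_a_only), (self.in_b_only, self.in_neither))


def fisher_overlap(
    set_a, set_b, universe, *, alternative: str = "greater"
) -> OverlapTestResult:
    """Enrichment of the overlap of two gene sets within a universe.

    The p-value is the hypergeometric upper tail
    ``P(X >= |A ∩ B|)`` with ``X ~ Hypergeom(N, |A|, |B|)``.  Elements
    of either set outside the universe are dropped with a warning.  The
    odds ratio is the sample odds ratio ``ad/bc``, with a Haldane 0.5
    correction applied to all cells (and flagged) only when some cell
    is zero.
    """
    if alternative != "greater":
        raise ValueError("only the 'greater' (enrichment) alternative is supported")
    universe = frozenset(universe)
    if len(universe) < 4:
        raise ValueError("universe must contain at least 4 genes")
    a_in, b_in = frozenset(set_a), frozenset(set_b)
    if a_in - universe or b_in - universe:
        import warnings

        warnings.warn(
            f"{len(a_in - universe) + len(b_in - universe)} set elements "
            "outside the universe were dropped",
            stacklevel=2,
        )
    A, B = a_in & universe, b_in & universe
    if not A or not B:
        raise ValueError("a set is empty after intersecting with the universe")
    N = len(universe)
    k = len(A & B)
    a, b, c = k, len(A) - k, len(B) - k
    d = N - a - b - c
    p = float(stats.hypergeom.sf(k - 1, N, len(A), len(B)))
    haldane = 0 in (a, b, c, d)
    if haldane:
        oratio = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        oratio = a * d / (b * c)
    return OverlapTestResult(a, b, c, d, float(oratio), p, N, haldane)


@dataclass(frozen=True)
class SignedOverlapResult:
    """Direction-aware overlap of two DEG tables."""

    up: OverlapTestResult
    down: OverlapTestResult
    concordant: OverlapTestResult
    n_discordant: int
    discordant_genes: tuple[str, ...]


def signed_overlap(
    deg_a: DEGTable,
    deg_b: DEGTable,
    *,
    threshold: str = "padj",
    cutoff: float = 0.05,
    universe=None,
) -> SignedOverlapResult:
    """Overlap of up- and downregulated DEGs between two experiments.

    Both tables are thresholded identically; the universe defaults to
    genes tested in both.  Direction tests compare up-with-up and
    down-with-down sets; the combined concordant test places the
    same-sign overlap in the "both" cell, with genes significant in
    both tables but with opposite fold-change signs counted as
    discordant (they appear in the single-set cells) and reported.
    """
    if universe is None:
        universe = deg_a.tested(threshold) & deg_b.tested(threshold)
    universe = frozenset(universe)
    sig_a = deg_a.significant(threshold, cutoff) & universe
    sig_b = deg_b.significant(threshold, cutoff) & universe

    def split(table: DEGTable, sig):
        lfc = table.frame["log2fc"]
        up = frozenset(g for g in sig if lfc[g] > 0)
        return up, sig - up

    up_a, down_a = split(deg_a, sig_a)
    up_b, down_b = split(deg_b, sig_b)
    up = fisher_overlap(up_a, up_b, universe)
    down = fisher_overlap(down_a, down_b, universe)

    concordant_set = (up_a & up_b) | (down_a & down_b)
    discordant = sorted((sig_a & sig_b) - concordant_set)
    N = len(universe)
    k = len(concordant_set)
    a_only = len(sig_a) - k
    b_only = len(sig_b) - k
    neither = N - k - a_only - b_only
    p = float(stats.hypergeom.sf(k - 1, N, len(sig_a), len(sig_b)))
    haldane = 0 in (k, a_only, b_only, neither)
    if haldane:
        oratio = (k + 0.5) * (neither + 0.5) / ((a_only + 0.5) * (b_only + 0.5))
    else:
        oratio = k * neither / (a_only * b_only)
    concordant = OverlapTestResult(k, a_only, b_only, neither, oratio, p, N, haldane)
    return SignedOverlapResult(up, down, concordant, len(discordant), tuple(discordant))


# ---------------------------------------------------------------------------
# rank-enrichment curve


@dataclass(frozen=True)
class EnrichmentCurve:
    """Cumulative DEG enrichment along a connectivity ranking.

    ``fold[i] = (hits[i]/cutoffs[i]) / (m/N)`` — precision among the
    top-k relative to DEG prevalence; 1.0 is the random expectation and
    ``fold`` closes to exactly 1 at ``k = N``.  ``rug`` holds the
    competition ranks of the DEGs along the connectivity ordering.
    """

    cutoffs: np.ndarray
    hits: np.ndarray
    fold: np.ndarray
    rug: np.ndarray
    n_deg: int
    universe_size: int
    expected: float = 1.0


def rank_enrichment_curve(
    net: FunctionalNetwork,
    hub: str,
    degs: DEGTable,
    *,
    threshold: str = "padj",
    cutoff: float = 0.05,
    cutoff_grid: str = "all",
    max_dense: int = 5000,
    n_log_cutoffs: int = 200,
) -> EnrichmentCurve:
    """DEG enrichment among genes ranked by connectivity to the hub.

    The universe (as in :func:`deg_connectivity_test`) is ordered by
    hub-edge weight descending, with ties broken by gene identifier so
    the curve is deterministic.  ``cutoff_grid="all"`` evaluates every
    rank when the universe has at most ``max_dense`` genes and falls
    back to ``n_log_cutoffs`` log-spaced cutoffs above that;
    ``"log"`` forces the log-spaced grid.
    """
    hub_i = net.index_of(hub)
    tested = degs.tested(threshold)
    universe = [g for g in net.genes if g in tested and g != hub]
    if not universe:
        raise ValueError("no overlap between network and DEG table")
    sig = degs.significant(threshold, cutoff)
    idx = np.array([net.index_of(g) for g in universe])
    w = net.weights[hub_i, idx]
    is_deg = np.array([g in sig for g in universe])
    if not is_deg.any():
        raise ValueError("no DEGs in the universe")

    N = len(universe)
    m = int(is_deg.sum())
    order = sorted(range(N), key=lambda i: (-w[i], universe[i]))
    w_sorted = w[order]
    deg_sorted = is_deg[order]
    # competition ranks over the sorted weights (ties share the min rank)
    comp_rank = np.empty(N, dtype=int)
    comp_rank[0] = 1
    for i in range(1, N):
        comp_rank[i] = comp_rank[i - 1] if w_sorted[i] == w_sorted[i - 1] else i + 1
    rug = comp_rank[deg_sorted]

    cum_hits = np.cumsum(deg_sorted)
    if cutoff_grid == "all" and N <= max_dense:
        ks = np.arange(1, N + 1)
    else:
        ks = np.unique(
            np.rint(np.logspace(0, np.log10(N), n_log_cutoffs)).astype(int)
        )
        ks = ks[(ks >= 1) & (ks <= N)]
        if ks[-1] != N:
            ks = np.append(ks, N)
    hits = cum_hits[ks - 1]
    fold = (hits / ks) / (m / N)
    return EnrichmentCurve(
        cutoffs=ks,
        hits=hits,
        fold=fold,
        rug=rug,
        n_deg=m,
        universe_size=N,
    )
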