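"""Module-connectivity z-scores and hub ranking.

The central statistic asks, for a gene *g* and a gene module *M*:
is *g* more strongly connected to *M* than expected from *g*'s overall
connectivity profile?  With edge weights being posterior probabilities
of functional interaction,

.. math::

    \\bar{x}_g = \\frac{1}{n}\\sum_{m \\in M} w_{gm}, \\qquad
    z_g = \\frac{\\bar{x}_g - \\mu_g}{\\sigma_g / \\sqrt{n}}

where ``mu_g`` and ``sigma_g`` are the mean and sample standard
deviation of *g*'s weights to every other gene in the network, and
``n`` is the effective module size.  A high z marks *g* as a candidate
hub regulator of the module.  The denominator is the standard error of
a mean of ``n`` draws, which makes z comparable across module sizes;
``sigma/n`` is also available for comparison via ``z_denominator``
(the two differ only by a factor of ``sqrt(n)``).

Self-edges are excluded everywhere, and a module member scored against
its own module excludes itself from the module mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .net_io import FunctionalNetwork, GeneModule

__all__ = [
    "ConnectivityResult",
    "DegenerateDistributionError",
    "module_connectivity_z",
    "rank_module_hubs",
    "pair_connectivity_rank",
]

DEFAULT_MIN_MODULE_SIZE = 3
Z_DENOMINATORS = ("se", "sd_over_n")


class DegenerateDistributionError(ValueError):
    """Raised when sigma == 0 so the z-score is undefined."""


@dataclass(frozen=True)
class ConnectivityResult:
    """Connectivity of one gene to one module.

    Attributes
    ----------
    gene : str
    xbar : float
        Mean posterior probability from the gene to the effective
        module members.
    mu, sigma : float
        Mean and sample standard deviation (divisor ``n-1``) of the
        gene's weights to all other network genes.
    n : int
        Effective module size used in the denominator.
    z : float
        Connectivity z-score; NaN when degenerate.
    degenerate : bool
        True when ``sigma == 0`` (z undefined).
    """

    gene: str
    xbar: float
    mu: float
    sigma: float
    n: int
    z: float
    degenerate: bool = False


def _effective_module_idx(
    net: FunctionalNetwork, module: GeneModule, min_module_size: int
) -> np.ndarray:
    present = sorted(module.members & set(net.genes))
    if len(present) < len(module.members):
        import warnings

        warnings.warn(
            f"{len(module.members) - len(present)} module genes absent "
            f"from the network were dropped",
            stacklevel=3,
        )
    idx = np.array([net.index_of(g) for g in present], dtype=int)
    if len(idx) < min_module_size:
        raise ValueError(
            f"module {module.name!r} has {len(idx)} genes in the network, "
            f"fewer than min_module_size={min_module_size}"
        )
    return idx


def _z_from_parts(xbar: float, mu: float, sigma: float, n: int, denom: str) -> float:
    if denom == "se":
        return (xbar - mu) / (sigma / math.sqrt(n))
    if denom == "sd_over_n":
        return (xbar - mu) / (sigma / n)
    raise ValueError(f"z_denominator must be one of {Z_DENOMINATORS}")


def module_connectivity_z(
    net: FunctionalNetwork,
    module: GeneModule,
    gene: str,
    *,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    z_denominator: str = "se",
) -> ConnectivityResult:
    """Connectivity z-score of one gene to one module.

    Raises
    ------
    KeyError
        Gene absent from the network.
    ValueError
        Effective module (intersected with the network, minus the gene
        itself) smaller than ``min_module_size``.
    DegenerateDistributionError
        The gene's weight distribution has zero variance.
    """
    if z_denominator not in Z_DENOMINATORS:
        raise ValueError(f"z_denominator must be one of {Z_DENOMINATORS}")
    gi = net.index_of(gene)
    midx = _effective_module_idx(net, module, min_module_size)
    midx = midx[midx != gi]
    if len(midx) < min_module_size:
        raise ValueError(
            f"effective module for {gene!r} has {len(midx)} genes, "
            f"fewer than min_module_size={min_module_size}"
        )
    row = net.weights[gi]
    others = np.delete(row, gi)
    mu = float(others.mean())
    sigma = float(others.std(ddof=1))
    xbar = float(row[midx].mean())
    n = len(midx)
    if sigma == 0.0:
        raise DegenerateDistributionError(
            f"all weights of {gene!r} are identical; z undefined"
        )
    z = _z_from_parts(xbar, mu, sigma, n, z_denominator)
    return ConnectivityResult(gene, xbar, mu, sigma, n, z)


def rank_module_hubs(
    net: FunctionalNetwork,
    module: GeneModule,
    *,
    include_module_members: bool = True,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    z_denominator: str = "se",
) -> pd.DataFrame:
    """Score every network gene against the module and rank by z.

    Returns a DataFrame with columns ``gene, xbar, mu, sigma, n, z,
    rank, flag, in_module``, sorted by z descending with ties broken by
    gene identifier; genes with a degenerate (zero-variance) weight
    distribution are flagged and placed last with no rank.  Ranks are
    1-based competition ranks ("1, 2, 2, 4").

    Per-gene failures never abort the ranking: a gene that cannot be
    scored (degenerate sigma, module too small after excluding itself)
    carries a flag instead.
    """
    if z_denominator not in Z_DENOMINATORS:
        raise ValueError(f"z_denominator must be one of {Z_DENOMINATORS}")
    midx = _effective_module_idx(net, module, min_module_size)
    in_module = np.zeros(net.n_genes, dtype=bool)
    in_module[midx] = True

    W = net.weights
    N = net.n_genes
    if N < 2:
        raise ValueError("network must contain at least 2 genes")

    # Two-pass row statistics excluding the diagonal, matching a naive
    # per-gene recomputation to floating-point roundoff.
    diag = np.diag(W)
    mu = (W.sum(axis=1) - diag) / (N - 1)
    dev = W - mu[:, None]
    ss = (dev**2).sum(axis=1) - (diag - mu) ** 2
    with np.errstate(invalid="ignore"):
        sigma = np.sqrt(ss / (N - 2)) if N > 2 else np.full(N, np.nan)

    msum = W[:, midx].sum(axis=1)
    m = len(midx)
    xbar = np.where(in_module, (msum - diag) / max(m - 1, 1), msum / m)
    n_eff = np.where(in_module, m - 1, m)

    rows = []
    for i, g in enumerate(net.genes):
        if in_module[i] and not include_module_members:
            continue
        flag = ""
        z = np.nan
        if n_eff[i] < min_module_size:
            flag = "module_too_small"
        elif not np.isfinite(sigma[i]) or sigma[i] == 0.0:
            flag = "degenerate_sigma"
        else:
            z = _z_from_parts(
                float(xbar[i]), float(mu[i]), float(sigma[i]), int(n_eff[i]), z_denominator
            )
        rows.append(
            {
                "gene": g,
                "xbar": float(xbar[i]),
                "mu": float(mu[i]),
                "sigma": float(sigma[i]),
                "n": int(n_eff[i]),
                "z": z,
                "flag": flag,
                "in_module": bool(in_module[i]),
            }
        )
    df = pd.DataFrame(rows)
    ok = df["flag"] == ""
    # sort: scored genes by z desc then gene asc; flagged genes last
    df = pd.concat(
        [
            df[ok].sort_values(["z", "gene"], ascending=[False, True]),
            df[~ok].sort_values("gene"),
        ]
    ).reset_index(drop=True)
    rank = pd.Series(np.nan, index=df.index)
    scored = df["flag"] == ""
    rank[scored] = df.loc[scored, "z"].rank(method="min", ascending=False)
    df["rank"] = rank
    df.attrs["z_denominator"] = z_denominator
    df.attrs["min_module_size"] = min_module_size
    df.attrs["module"] = module.name
    return df


def pair_connectivity_rank(
    net: FunctionalNetwork, query: str, target: str
) -> tuple[float, int, int]:
    """How close a functional partner of ``target`` is ``query``?

    Returns ``(weight, rank, total)`` where ``weight`` is the edge
    posterior probability between the two genes and ``rank`` is the
    1-based competition rank of ``query`` among all genes ``g != target``
    ordered by ``weight(g, target)`` descending; ``total`` is the number
    of genes ranked (``n_genes - 1``).
    """
    if query == target:
        raise ValueError("query and target must differ")
    qi, ti = net.index_of(query), net.index_of(target)
    col = np.delete(net.weights[:, ti], ti)
    w = net.weights[qi, ti]
    rank = int((col > w).sum()) + 1
    return float(w), rank, len(col)
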