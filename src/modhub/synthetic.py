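"""Planted-module network and perturbation-DEG simulator.

The generator produces the three inputs the analysis consumes, with
known ground truth:

1. a symmetric posterior-probability network in which edge weights are
   Beta-distributed — background pairs from ``Beta(1, 9)`` (mean 0.1),
   pairs internal to a planted module from ``Beta(4, 6)`` (mean 0.4),
   and edges between a planted hub and the module from ``Beta(6, 4)``
   (mean 0.6).  Beta edges respect the ``[0, 1]`` posterior semantics.
   The hub sits outside the module by default: it emulates a regulator
   of the module rather than a member;
2. a DESeq2-shaped DEG table for a perturbation of the hub, in which
   each gene's probability of being differentially expressed follows a
   logistic model in its connectivity to the hub,
   ``P(DE) = logistic(b0 + b1 * w(hub, g))``.  DE genes receive
   p-values ``10**(-U(lo, hi))`` and fold changes ``+-N(mean, sd)``;
   null genes receive uniform p-values and small noise fold changes.
   P-values are drawn directly rather than simulated from counts: the
   pipeline consumes differential-expression *output*, and the label
   model is what the validation statistics respond to;
3. optionally a second, attenuated table sharing the same truth labels
   and signs but independent noise — emulating a paired in vitro /
   in vivo design where the second assay is weaker.

A single integer seed governs everything through one stream-splitting
rule: ``SeedSequence(seed).spawn(3)`` yields the *network* stream
(module/hub placement and edge weights), the *label* stream (DE
labels and signs) and the *noise* stream (p-values and fold-change
magnitudes).  Identical seeds give bit-identical outputs; the three
components are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .net_io import DEGTable, FunctionalNetwork, GeneModule
from .validation import bh_adjust

__all__ = [
    "GeneratorParams",
    "SyntheticTruth",
    "generate_network",
    "generate_perturbation_degs",
    "generate_paired_degs",
    "simulate",
]


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the planted-module simulator.

    Attributes
    ----------
    n_genes, module_size : int
        Network size and planted module size.
    background_beta, module_beta, hub_beta : (float, float)
        Beta shape pairs for background, module-internal and
        hub-to-module edge weights.
    de_intercept, de_slope : float
        Logit-scale intercept (b0) and slope per unit edge weight (b1)
        of the DE-probability model.  ``de_slope = 0`` gives the null
        in which DE labels are independent of connectivity.
    lfc_de : (float, float)
        Mean and SD of |log2 fold change| for DE genes (log2 units).
    lfc_null_sd : float
        SD of the null genes' log2 fold-change noise.
    p_de_exponent_range : (float, float)
        DE p-values are drawn as ``10**(-U(lo, hi))``.
    hub_in_module : bool
        Place the hub inside the module (default False).
    module_down_bias : float
        Probability that a DE *module* gene is downregulated
        (0.5 = unbiased).
    perturbation : str
        ``"silencing"`` (hub log2fc strongly negative) or
        ``"overexpression"`` (strongly positive).
    seed : int
    """

    n_genes: int = 2000
    module_size: int = 100
    background_beta: tuple[float, float] = (1.0, 9.0)
    module_beta: tuple[float, float] = (4.0, 6.0)
    hub_beta: tuple[float, float] = (6.0, 4.0)
    de_intercept: float = -3.0
    de_slope: float = 6.0
    lfc_de: tuple[float, float] = (2.0, 0.5)
    lfc_null_sd: float = 0.25
    p_de_exponent_range: tuple[float, float] = (2.0, 10.0)
    hub_in_module: bool = False
    module_down_bias: float = 0.5
    perturbation: str = "silencing"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_genes > self.module_size >= 3:
            raise ValueError("need n_genes > module_size >= 3")
        for name in ("background_beta", "module_beta", "hub_beta"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ValueError(f"{name} shapes must be positive")
        a1, b1 = self.module_beta
        a0, b0 = self.background_beta
        if a1 / (a1 + b1) <= a0 / (a0 + b0):
            raise ValueError("module Beta mean must exceed background Beta mean")
        lo, hi = self.p_de_exponent_range
        if not lo < hi:
            raise ValueError("p_de_exponent_range must satisfy lo < hi")
        if not 0.0 <= self.module_down_bias <= 1.0:
            raise ValueError("module_down_bias must lie in [0, 1]")
        if self.perturbation not in ("silencing", "overexpression"):
            raise ValueError("perturbation must be 'silencing' or 'overexpression'")

    def streams(self) -> tuple[np.random.Generator, ...]:
        """(network, label, noise) generators derived from the seed."""
        return tuple(
            np.random.default_rng(s) for s in np.random.SeedSequence(self.seed).spawn(3)
        )


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated dataset."""

    module: GeneModule
    hub: str
    params: GeneratorParams
    de_labels: dict[str, bool] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "module": sorted(self.module.members),
            "module_name": self.module.name,
            "hub": self.hub,
            "params": asdict(self.params),
            "de_labels": dict(sorted(self.de_labels.items())),
        }


def _gene_names(n: int) -> tuple[str, ...]:
    width = max(4, len(str(n - 1)))
    return tuple(f"G{i:0{width}d}" for i in range(n))


def generate_network(
    params: GeneratorParams,
) -> tuple[FunctionalNetwork, SyntheticTruth]:
    """Draw a planted-module network.

    Every unordered gene pair gets a background Beta weight; pairs
    internal to the planted module are overwritten from the module
    Beta, and hub-module pairs from the hub Beta.  The matrix is
    symmetric by construction and fully reproducible from the seed.
    The returned truth carries module membership and hub identity;
    DE labels are filled in by :func:`generate_perturbation_degs`.
    """
    rng, _, _ = params.streams()
    n = params.n_genes
    genes = _gene_names(n)

    perm = rng.permutation(n)
    module_idx = np.sort(perm[: params.module_size])
    if params.hub_in_module:
        hub_idx = int(rng.choice(module_idx))
    else:
        non_module = np.setdiff1d(np.arange(n), module_idx)
        hub_idx = int(rng.choice(non_module))

    iu = np.triu_indices(n, k=1)
    w = rng.beta(*params.background_beta, size=iu[0].size)
    W = np.zeros((n, n))
    W[iu] = w
    W += W.T

    in_mod = np.zeros(n, dtype=bool)
    in_mod[module_idx] = True
    mod_pair = in_mod[iu[0]] & in_mod[iu[1]]
    mod_vals = rng.beta(*params.module_beta, size=int(mod_pair.sum()))
    mi, mj = iu[0][mod_pair], iu[1][mod_pair]
    W[mi, mj] = W[mj, mi] = mod_vals

    hub_pair = ((iu[0] == hub_idx) & in_mod[iu[1]]) | (
        (iu[1] == hub_idx) & in_mod[iu[0]]
    )
    hub_vals = rng.beta(*params.hub_beta, size=int(hub_pair.sum()))
    hi, hj = iu[0][hub_pair], iu[1][hub_pair]
    W[hi, hj] = W[hj, hi] = hub_vals

    np.fill_diagonal(W, 1.0)
    net = FunctionalNetwork(genes, W)
    module = GeneModule("PLANTED", frozenset(genes[i] for i in module_idx))
    truth = SyntheticTruth(module=module, hub=genes[hub_idx], params=params)
    return net, truth


def _draw_degs(
    net: FunctionalNetwork,
    truth: SyntheticTruth,
    params: GeneratorParams,
    labels: np.ndarray,
    signs: np.ndarray,
    noise_rng: np.random.Generator,
) -> DEGTable:
    """Realize a DEG table from fixed labels/signs and a noise stream."""
    import pandas as pd

    hub_i = net.index_of(truth.hub)
    n = net.n_genes
    lo, hi = params.p_de_exponent_range
    pvals = noise_rng.uniform(0.0, 1.0, size=n)
    lfc = noise_rng.normal(0.0, params.lfc_null_sd, size=n)
    de = labels
    pvals[de] = 10.0 ** (-noise_rng.uniform(lo, hi, size=int(de.sum())))
    mags = noise_rng.normal(*params.lfc_de, size=int(de.sum()))
    lfc[de] = signs[de] * np.abs(mags)

    hub_mag = params.lfc_de[0] + 3.0 * params.lfc_de[1]
    lfc[hub_i] = -hub_mag if params.perturbation == "silencing" else hub_mag
    pvals[hub_i] = 10.0**-hi

    frame = pd.DataFrame(
        {
            "gene": net.genes,
            "log2fc": lfc,
            "pvalue": pvals,
            "padj": bh_adjust(pvals),
        }
    )
    return DEGTable(frame)


def _draw_labels(
    net: FunctionalNetwork,
    truth: SyntheticTruth,
    params: GeneratorParams,
    label_rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    hub_i = net.index_of(truth.hub)
    w_hub = net.weights[hub_i].copy()
    logit = params.de_intercept + params.de_slope * w_hub
    p_de = 1.0 / (1.0 + np.exp(-logit))
    labels = label_rng.uniform(size=net.n_genes) < p_de
    labels[hub_i] = False  # the perturbed gene is handled separately

    in_mod = np.array([g in truth.module.members for g in net.genes])
    signs = np.where(label_rng.uniform(size=net.n_genes) < 0.5, 1.0, -1.0)
    mod_signs = np.where(
        label_rng.uniform(size=net.n_genes) < params.module_down_bias, -1.0, 1.0
    )
    signs = np.where(in_mod, mod_signs, signs)
    return labels, signs


def generate_perturbation_degs(
    net: FunctionalNetwork,
    truth: SyntheticTruth,
    params: GeneratorParams | None = None,
) -> tuple[DEGTable, SyntheticTruth]:
    """Simulate the DEG table of a hub-perturbation experiment.

    For each gene ``g != hub``, ``P(DE) = logistic(b0 + b1 * w(hub, g))``.
    The hub itself gets an extreme p-value and a strong fold change in
    the direction of the perturbation.  Adjusted p-values come from
    :func:`modhub.validation.bh_adjust` over all genes.  The returned
    truth includes the realized DE labels (for every gene except the
    hub).
    """
    params = params or truth.params
    _, label_rng, noise_rng = params.streams()
    labels, signs = _draw_labels(net, truth, params, label_rng)
    table = _draw_degs(net, truth, params, labels, signs, noise_rng)
    truth.de_labels = {
        g: bool(labels[i]) for i, g in enumerate(net.genes) if g != truth.hub
    }
    return table, truth


def generate_paired_degs(
    net: FunctionalNetwork,
    truth: SyntheticTruth,
    params: GeneratorParams | None = None,
    *,
    seed2: int = 1,
    attenuation: float = 0.5,
) -> tuple[DEGTable, DEGTable]:
    """Two DEG tables sharing truth labels, with independent noise.

    The second table emulates a weaker replicate assay: a fraction
    ``attenuation`` of the DE genes (chosen from the ``seed2`` stream)
    is reverted to null before its noise is drawn.
    """
    if not 0.0 <= attenuation <= 1.0:
        raise ValueError("attenuation must lie in [0, 1]")
    params = params or truth.params
    _, label_rng, noise_rng = params.streams()
    labels, signs = _draw_labels(net, truth, params, label_rng)
    table_a = _draw_degs(net, truth, params, labels, signs, noise_rng)
    truth.de_labels = {
        g: bool(labels[i]) for i, g in enumerate(net.genes) if g != truth.hub
    }

    rng2 = np.random.default_rng(np.random.SeedSequence(seed2))
    labels_b = labels.copy()
    de_idx = np.flatnonzero(labels)
    n_revert = int(round(attenuation * len(de_idx)))
    if n_revert:
        revert = rng2.choice(de_idx, size=n_revert, replace=False)
        labels_b[revert] = False
    table_b = _draw_degs(net, truth, params, labels_b, signs, rng2)
    return table_a, table_b


def simulate(
    params: GeneratorParams,
) -> tuple[FunctionalNetwork, DEGTable, SyntheticTruth]:
    """Convenience: network + single perturbation DEG table + truth."""
    net, truth = generate_network(params)
    degs, truth = generate_perturbation_degs(net, truth, params)
    return net, degs, truth
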