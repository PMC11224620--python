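"""Readers, writers and the canonical in-memory data model.

Three kinds of inputs are handled:

* **Functional networks** — symmetric gene-by-gene matrices of posterior
  probabilities in ``[0, 1]`` that two genes act in the same cellular
  process in a given cell type.  Two on-disk dialects are supported: a
  headerless three-column undirected edge list, and a dense matrix TSV
  with gene identifiers as header row and index column.
* **Gene modules** — named gene sets in standard GMT format.
* **DEG tables** — per-gene differential-expression records with the
  shape of a DESeq2 results table (``gene``, ``log2fc``, ``pvalue``,
  optional ``padj``).

Gene identifiers are opaque, case-sensitive strings; no symbol or
ortholog mapping is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FunctionalNetwork",
    "GeneModule",
    "DEGTable",
    "NetworkFormatError",
    "read_network",
    "write_network",
    "read_gmt",
    "write_gmt",
    "read_deg_table",
    "write_deg_table",
]

#: Stored self-weight.  Self-edges are *never* used by any statistic;
#: every downstream operation excludes the diagonal.
DIAGONAL_WEIGHT = 1.0

#: Decimal places used when serialising edge-list weights.
EDGE_LIST_PRECISION = 6


class NetworkFormatError(ValueError):
    """Malformed network, gene-set or DEG input."""


@dataclass(frozen=True)
class FunctionalNetwork:
    """Symmetric gene-gene network of edge posterior probabilities.

    Parameters
    ----------
    genes
        Ordered, unique, non-empty gene identifiers.
    weights
        ``(n, n)`` symmetric float array with values in ``[0, 1]``.
        The diagonal holds :data:`DIAGONAL_WEIGHT` by convention and is
        excluded from every statistic computed on the network.
    """

    genes: tuple[str, ...]
    weights: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        genes = tuple(str(g) for g in self.genes)
        if len(genes) == 0:
            raise NetworkFormatError("network has no genes")
        if any(g == "" for g in genes):
            raise NetworkFormatError("empty gene identifier")
        if len(set(genes)) != len(genes):
            raise NetworkFormatError("duplicate gene identifiers")
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(genes), len(genes)):
            raise NetworkFormatError(
                f"weight matrix shape {w.shape} does not match {len(genes)} genes"
            )
        if not np.array_equal(w, w.T):
            raise NetworkFormatError("weight matrix is not symmetric")
        off = ~np.eye(len(genes), dtype=bool)
        if w[off].size and (np.nanmin(w[off]) < 0.0 or np.nanmax(w[off]) > 1.0):
            raise NetworkFormatError("edge weights outside [0, 1]")
        if np.isnan(w).any():
            raise NetworkFormatError("NaN edge weight")
        np.fill_diagonal(w, DIAGONAL_WEIGHT)
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "_index", {g: i for i, g in enumerate(genes)})

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def index_of(self, gene: str) -> int:
        try:
            return self._index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in network") from None

    def __contains__(self, gene: object) -> bool:
        return gene in self._index

    def weight(self, a: str, b: str) -> float:
        """Edge posterior probability between two distinct genes."""
        i, j = self.index_of(a), self.index_of(b)
        if i == j:
            raise ValueError("self-weight is undefined; self-edges are never used")
        return float(self.weights[i, j])


@dataclass(frozen=True)
class GeneModule:
    """A named gene set, e.g. a disease-vulnerability module."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        members = frozenset(str(m) for m in self.members)
        if not self.name:
            raise NetworkFormatError("module name must be non-empty")
        if not members:
            raise NetworkFormatError(f"module {self.name!r} is empty")
        object.__setattr__(self, "members", members)

    def __len__(self) -> int:
        return len(self.members)


class DEGTable:
    """Per-gene differential-expression records (DESeq2 results shape).

    Wraps a DataFrame indexed by gene with columns ``log2fc``,
    ``pvalue`` and ``padj``.  Extra columns present in the source file
    are preserved but ignored by all statistics.
    """

    REQUIRED = ("log2fc", "pvalue")

    def __init__(self, frame: pd.DataFrame):
        df = frame.copy()
        if df.index.name != "gene":
            if "gene" not in df.columns:
                raise NetworkFormatError("DEG table requires a 'gene' column")
            df = df.set_index("gene")
        df.index = df.index.astype(str)
        if df.index.duplicated().any():
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise NetworkFormatError(f"duplicate gene rows in DEG table: {dups[:5]}")
        for col in self.REQUIRED:
            if col not in df.columns:
                raise NetworkFormatError(f"DEG table missing required column {col!r}")
            df[col] = pd.to_numeric(df[col], errors="raise")
        for col in ("pvalue", "padj"):
            if col in df.columns:
                vals = df[col].dropna()
                if ((vals < 0) | (vals > 1)).any():
                    raise NetworkFormatError(f"{col} outside [0, 1]")
        if "padj" not in df.columns:
            from .validation import bh_adjust  # deferred: avoids import cycle

            padj = np.full(len(df), np.nan)
            ok = df["pvalue"].notna().to_numpy()
            padj[ok] = bh_adjust(df["pvalue"].to_numpy()[ok])
            df["padj"] = padj
        else:
            df["padj"] = pd.to_numeric(df["padj"], errors="raise")
        self.frame = df

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.frame.index)

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, gene: object) -> bool:
        return gene in self.frame.index

    def significant(
        self, threshold: str = "padj", cutoff: float = 0.05
    ) -> frozenset[str]:
        """Genes called differentially expressed at ``threshold < cutoff``.

        Genes with a missing value in the threshold column are excluded
        (they are untested, not non-significant).
        """
        if threshold not in ("padj", "pvalue"):
            raise ValueError("threshold must be 'padj' or 'pvalue'")
        col = self.frame[threshold]
        return frozenset(self.frame.index[col.notna() & (col < cutoff)])

    def tested(self, threshold: str = "padj") -> frozenset[str]:
        """Genes with a non-missing value in the threshold column."""
        if threshold not in ("padj", "pvalue"):
            raise ValueError("threshold must be 'padj' or 'pvalue'")
        return frozenset(self.frame.index[self.frame[threshold].notna()])


# ---------------------------------------------------------------------------
# networks


def _read_edge_list(path) -> FunctionalNetwork:
    seen: dict[tuple[str, str], float] = {}
    genes: dict[str, None] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise NetworkFormatError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}"
                )
            a, b, ws = parts
            if not a or not b:
                raise NetworkFormatError(f"{path}:{lineno}: empty gene identifier")
            if a == b:
                raise NetworkFormatError(f"{path}:{lineno}: self-edge {a!r}")
            try:
                w = float(ws)
            except ValueError:
                raise NetworkFormatError(
                    f"{path}:{lineno}: non-numeric weight {ws!r}"
                ) from None
            if not 0.0 <= w <= 1.0:
                raise NetworkFormatError(f"{path}:{lineno}: weight {w} outside [0, 1]")
            key = (a, b) if a < b else (b, a)
            if key in seen and seen[key] != w:
                raise NetworkFormatError(
                    f"{path}:{lineno}: asymmetric edge {a}-{b}: "
                    f"{seen[key]} vs {w}"
                )
            seen[key] = w
            genes.setdefault(a)
            genes.setdefault(b)
    order = list(genes)
    idx = {g: i for i, g in enumerate(order)}
    w = np.zeros((len(order), len(order)))
    for (a, b), val in seen.items():
        w[idx[a], idx[b]] = w[idx[b], idx[a]] = val
    return FunctionalNetwork(tuple(order), w)


def _read_dense(path) -> FunctionalNetwork:
    # round_trip: dense matrices must reproduce weights bit-exactly
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    header = [str(c) for c in df.columns]
    if len(set(header)) != len(header):
        raise NetworkFormatError(f"{path}: duplicate gene in dense header")
    index = [str(i) for i in df.index]
    if header != index:
        raise NetworkFormatError(f"{path}: header and index gene order differ")
    return FunctionalNetwork(tuple(header), df.to_numpy(dtype=float))


def read_network(path, format: str = "edge_list") -> FunctionalNetwork:
    """Read a functional network from disk.

    Parameters
    ----------
    path
        Input file.
    format
        ``"edge_list"`` — headerless TSV rows ``(gene_a, gene_b, weight)``;
        pairs not listed default to weight 0.  ``"dense_matrix"`` — TSV
        with gene identifiers as header row and first column.
    """
    if format == "edge_list":
        return _read_edge_list(path)
    if format == "dense_matrix":
        return _read_dense(path)
    raise ValueError(f"unknown network format {format!r}")


def write_network(net: FunctionalNetwork, path, format: str = "edge_list") -> None:
    """Write a network; inverse of :func:`read_network`.

    Edge-list output stores weights at 6 decimal places and omits
    zero-weight pairs; the dense matrix is written at full precision.
    """
    if format == "edge_list":
        with open(path, "w") as fh:
            for i in range(net.n_genes):
                for j in range(i + 1, net.n_genes):
                    w = net.weights[i, j]
                    if w != 0.0:
                        fh.write(
                            f"{net.genes[i]}\t{net.genes[j]}\t"
                            f"{w:.{EDGE_LIST_PRECISION}f}\n"
                        )
    elif format == "dense_matrix":
        df = pd.DataFrame(net.weights, index=net.genes, columns=net.genes)
        df.to_csv(path, sep="\t", float_format="%.17g")
    else:
        raise ValueError(f"unknown network format {format!r}")


# ---------------------------------------------------------------------------
# gene sets


def read_gmt(path) -> list[GeneModule]:
    """Read gene modules from a GMT file.

    Standard dialect: one set per line, tab-separated; column 1 is the
    set name, column 2 a description (ignored), columns 3+ the members.
    Duplicate members within a line are collapsed with a warning.
    """
    modules: list[GeneModule] = []
    names: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise NetworkFormatError(
                    f"{path}:{lineno}: GMT line has fewer than 3 columns"
                )
            name, _desc, *members = parts
            if name in names:
                raise NetworkFormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            names.add(name)
            members = [m for m in members if m]
            if len(set(members)) != len(members):
                warnings.warn(
                    f"{path}:{lineno}: duplicate genes in set {name!r} collapsed",
                    stacklevel=2,
                )
            modules.append(GeneModule(name, frozenset(members)))
    return modules


def write_gmt(modules: list[GeneModule], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for mod in modules:
            fh.write("\t".join([mod.name, description, *sorted(mod.members)]) + "\n")


# ---------------------------------------------------------------------------
# DEG tables


def read_deg_table(path) -> DEGTable:
    """Read a DESeq2-shaped DEG table.

    TSV with a header containing at least ``gene``, ``log2fc`` and
    ``pvalue``; ``padj`` is taken verbatim when present and otherwise
    computed by Benjamini-Hochberg over the non-missing p-values.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    df.columns = [str(c) for c in df.columns]
    if "gene" not in df.columns:
        raise NetworkFormatError(f"{path}: missing 'gene' column")
    return DEGTable(df)


def write_deg_table(table: DEGTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=True, index_label="gene")
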