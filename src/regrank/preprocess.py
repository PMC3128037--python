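"""Expression-matrix containers, gene filtering and tertile discretization.

Genes enter the scored network only if they (1) vary strongly across samples
(top-N by standard deviation), (2) appear in the regulatory network and
(3) have at most ``max_parents`` regulators — in a multinomial model the
parameter count grows exponentially with the number of parents, so a highly
connected gene cannot score well on a small dataset anyway.

Expression values are discretized per gene into three evenly populated
states (low / medium / high) by rank, so any strictly increasing transform
of a gene's values leaves its discretization unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .network import RegulatoryNetwork

__all__ = [
    "ExpressionMatrix",
    "DiscretizedMatrix",
    "read_expression",
    "select_top_variable_genes",
    "filter_by_network",
    "induce_subnetwork",
    "discretize_tertiles",
    "configuration_space_log10",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Continuous gene x sample expression values (unitless, pre-normalized).

    Missing values are rejected at construction; imputation and probe-level
    normalization belong upstream.
    """

    genes: tuple[str, ...]
    samples: tuple[str, ...]
    values: np.ndarray  # float, shape (n_genes, n_samples)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values shape {values.shape} != ({len(self.genes)}, {len(self.samples)})"
            )
        if np.isnan(values).any():
            raise ValueError("expression matrix contains missing values")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene symbols")
        object.__setattr__(self, "values", values)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(tuple(df.index), tuple(df.columns), df.to_numpy(dtype=float))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.genes), columns=list(self.samples))

    def subset(self, genes: list[str]) -> "ExpressionMatrix":
        """Restrict to the given genes, in the given order."""
        pos = {g: i for i, g in enumerate(self.genes)}
        idx = [pos[g] for g in genes]
        return ExpressionMatrix(tuple(genes), self.samples, self.values[idx])

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="gene")


@dataclass(frozen=True)
class DiscretizedMatrix:
    """Gene x sample states in {0=low, 1=medium, 2=high}."""

    genes: tuple[str, ...]
    samples: tuple[str, ...]
    states: np.ndarray  # int8, shape (n_genes, n_samples)
    n_states: int = 3

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=np.int8)
        if states.shape != (len(self.genes), len(self.samples)):
            raise ValueError("states shape does not match gene/sample labels")
        if states.size and (states.min() < 0 or states.max() >= self.n_states):
            raise ValueError(f"states must lie in [0, {self.n_states})")
        object.__setattr__(self, "states", states)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def row(self, gene: str) -> np.ndarray:
        return self.states[self.genes.index(gene)]

    def subset(self, genes: list[str]) -> "DiscretizedMatrix":
        pos = {g: i for i, g in enumerate(self.genes)}
        idx = [pos[g] for g in genes]
        return DiscretizedMatrix(tuple(genes), self.samples, self.states[idx], self.n_states)

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.states, index=list(self.genes), columns=list(self.samples)).to_csv(
            path, sep="\t", index_label="gene"
        )


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a TSV with gene symbols in the first column and one column per
    sample (header row of sample IDs).  Missing entries are an error."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()[:5]
        raise ValueError(f"missing expression values, e.g. for genes {bad}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix.from_dataframe(df)


def select_top_variable_genes(expr: ExpressionMatrix, n: int) -> list[str]:
    """The ``n`` genes with the largest sample standard deviation (ddof=1)
    across samples; ties break by ascending gene symbol.  If ``n`` exceeds
    the gene count, all genes are returned (ranked)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if expr.n_samples < 2:
        raise ValueError("standard deviation needs at least 2 samples")
    sd = expr.values.std(axis=1, ddof=1)
    order = sorted(range(len(expr.genes)), key=lambda i: (-sd[i], expr.genes[i]))
    return [expr.genes[i] for i in order[:n]]


def filter_by_network(
    genes: list[str], net: RegulatoryNetwork, max_parents: int = 10
) -> list[str]:
    """Keep genes present in the network with at most ``max_parents``
    regulator parents; input order is preserved."""
    in_net = set(net.genes)
    return [
        g for g in genes if g in in_net and len(net.parents_of(g)) <= max_parents
    ]


def induce_subnetwork(
    net: RegulatoryNetwork, kept_genes: list[str]
) -> RegulatoryNetwork:
    """Restrict the network to ``kept_genes``; regulators left without edges
    are dropped, as are kept genes without any remaining parent."""
    missing = [g for g in kept_genes if g not in set(net.genes)]
    if missing:
        raise ValueError(f"genes not in network: {missing[:5]}")
    kept = set(kept_genes)
    edges = {(r, g) for r, g in net.edges if g in kept}
    with_edge_r = {r for r, _ in edges}
    with_edge_g = {g for _, g in edges}
    return RegulatoryNetwork(
        tuple(r for r in net.regulators if r in with_edge_r),
        tuple(g for g in kept_genes if g in with_edge_g),
        frozenset(edges),
    )


def configuration_space_log10(n_obs: int, n_regulators: int, n_bins: int = 3) -> float:
    """log10 of the hidden-state configuration space, n_bins^(n_obs * n_regs).

    The Gibbs sampler explores this space, and it grows exponentially in the
    bin count — e.g. 100 observations and 2 hidden regulators give ~10^95
    configurations with 3 bins — which is the computational argument for
    keeping the discretization as coarse as the data allows.
    """
    if n_obs < 1 or n_regulators < 1 or n_bins < 2:
        raise ValueError("need n_obs >= 1, n_regulators >= 1, n_bins >= 2")
    return n_obs * n_regulators * math.log10(n_bins)


def discretize_tertiles(expr: ExpressionMatrix, n_bins: int = 3) -> DiscretizedMatrix:
    """Per-gene rank-based binning into ``n_bins`` evenly populated states.

    Samples are ranked ascending by value (ties broken stably by sample
    order) and the sample at 0-based rank ``r`` out of ``n`` gets state
    ``floor(n_bins * r / n)``, so bin occupancies differ by at most one.
    """
    n = expr.n_samples
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} samples, got {n}")
    states = np.empty(expr.values.shape, dtype=np.int8)
    rank_states = (n_bins * np.arange(n)) // n  # state per ascending rank
    for i in range(len(expr.genes)):
        order = np.argsort(expr.values[i], kind="stable")
        states[i, order] = rank_states
    return DiscretizedMatrix(expr.genes, expr.samples, states, n_bins)
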