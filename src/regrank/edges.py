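"""Edge-removal scoring, normalization, selection and empirical null tests.

The importance of a regulator->gene edge is the change in the average
network score, over retained Gibbs samples, when the edge is removed versus
present (positive = the edge helps explain the data).  Because the BDe score
decomposes over families, only the target gene's local term changes, so each
edge delta is computed as a local-score difference — contractually equal to
rescoring the whole network with the edge removed and re-added.

Two empirical significance procedures accompany the ranking:

* a random-activity null: hidden activities drawn iid uniform (no Gibbs),
  edges rescored and re-ranked identically, repeated ``n_reps`` times; an
  edge's p-value at K is the add-one fraction of replicates where it lands
  in the null top K;
* a paired disconnection test against the intact network: a one-sided
  sign-flip permutation test on the per-Gibbs-sample deltas of each edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .bde import PriorSpec, score_counts
from .gibbs import HiddenStateMatrix
from .network import RegulatoryNetwork
from .preprocess import DiscretizedMatrix

__all__ = [
    "EdgeScore",
    "NullTestConfig",
    "edge_importance",
    "normalize_scores",
    "select_top_edges",
    "null_edge_test",
    "disconnection_significance",
    "write_edge_table",
]


@dataclass(frozen=True)
class EdgeScore:
    """Score record for one regulator->gene edge.

    ``raw_delta`` is in nats: mean score with the edge present minus mean
    score with it removed, averaged over retained samples.  ``norm_score``
    is the min-max normalization of ``raw_delta`` over the edge set;
    ``rank`` 1 is the strongest edge.
    """

    edge: tuple[str, str]
    raw_delta: float
    norm_score: float | None = None
    rank: int | None = None
    p_value: float | None = None


@dataclass(frozen=True)
class NullTestConfig:
    n_reps: int = 5000
    top_k: tuple[int, ...] = (10, 50, 100, 250)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1 or any(k < 1 for k in self.top_k):
            raise ValueError("n_reps and every top_k must be >= 1")


def _gene_score_cache(
    net: RegulatoryNetwork,
    genes: DiscretizedMatrix,
    sample: HiddenStateMatrix,
    prior: PriorSpec,
) -> dict[tuple[str, tuple[str, ...]], float]:
    """Local BDe score of every gene under its full parent set and under
    each leave-one-parent-out set, for one hidden-state sample."""
    arity = genes.n_states
    reg_row = {r: np.asarray(sample.row(r), dtype=np.int64) for r in net.regulators}
    out: dict[tuple[str, tuple[str, ...]], float] = {}
    for g in net.genes:
        parents = net.parents_of(g)
        x = np.asarray(genes.row(g), dtype=np.int64)
        subsets = [parents] + [
            tuple(p for p in parents if p != drop) for drop in parents
        ]
        for ps in subsets:
            key = (g, ps)
            if key in out:
                continue
            q = arity ** len(ps)
            cfg = np.zeros(len(x), dtype=np.int64)
            for p in ps:
                cfg = cfg * arity + reg_row[p]
            counts = np.bincount(cfg * arity + x, minlength=q * arity).reshape(q, arity)
            out[key] = score_counts(counts, prior.cell_alpha(q, arity))
    return out


def edge_importance(
    net: RegulatoryNetwork,
    genes: DiscretizedMatrix,
    samples: list[HiddenStateMatrix],
    prior: PriorSpec,
) -> list[EdgeScore]:
    """Raw present-minus-removed score delta for every edge, averaged over
    the retained hidden-state samples; edges are returned in (regulator
    declaration, gene declaration) order."""
    if not samples:
        raise ValueError("need at least one retained hidden-state sample")
    edges = net.sorted_edges()
    deltas = np.zeros(len(edges))
    for sample in samples:
        cache = _gene_score_cache(net, genes, sample, prior)
        for i, (r, g) in enumerate(edges):
            full = cache[(g, net.parents_of(g))]
            reduced = cache[(g, tuple(p for p in net.parents_of(g) if p != r))]
            deltas[i] += full - reduced
    deltas /= len(samples)
    return [EdgeScore(e, float(d)) for e, d in zip(edges, deltas)]


def per_sample_deltas(
    net: RegulatoryNetwork,
    genes: DiscretizedMatrix,
    samples: list[HiddenStateMatrix],
    prior: PriorSpec,
) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Edge x sample matrix of present-minus-removed score deltas."""
    edges = net.sorted_edges()
    out = np.zeros((len(edges), len(samples)))
    for s, sample in enumerate(samples):
        cache = _gene_score_cache(net, genes, sample, prior)
        for i, (r, g) in enumerate(edges):
            full = cache[(g, net.parents_of(g))]
            reduced = cache[(g, tuple(p for p in net.parents_of(g) if p != r))]
            out[i, s] = full - reduced
    return edges, out


def normalize_scores(edge_scores: list[EdgeScore]) -> list[EdgeScore]:
    """Min-max normalize raw deltas to [0, 1] (strongest edge 1.0, weakest
    0.0) and assign ranks 1..E by descending delta (ties break by edge name).
    Degenerate cases: all-equal deltas (or a single edge) normalize to 1.0."""
    if not edge_scores:
        return []
    deltas = np.array([e.raw_delta for e in edge_scores])
    lo, hi = deltas.min(), deltas.max()
    if len(edge_scores) < 2 or hi == lo:
        norms = np.ones(len(edge_scores))
    else:
        norms = (deltas - lo) / (hi - lo)
    order = sorted(
        range(len(edge_scores)),
        key=lambda i: (-edge_scores[i].raw_delta, edge_scores[i].edge),
    )
    ranks = {i: pos + 1 for pos, i in enumerate(order)}
    return [
        replace(e, norm_score=float(norms[i]), rank=ranks[i])
        for i, e in enumerate(edge_scores)
    ]


def select_top_edges(
    edge_scores: list[EdgeScore], method: str, param: float | int | None = None
) -> list[EdgeScore]:
    """Select the strong-edge set.

    ``fixed_k``: the k best by normalized score (ties by raw delta, then
    lexicographic edge).  ``score_threshold``: all edges with norm_score >
    param.  ``largest_gap``: sort descending and cut at the largest
    consecutive score gap within the top half of the list.
    """
    ordered = sorted(
        edge_scores, key=lambda e: (-e.norm_score, -e.raw_delta, e.edge)
    )
    if method == "fixed_k":
        k = int(param)
        if k > len(ordered):
            warnings.warn(
                f"requested top {k} of {len(ordered)} edges; returning all",
                stacklevel=2,
            )
            k = len(ordered)
        return ordered[:k]
    if method == "score_threshold":
        return [e for e in ordered if e.norm_score > float(param)]
    if method == "largest_gap":
        if len(ordered) < 2:
            return list(ordered)
        half = (len(ordered) + 1) // 2
        gaps = [
            ordered[i].norm_score - ordered[i + 1].norm_score for i in range(half)
        ]
        cut = int(np.argmax(gaps)) + 1  # first index of max gap wins ties
        return ordered[:cut]
    raise ValueError(f"unknown selection method {method!r}")


def null_edge_test(
    net: RegulatoryNetwork,
    genes: DiscretizedMatrix,
    observed_scores: list[EdgeScore],
    config: NullTestConfig,
    prior: PriorSpec,
) -> pd.DataFrame:
    """Random-activity null for top-K membership.

    Each replicate assigns iid uniform random states to every regulator
    activity (no Gibbs), rescores and re-ranks all edges exactly as the real
    pipeline does, and records which edges fall in the null top K.  Returns
    a DataFrame indexed by (regulator, gene) with one add-one p-value column
    per K — p(e, K) = (1 + #{replicates with e in top K}) / (n_reps + 1) —
    and a ``significant_top{K}`` flag: edge in the *observed* top K and
    p < 0.05.  The observed ranking is fixed; only the null is randomized.
    """
    rng = np.random.default_rng(config.seed)
    edges = net.sorted_edges()
    n_obs = genes.n_samples
    ks = [min(k, len(edges)) for k in config.top_k]
    hits = np.zeros((len(edges), len(ks)), dtype=np.int64)
    idx = np.arange(len(edges))
    for _ in range(config.n_reps):
        h = HiddenStateMatrix(
            net.regulators,
            genes.samples,
            rng.integers(0, 3, size=(len(net.regulators), n_obs), dtype=np.int8),
        )
        scores = edge_importance(net, genes, [h], prior)
        order = sorted(idx, key=lambda i: (-scores[i].raw_delta, scores[i].edge))
        for kj, k in enumerate(ks):
            hits[np.array(order[:k]), kj] += 1
    p = (1.0 + hits) / (config.n_reps + 1.0)
    obs_rank = {e.edge: e.rank for e in observed_scores}
    data = {}
    for kj, (k_label, k) in enumerate(zip(config.top_k, ks)):
        data[f"p_top{k_label}"] = p[:, kj]
        data[f"significant_top{k_label}"] = [
            obs_rank.get(e) is not None
            and obs_rank[e] <= k
            and p[i, kj] < 0.05
            for i, e in enumerate(edges)
        ]
    return pd.DataFrame(data, index=pd.MultiIndex.from_tuples(edges, names=["regulator", "gene"]))


def disconnection_significance(
    net: RegulatoryNetwork,
    genes: DiscretizedMatrix,
    samples: list[HiddenStateMatrix],
    prior: PriorSpec,
    n_perm: int = 10_000,
    seed: int = 0,
    min_samples: int = 20,
) -> dict[tuple[str, str], float]:
    """Paired test of each edge's disconnection against the intact network.

    For edge e the per-sample deltas d_s = score(net, s) - score(net - e, s)
    are compared under H0 "removal does not hurt" with a one-sided sign-flip
    permutation test: p = (1 + #{flips with flipped sum >= observed sum}) /
    (n_perm + 1).  Requires at least ``min_samples`` retained samples.
    """
    if len(samples) < min_samples:
        raise ValueError(
            f"paired disconnection test needs >= {min_samples} retained samples, "
            f"got {len(samples)}"
        )
    edges, deltas = per_sample_deltas(net, genes, samples, prior)
    rng = np.random.default_rng(seed)
    flips = rng.integers(0, 2, size=(n_perm, deltas.shape[1])) * 2 - 1
    observed = deltas.sum(axis=1)
    null = deltas @ flips.T  # (E, n_perm)
    p = (1.0 + (null >= observed[:, None]).sum(axis=1)) / (n_perm + 1.0)
    return {e: float(v) for e, v in zip(edges, p)}


def write_edge_table(
    scores: list[EdgeScore],
    path: str | Path,
    null_pvalues: pd.DataFrame | None = None,
    disconnect_pvalues: dict[tuple[str, str], float] | None = None,
    top_k: tuple[int, ...] = (10, 50, 100, 250),
) -> pd.DataFrame:
    """Write the ranked-edge TSV.

    Columns: rank, regulator, gene, raw_delta (nats, present minus removed;
    positive = edge helps), norm_score, one p_top{K} column per K, and
    p_disconnect.  Missing p-values are written as NA.
    """
    ordered = sorted(scores, key=lambda e: e.rank)
    rows = []
    for e in ordered:
        row = {
            "rank": e.rank,
            "regulator": e.edge[0],
            "gene": e.edge[1],
            "raw_delta": e.raw_delta,
            "norm_score": e.norm_score,
        }
        for k in top_k:
            col = f"p_top{k}"
            if null_pvalues is not None and col in null_pvalues.columns:
                row[col] = null_pvalues.loc[e.edge, col]
            else:
                row[col] = np.nan
        row["p_disconnect"] = (
            disconnect_pvalues.get(e.edge, np.nan) if disconnect_pvalues else np.nan
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
    return df
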