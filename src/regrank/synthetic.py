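"""Synthetic bipartite networks and expression data with known ground truth.

The generator emulates the shape of the real problem: a known regulator ->
gene network, hidden 3-state regulator activities, and a continuous gene x
sample expression matrix driven by those activities through linear effects
— plus optional nonlinear interaction genes and decoy (zero-effect) edges
so that ranking quality is measurable.

Linear genes mix centered activities: value = sum_e w_e * (a_r - 1) + noise,
so "medium" activity (state 1) is neutral.  A nonlinear gene with rule
``exactly_one_high`` on two parents takes value +2 when exactly one parent
is in the high state and -2 otherwise (plus noise): an XOR-like interaction
with near-zero marginal correlation to either parent, invisible to pairwise
linear detectors but visible to a multinomial model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gibbs import HiddenStateMatrix
from .network import RegulatoryNetwork
from .preprocess import ExpressionMatrix

__all__ = [
    "SyntheticModel",
    "generate_network",
    "generate_data",
    "planted_edge_labels",
]

EXACTLY_ONE_HIGH = "exactly_one_high"


@dataclass(frozen=True)
class SyntheticModel:
    """A generated network plus its generative parameters.

    ``weights`` maps every edge to its linear effect size (0 for decoy
    edges and for edges feeding a nonlinear rule); ``nonlinear_genes`` maps
    gene -> rule tag.
    """

    net: RegulatoryNetwork
    weights: dict[tuple[str, str], float]
    noise_sd: float
    seed: int
    nonlinear_genes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if set(self.weights) != self.net.edges:
            raise ValueError("weights must cover exactly the network edges")
        for g, rule in self.nonlinear_genes.items():
            if rule != EXACTLY_ONE_HIGH:
                raise ValueError(f"unknown nonlinear rule {rule!r}")
            if len(self.net.parents_of(g)) != 2:
                raise ValueError(
                    f"nonlinear gene {g} needs exactly 2 parents, "
                    f"has {len(self.net.parents_of(g))}"
                )


def generate_network(
    n_regs: int,
    n_genes: int,
    parents_per_gene: tuple[int, int] = (1, 3),
    decoy_fraction: float = 0.0,
    seed: int = 0,
    n_nonlinear: int = 0,
    noise_sd: float = 0.5,
) -> SyntheticModel:
    """Random bipartite network with planted effect sizes.

    Each gene draws a parent count uniformly from ``parents_per_gene``
    (inclusive) and that many distinct random regulators.  Effect sizes are
    uniform on +/-[0.8, 1.5] — large enough that tertile discretization
    retains the signal at noise_sd 0.5; ``round(decoy_fraction * n_edges)``
    of the linear-gene edges are then zeroed out as decoys.  The first
    ``n_nonlinear`` randomly chosen genes get exactly two parents and the
    ``exactly_one_high`` rule instead of linear weights.
    """
    lo, hi = parents_per_gene
    if n_regs < 1:
        raise ValueError("need at least one regulator")
    if not (1 <= lo <= hi):
        raise ValueError("parents_per_gene must satisfy 1 <= min <= max")
    if hi > min(n_regs, 10):
        raise ValueError(
            f"max parents per gene ({hi}) exceeds feasible limit "
            f"({min(n_regs, 10)}: regulator count, and 10-parent cap)"
        )
    if not 0 <= decoy_fraction < 1:
        raise ValueError("decoy_fraction must lie in [0, 1)")
    if n_nonlinear > 0 and n_regs < 2:
        raise ValueError("nonlinear genes need at least 2 regulators")
    rng = np.random.default_rng(seed)
    regs = tuple(f"R{i + 1:02d}" for i in range(n_regs))
    gene_names = tuple(f"G{i + 1:03d}" for i in range(n_genes))
    nonlinear = set(rng.choice(n_genes, size=n_nonlinear, replace=False)) if n_nonlinear else set()
    edges: list[tuple[str, str]] = []
    gene_parent_count: dict[str, int] = {}
    for gi, g in enumerate(gene_names):
        k = 2 if gi in nonlinear else int(rng.integers(lo, hi + 1))
        parents = rng.choice(n_regs, size=k, replace=False)
        gene_parent_count[g] = k
        edges.extend((regs[int(p)], g) for p in sorted(parents))
    net = RegulatoryNetwork(regs, gene_names, frozenset(edges))
    nonlinear_genes = {gene_names[gi]: EXACTLY_ONE_HIGH for gi in sorted(nonlinear)}
    weights: dict[tuple[str, str], float] = {}
    linear_edges = [e for e in edges if e[1] not in nonlinear_genes]
    for e in sorted(linear_edges):
        mag = rng.uniform(0.8, 1.5)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        weights[e] = sign * mag
    n_decoy = int(round(decoy_fraction * len(linear_edges)))
    decoy_idx = rng.choice(len(linear_edges), size=n_decoy, replace=False)
    for i in decoy_idx:
        weights[sorted(linear_edges)[int(i)]] = 0.0
    for e in edges:
        if e[1] in nonlinear_genes:
            weights[e] = 0.0
    return SyntheticModel(net, weights, noise_sd, seed, nonlinear_genes)


def generate_data(
    model: SyntheticModel, n_obs: int, seed: int = 0
) -> tuple[ExpressionMatrix, HiddenStateMatrix]:
    """Sample hidden activities and expression under the model.

    Activities are iid uniform over {0, 1, 2} per regulator per observation.
    Linear genes mix centered parent activities through the planted weights;
    nonlinear genes apply their interaction rule; Gaussian noise with the
    model's noise_sd is added everywhere.  The true activities are returned
    for recovery scoring.
    """
    if n_obs < 3:
        raise ValueError("need at least 3 observations for tertile binning")
    rng = np.random.default_rng(seed)
    net = model.net
    regs = net.regulators
    activities = rng.integers(0, 3, size=(len(regs), n_obs), dtype=np.int8)
    reg_idx = {r: i for i, r in enumerate(regs)}
    sample_ids = tuple(f"S{i + 1:03d}" for i in range(n_obs))
    values = np.zeros((len(net.genes), n_obs))
    for gi, g in enumerate(net.genes):
        parents = net.parents_of(g)
        if g in model.nonlinear_genes:
            if len(parents) != 2:
                raise ValueError(f"nonlinear gene {g} needs exactly 2 parents")
            high = (activities[reg_idx[parents[0]]] == 2).astype(int) + (
                activities[reg_idx[parents[1]]] == 2
            ).astype(int)
            values[gi] = np.where(high == 1, 2.0, -2.0)
        else:
            for r in parents:
                values[gi] += model.weights[(r, g)] * (
                    activities[reg_idx[r]].astype(float) - 1.0
                )
    values += rng.normal(0.0, model.noise_sd, size=values.shape)
    expr = ExpressionMatrix(net.genes, sample_ids, values)
    truth = HiddenStateMatrix(regs, sample_ids, activities)
    return expr, truth


def planted_edge_labels(model: SyntheticModel) -> dict[tuple[str, str], str]:
    """Label each edge ``strong`` (nonzero effect, or feeds a nonlinear
    rule) or ``decoy`` (zero effect)."""
    labels = {}
    for e in model.net.edges:
        if e[1] in model.nonlinear_genes or abs(model.weights[e]) > 0:
            labels[e] = "strong"
        else:
            labels[e] = "decoy"
    return labels
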