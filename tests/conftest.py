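import numpy as np
import pytest

from regrank import (
    DiscretizedMatrix,
    ExpressionMatrix,
    PriorSpec,
    RegulatoryNetwork,
)


@pytest.fixture
def prior():
    return PriorSpec()


@pytest.fixture
def small_net():
    """2 regulators, 3 genes; G2 has both regulators as parents."""
    return RegulatoryNetwork(
        ("R1", "R2"),
        ("G1", "G2", "G3"),
        frozenset({("R1", "G1"), ("R1", "G2"), ("R2", "G2"), ("R2", "G3")}),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_network(rng, n_regs, n_genes, max_parents=3) -> RegulatoryNetwork:
    """Random bipartite network where every gene has >= 1 parent."""
    regs = tuple(f"R{i}" for i in range(n_regs))
    genes = tuple(f"G{i}" for i in range(n_genes))
    edges = set()
    for g in genes:
        k = int(rng.integers(1, min(max_parents, n_regs) + 1))
        for p in rng.choice(n_regs, size=k, replace=False):
            edges.add((regs[int(p)], g))
    return RegulatoryNetwork(regs, genes, frozenset(edges))


def random_discretized(rng, genes, n_obs) -> DiscretizedMatrix:
    return DiscretizedMatrix(
        tuple(genes),
        tuple(f"s{i}" for i in range(n_obs)),
        rng.integers(0, 3, size=(len(genes), n_obs), dtype=np.int8),
    )


def random_expression(rng, n_genes, n_obs) -> ExpressionMatrix:
    return ExpressionMatrix(
        tuple(f"G{i}" for i in range(n_genes)),
        tuple(f"s{i}" for i in range(n_obs)),
        rng.normal(size=(n_genes, n_obs)),
    )
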