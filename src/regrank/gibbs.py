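"""Gibbs sampling of hidden regulator activities.

Regulator activities are never observed; the sampler draws completions of
the regulator x sample state matrix from their posterior given the observed
discretized genes.  Because the BDe score decomposes over families, the full
conditional of one hidden cell (regulator r, observation m) involves only
r's own parentless term and the local terms of r's target genes, and reduces
to a product of Dirichlet-multinomial one-step predictive probabilities with
observation m's contribution removed from the counts.  The sweep visits
cells in a fixed scan order (regulators in declared order, observations in
sample order) so a run is a pure function of its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bde import PriorSpec, network_score
from .network import RegulatoryNetwork
from .preprocess import DiscretizedMatrix

__all__ = [
    "HiddenStateMatrix",
    "GibbsConfig",
    "init_hidden_states",
    "cell_conditional",
    "gibbs_sweep",
    "run_gibbs",
]


@dataclass(frozen=True)
class HiddenStateMatrix:
    """Regulator x sample matrix of discrete activity states in {0, 1, 2}."""

    regulators: tuple[str, ...]
    samples: tuple[str, ...]
    states: np.ndarray  # int8, shape (n_regulators, n_samples)
    n_states: int = 3

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=np.int8)
        if states.shape != (len(self.regulators), len(self.samples)):
            raise ValueError("states shape does not match regulator/sample labels")
        if states.size and (states.min() < 0 or states.max() >= self.n_states):
            raise ValueError(f"states must lie in [0, {self.n_states})")
        object.__setattr__(self, "states", states)

    def row(self, regulator: str) -> np.ndarray:
        return self.states[self.regulators.index(regulator)]

    def with_cell(self, regulator: str, m: int, state: int) -> "HiddenStateMatrix":
        states = self.states.copy()
        states[self.regulators.index(regulator), m] = state
        return HiddenStateMatrix(self.regulators, self.samples, states, self.n_states)

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.states, index=list(self.regulators), columns=list(self.samples)
        ).to_csv(path, sep="\t", index_label="regulator")


@dataclass(frozen=True)
class GibbsConfig:
    """Sampler schedule: ``burn_in`` discarded sweeps, then ``n_samples``
    retained states separated by ``thinning`` sweeps."""

    burn_in: int = 10
    n_samples: int = 50
    thinning: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.n_samples < 1 or self.thinning < 1:
            raise ValueError("require burn_in >= 0, n_samples >= 1, thinning >= 1")


def init_hidden_states(
    net: RegulatoryNetwork,
    n_obs: int,
    seed: int | np.random.Generator,
    sample_ids: tuple[str, ...] | None = None,
) -> HiddenStateMatrix:
    """Uniform-random initial completion, deterministic under the seed."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = rng.integers(0, 3, size=(len(net.regulators), n_obs), dtype=np.int8)
    if sample_ids is None:
        sample_ids = tuple(f"obs{i + 1}" for i in range(n_obs))
    return HiddenStateMatrix(net.regulators, sample_ids, states)


def cell_conditional(
    r: str,
    m: int,
    current: HiddenStateMatrix,
    genes: DiscretizedMatrix,
    net: RegulatoryNetwork,
    prior: PriorSpec,
) -> np.ndarray:
    """Full conditional P(state of cell (r, m) | everything else) as a
    probability vector over {0, 1, 2}.

    Reference definition: P(k) is proportional to exp(network score with the
    cell set to k).  This evaluates the three completed-data scores in full;
    the sweep engine computes the same distribution from local terms only.
    """
    logp = np.array(
        [
            network_score(net, genes, current.with_cell(r, m, k), prior)
            for k in range(current.n_states)
        ]
    )
    logp -= logp.max()
    p = np.exp(logp)
    return p / p.sum()


class _GibbsEngine:
    """Incremental count-table state for fast sweeps.

    Maintains, for the current completion, each regulator's marginal counts
    and each gene family's (parent-config x state) count table; resampling a
    cell touches only the tables of that regulator and its target genes.
    Plain Python lists are used for the scalar-heavy inner loop.
    """

    def __init__(
        self,
        net: RegulatoryNetwork,
        genes: DiscretizedMatrix,
        prior: PriorSpec,
        init: HiddenStateMatrix,
    ) -> None:
        if init.states.shape[1] != genes.states.shape[1]:
            raise ValueError("hidden and gene matrices have different sample counts")
        self.net = net
        self.prior = prior
        self.arity = genes.n_states
        self.n_obs = genes.states.shape[1]
        self.regulators = list(net.regulators)
        self.sample_ids = init.samples
        self.H: list[list[int]] = [list(map(int, row)) for row in init.states]

        arity = self.arity
        gene_index = {g: i for i, g in enumerate(net.genes)}
        reg_index = {r: i for i, r in enumerate(net.regulators)}
        self.gene_x: list[list[int]] = [
            list(map(int, genes.row(g))) for g in net.genes
        ]
        # per gene: parent regulator indices, per-parent stride, q, tables
        self.gene_parents: list[list[int]] = []
        self.gene_stride: list[dict[int, int]] = []
        self.gene_alpha: list[float] = []
        self.gene_row_alpha: list[float] = []
        self.tables: list[list[list[int]]] = []  # [gene][config][state]
        self.rowsums: list[list[int]] = []  # [gene][config]
        self.cfg: list[list[int]] = []  # [gene][obs] current parent config
        for gi, g in enumerate(net.genes):
            parents = [reg_index[p] for p in net.parents_of(g)]
            q = arity ** len(parents)
            strides = {}
            s = q
            for p in parents:  # first parent most significant
                s //= arity
                strides[p] = s
            a = prior.cell_alpha(q, arity)
            self.gene_parents.append(parents)
            self.gene_stride.append(strides)
            self.gene_alpha.append(a)
            self.gene_row_alpha.append(a * arity)
            table = [[0] * arity for _ in range(q)]
            rowsum = [0] * q
            x = self.gene_x[gi]
            cfg_row = []
            for m in range(self.n_obs):
                c = 0
                for p in parents:
                    c = c * arity + self.H[p][m]
                table[c][x[m]] += 1
                rowsum[c] += 1
                cfg_row.append(c)
            self.tables.append(table)
            self.rowsums.append(rowsum)
            self.cfg.append(cfg_row)
        # regulator marginal counts and child lists
        self.reg_alpha = prior.cell_alpha(1, arity)
        self.reg_counts: list[list[int]] = []
        self.reg_children: list[list[int]] = []
        for ri, r in enumerate(net.regulators):
            counts = [0] * arity
            for v in self.H[ri]:
                counts[v] += 1
            self.reg_counts.append(counts)
            self.reg_children.append([gene_index[g] for g in net.children_of(r)])

    def conditional(self, ri: int, m: int) -> list[float]:
        """Normalized full conditional of cell (ri, m); leaves state intact."""
        logp = self._candidate_logp(ri, m, remove=False)
        mx = max(logp)
        w = [math.exp(v - mx) for v in logp]
        tot = sum(w)
        return [v / tot for v in w]

    def _candidate_logp(self, ri: int, m: int, remove: bool) -> list[float]:
        """Unnormalized log conditional for the 3 candidate states.

        With ``remove=True`` the cell's current contribution stays removed
        from the tables on return (caller must re-add via ``_add``).
        """
        arity = self.arity
        old = self.H[ri][m]
        rc = self.reg_counts[ri]
        rc[old] -= 1
        children = self.reg_children[ri]
        bases = []
        for gi in children:
            c = self.cfg[gi][m]
            x = self.gene_x[gi][m]
            self.tables[gi][c][x] -= 1
            self.rowsums[gi][c] -= 1
            bases.append((gi, c - old * self.gene_stride[gi][ri], x))
        a = self.reg_alpha
        logp = [math.log(a + rc[0]), math.log(a + rc[1]), math.log(a + rc[2])]
        for gi, base, x in bases:
            stride = self.gene_stride[gi][ri]
            table = self.tables[gi]
            rowsum = self.rowsums[gi]
            ag = self.gene_alpha[gi]
            arow = self.gene_row_alpha[gi]
            for k in range(arity):
                c = base + k * stride
                logp[k] += math.log((ag + table[c][x]) / (arow + rowsum[c]))
        if not remove:
            self._add(ri, m, old, bases)
        self._pending = bases
        return logp

    def _add(self, ri: int, m: int, k: int, bases) -> None:
        self.reg_counts[ri][k] += 1
        for gi, base, x in bases:
            c = base + k * self.gene_stride[gi][ri]
            self.tables[gi][c][x] += 1
            self.rowsums[gi][c] += 1
            self.cfg[gi][m] = c
        self.H[ri][m] = k

    def sweep(self, rng: np.random.Generator) -> None:
        """One systematic scan: every cell resampled once from its full
        conditional, consuming one uniform per cell in scan order."""
        n_regs = len(self.regulators)
        u = rng.random(n_regs * self.n_obs)
        ui = 0
        for ri in range(n_regs):
            for m in range(self.n_obs):
                logp = self._candidate_logp(ri, m, remove=True)
                mx = logp[0]
                if logp[1] > mx:
                    mx = logp[1]
                if logp[2] > mx:
                    mx = logp[2]
                w0 = math.exp(logp[0] - mx)
                w1 = math.exp(logp[1] - mx)
                w2 = math.exp(logp[2] - mx)
                t = u[ui] * (w0 + w1 + w2)
                ui += 1
                if t < w0:
                    k = 0
                elif t < w0 + w1:
                    k = 1
                else:
                    k = 2
                self._add(ri, m, k, self._pending)

    def snapshot(self) -> HiddenStateMatrix:
        return HiddenStateMatrix(
            tuple(self.regulators),
            self.sample_ids,
            np.array(self.H, dtype=np.int8),
            self.arity,
        )


def gibbs_sweep(
    current: HiddenStateMatrix,
    genes: DiscretizedMatrix,
    net: RegulatoryNetwork,
    prior: PriorSpec,
    rng: np.random.Generator,
) -> HiddenStateMatrix:
    """One full systematic-scan sweep; returns a new state matrix."""
    engine = _GibbsEngine(net, genes, prior, current)
    engine.sweep(rng)
    return engine.snapshot()


def run_gibbs(
    net: RegulatoryNetwork,
    genes: DiscretizedMatrix,
    prior: PriorSpec,
    config: GibbsConfig,
) -> list[HiddenStateMatrix]:
    """Run the sampler: uniform-random initialization, ``burn_in`` discarded
    sweeps, then ``n_samples`` retained states ``thinning`` sweeps apart.

    One RNG stream, seeded from ``config.seed``, drives the initialization
    and every sweep, so the retained-sample list is a pure function of
    (inputs, seed).
    """
    rng = np.random.default_rng(config.seed)
    init = init_hidden_states(net, genes.n_samples, rng, sample_ids=genes.samples)
    engine = _GibbsEngine(net, genes, prior, init)
    for _ in range(config.burn_in):
        engine.sweep(rng)
    retained: list[HiddenStateMatrix] = []
    for _ in range(config.n_samples):
        for _ in range(config.thinning):
            engine.sweep(rng)
        retained.append(engine.snapshot())
    return retained
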