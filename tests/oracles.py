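"""Independent reference implementations used only as test oracles.

Everything here is deliberately written from the closed-form definitions
with naive loops and ``math.lgamma`` — no code is shared with the package's
scoring or sampling paths, so agreement is evidence, not tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.special import gammaln


def naive_local_score(counts_2d, cell_alpha: float) -> float:
    """BDe local family score from a (q x r) count table, by direct loops."""
    score = 0.0
    for row in counts_2d:
        n_ij = sum(row)
        a_ij = cell_alpha * len(row)
        score += math.lgamma(a_ij) - math.lgamma(a_ij + n_ij)
        for n in row:
            score += math.lgamma(cell_alpha + n) - math.lgamma(cell_alpha)
    return score


def naive_network_score(
    regulators: list[str],
    genes: list[str],
    parents: dict[str, list[str]],
    hidden: dict[str, list[int]],
    observed: dict[str, list[int]],
    cell_alpha: float = 1.0,
    arity: int = 3,
) -> float:
    """Closed-form Dirichlet-multinomial network score by brute force.

    ``parents`` maps gene -> ordered regulator list; ``hidden``/``observed``
    map variable -> state sequence.  Families are tallied with explicit
    per-observation loops.
    """
    n_obs = len(next(iter(observed.values()))) if observed else len(next(iter(hidden.values())))
    total = 0.0
    for r in regulators:
        counts = [[0] * arity]
        for v in hidden[r]:
            counts[0][v] += 1
        total += naive_local_score(counts, cell_alpha)
    for g in genes:
        ps = parents.get(g, [])
        q = arity ** len(ps)
        counts = [[0] * arity for _ in range(q)]
        for m in range(n_obs):
            j = 0
            for p in ps:
                j = j * arity + hidden[p][m]
            counts[j][observed[g][m]] += 1
        total += naive_local_score(counts, cell_alpha)
    return total


def _compositions(total: int, bins: int):
    """All nonnegative integer vectors of length ``bins`` summing to ``total``."""
    if bins == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, bins - 1):
            yield (first,) + rest


def exact_cell_marginals_two_regs(
    gene_parents: dict[str, list[str]],
    gene_states: dict[str, list[int]],
    n_obs: int,
    cell_alpha: float = 1.0,
):
    """Exact posterior hidden-cell marginals for a 2-regulator network.

    The posterior over completions P(H | X) is proportional to
    exp(network score).  Each observation's hidden pair (h1, h2) is one of
    nine joint configurations, and the score depends on the completion only
    through per-group counts of those configurations, where a "group" is a
    set of observations sharing an identical gene-state column.  Summing
    over count vectors (with multinomial multiplicities) instead of raw
    completions makes tiny instances exactly enumerable.

    Supports exactly two distinct gene-state columns.  Returns an array of
    shape (2, n_obs, 3): marginal P(H[r, m] = k | X).
    """
    regs = ["_R1", "_R2"]
    genes = list(gene_parents)
    columns = [tuple(gene_states[g][m] for g in genes) for m in range(n_obs)]
    groups = list(dict.fromkeys(columns))
    assert len(groups) == 2, "oracle supports exactly two distinct gene columns"
    group_of = [groups.index(c) for c in columns]
    sizes = [group_of.count(0), group_of.count(1)]

    V = [np.array(list(_compositions(n, 9)), dtype=float) for n in sizes]
    lw = [
        np.array([_log_multinomial(n, v) for v in Vg])
        for n, Vg in zip(sizes, V)
    ]
    n1, n2 = V[0].shape[0], V[1].shape[0]

    # regulator marginal counts per joint-config vector: h1 = c // 3, h2 = c % 3
    c_idx = np.arange(9)
    h1_of = c_idx // 3
    h2_of = c_idx % 3
    # total config counts per (i, l) pair
    T = V[0][:, None, :] + V[1][None, :, :]  # (n1, n2, 9)

    def fam_score_from_counts(tbl):
        """tbl shape (..., q, r): BDe score per leading index."""
        a = cell_alpha
        r = tbl.shape[-1]
        n_ij = tbl.sum(-1)
        return (
            (gammaln(a * r) - gammaln(a * r + n_ij)).sum(-1)
            + (gammaln(a + tbl) - gammaln(a)).sum((-2, -1))
        )

    logw = lw[0][:, None] + lw[1][None, :]
    for ri, h_of in ((0, h1_of), (1, h2_of)):
        reg_counts = np.stack(
            [T[:, :, h_of == k].sum(-1) for k in range(3)], axis=-1
        )[:, :, None, :]  # (n1, n2, 1, 3)
        logw = logw + fam_score_from_counts(reg_counts)
    for g in genes:
        ps = gene_parents[g]
        if ps == ["_R1"]:
            cfg_of = h1_of
            q = 3
        elif ps == ["_R2"]:
            cfg_of = h2_of
            q = 3
        elif ps == ["_R1", "_R2"]:
            cfg_of = c_idx  # mixed radix, first parent most significant
            q = 9
        else:
            raise AssertionError(f"unsupported parent set {ps}")
        x_by_group = [groups[0][genes.index(g)], groups[1][genes.index(g)]]
        tbl = np.zeros((n1, n2, q, 3))
        for gi, (Vg, axis) in enumerate(zip(V, (0, 1))):
            marg = np.zeros((Vg.shape[0], q))
            for c in range(9):
                marg[:, cfg_of[c]] += Vg[:, c]
            shape = (n1, 1, q) if axis == 0 else (1, n2, q)
            tbl[:, :, :, x_by_group[gi]] += marg.reshape(shape)
        logw = logw + fam_score_from_counts(tbl)

    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    # E[fraction of group-g observations in joint config c]
    exp_v1 = np.einsum("il,ic->c", w, V[0]) / sizes[0]
    exp_v2 = np.einsum("il,lc->c", w, V[1]) / sizes[1]
    p_config = [exp_v1, exp_v2]  # P(c_m = c) for m in group g
    out = np.zeros((2, n_obs, 3))
    for m in range(n_obs):
        pc = p_config[group_of[m]]
        for k in range(3):
            out[0, m, k] = pc[h1_of == k].sum()
            out[1, m, k] = pc[h2_of == k].sum()
    return out


def _log_multinomial(n: int, v) -> float:
    out = math.lgamma(n + 1)
    for x in v:
        out -= math.lgamma(x + 1)
    return out


def brute_force_cell_marginals(
    gene_parents: dict[str, list[str]],
    gene_states: dict[str, list[int]],
    n_regs: int,
    n_obs: int,
    cell_alpha: float = 1.0,
):
    """Exact marginals by raw enumeration of all 3^(n_regs * n_obs) hidden
    completions — only viable for very small instances; used to validate the
    count-vector oracle above."""
    regs = [f"_R{i + 1}" for i in range(n_regs)]
    genes = list(gene_parents)
    logw = []
    assignments = list(itertools.product(range(3), repeat=n_regs * n_obs))
    for flat in assignments:
        hidden = {
            r: list(flat[i * n_obs : (i + 1) * n_obs]) for i, r in enumerate(regs)
        }
        logw.append(
            naive_network_score(
                regs, genes, gene_parents, hidden, gene_states, cell_alpha
            )
        )
    logw = np.array(logw)
    w = np.exp(logw - logw.max())
    w /= w.sum()
    out = np.zeros((n_regs, n_obs, 3))
    for a, wa in zip(assignments, w):
        for ri in range(n_regs):
            for m in range(n_obs):
                out[ri, m, a[ri * n_obs + m]] += wa
    return out
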