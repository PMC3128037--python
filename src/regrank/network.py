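"""Bipartite regulator->gene network container and its file formats.

The network has two layers: regulators on top (hidden transcription-factor
activities) and target genes below (observed expression).  A symbol may
legally appear both as a regulator ID and as a gene symbol — the activity of
transcription factor "A" and the expression of gene "A" are two different
variables, so the two namespaces never mix.

Supported formats:

* MsigDB-style GMT gene sets (one motif / TF gene set per line:
  ``name<TAB>description<TAB>member...``), with an optional motif -> TF-name
  mapping; motifs without a known TF name receive ``UK1``, ``UK2``, ...
  labels in input order.
* Two-column TSV edge lists with header ``regulator<TAB>gene``.

Gene symbols are taken verbatim (case-sensitive, no alias resolution):
mapping to official symbols is part of upstream input preparation.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "RegulatoryNetwork",
    "NetworkFormatError",
    "read_gmt",
    "read_edge_list",
    "read_tf_mapping",
    "write_network",
    "assign_unknown_labels",
]


class NetworkFormatError(ValueError):
    """Raised when a network file does not conform to its declared format."""


@dataclass(frozen=True)
class RegulatoryNetwork:
    """Immutable bipartite regulator->gene network.

    Parameters
    ----------
    regulators
        Regulator IDs in declaration order (defines Gibbs scan order).
    genes
        Gene symbols in declaration order.
    edges
        Set of ``(regulator_id, gene_symbol)`` pairs.  Every edge endpoint
        must be declared; edges are regulator->gene only.
    """

    regulators: tuple[str, ...]
    genes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    _parents: dict = field(init=False, repr=False, compare=False, default=None)
    _children: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        regs, genes = set(self.regulators), set(self.genes)
        if len(regs) != len(self.regulators):
            raise ValueError("duplicate regulator IDs")
        if len(genes) != len(self.genes):
            raise ValueError("duplicate gene symbols")
        if any(not r for r in self.regulators) or any(not g for g in self.genes):
            raise ValueError("empty regulator ID or gene symbol")
        for r, g in self.edges:
            if r not in regs:
                raise ValueError(f"edge regulator {r!r} not declared")
            if g not in genes:
                raise ValueError(f"edge gene {g!r} not declared")
        parents: dict[str, list[str]] = {g: [] for g in self.genes}
        children: dict[str, list[str]] = {r: [] for r in self.regulators}
        # adjacency in declaration order, deterministically
        gene_pos = {g: i for i, g in enumerate(self.genes)}
        reg_pos = {r: i for i, r in enumerate(self.regulators)}
        for r, g in sorted(self.edges, key=lambda e: (reg_pos[e[0]], gene_pos[e[1]])):
            parents[g].append(r)
            children[r].append(g)
        object.__setattr__(self, "_parents", {g: tuple(v) for g, v in parents.items()})
        object.__setattr__(self, "_children", {r: tuple(v) for r, v in children.items()})

    # Identity ignores declaration order: the same edge structure read back
    # from disk is the same network even if node order differs.
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        return (
            set(self.regulators) == set(other.regulators)
            and set(self.genes) == set(other.genes)
            and self.edges == other.edges
        )

    def __hash__(self) -> int:
        return hash((frozenset(self.regulators), frozenset(self.genes), self.edges))

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        regulators: Sequence[str] | None = None,
        genes: Sequence[str] | None = None,
    ) -> "RegulatoryNetwork":
        """Build a network from edges, inferring node sets in first-appearance
        order unless explicit orders are given."""
        edge_list = list(edges)
        if regulators is None:
            regulators = list(dict.fromkeys(r for r, _ in edge_list))
        if genes is None:
            genes = list(dict.fromkeys(g for _, g in edge_list))
        return cls(tuple(regulators), tuple(genes), frozenset(edge_list))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def parents_of(self, gene: str) -> tuple[str, ...]:
        """Regulators with an edge into ``gene``, in regulator declaration order."""
        return self._parents[gene]

    def children_of(self, regulator: str) -> tuple[str, ...]:
        """Genes targeted by ``regulator``, in gene declaration order."""
        return self._children[regulator]

    def without_edge(self, regulator: str, gene: str) -> "RegulatoryNetwork":
        """Copy of the network with one edge removed (nodes are kept)."""
        if (regulator, gene) not in self.edges:
            raise KeyError(f"edge ({regulator}, {gene}) not in network")
        return RegulatoryNetwork(
            self.regulators, self.genes, self.edges - {(regulator, gene)}
        )

    def sorted_edges(self) -> list[tuple[str, str]]:
        """Edges ordered by (regulator declaration, gene declaration)."""
        reg_pos = {r: i for i, r in enumerate(self.regulators)}
        gene_pos = {g: i for i, g in enumerate(self.genes)}
        return sorted(self.edges, key=lambda e: (reg_pos[e[0]], gene_pos[e[1]]))


def assign_unknown_labels(
    motif_names: Sequence[str], tf_mapping: Mapping[str, str] | None
) -> dict[str, str]:
    """Map motif names to regulator IDs.

    Motifs present in ``tf_mapping`` keep their TF name; the rest are labeled
    ``UK1``, ``UK2``, ... in input order.  Two distinct motifs mapping to the
    same TF name are merged into one regulator (a warning is logged): the
    regulator variable is the TF's activity, not the motif.
    """
    tf_mapping = tf_mapping or {}
    labels: dict[str, str] = {}
    seen_tf: dict[str, str] = {}
    counter = 0
    for motif in motif_names:
        if motif in tf_mapping:
            tf = tf_mapping[motif]
            if tf in seen_tf.values() and motif not in seen_tf:
                logger.warning(
                    "motifs %r map to the same TF %r; merging their targets",
                    [m for m, t in seen_tf.items() if t == tf] + [motif],
                    tf,
                )
            labels[motif] = tf
            seen_tf[motif] = tf
        else:
            counter += 1
            labels[motif] = f"UK{counter}"
    return labels


def read_tf_mapping(path: str | Path) -> dict[str, str]:
    """Read a motif -> TF-name mapping TSV with header ``motif<TAB>tf_name``."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        cols = reader.fieldnames or []
        if "motif" not in cols or "tf_name" not in cols:
            raise NetworkFormatError(
                f"{path}: mapping file needs columns 'motif' and 'tf_name', got {cols}"
            )
        return {row["motif"]: row["tf_name"] for row in reader if row["motif"]}


def read_gmt(
    path: str | Path, tf_mapping: Mapping[str, str] | None = None
) -> RegulatoryNetwork:
    """Parse an MsigDB-style GMT file into a bipartite network.

    Each line is ``set_name<TAB>description<TAB>gene...``; every gene set
    becomes one regulator whose targets are the member genes.  Duplicate
    (regulator, gene) pairs collapse to a single edge.  An empty file yields
    an empty network; a line with fewer than three tab-separated fields is a
    format error naming the line number.
    """
    path = Path(path)
    motif_members: dict[str, list[str]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise NetworkFormatError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields "
                    f"(name, description, members...), got {len(fields)}"
                )
            name, _desc, *members = fields
            motif_members.setdefault(name, []).extend(m for m in members if m)
    labels = assign_unknown_labels(list(motif_members), tf_mapping)
    edges: list[tuple[str, str]] = []
    for motif, members in motif_members.items():
        reg = labels[motif]
        edges.extend((reg, g) for g in members)
    regulators = list(dict.fromkeys(labels[m] for m in motif_members))
    genes = list(dict.fromkeys(g for _, g in edges))
    return RegulatoryNetwork(tuple(regulators), tuple(genes), frozenset(edges))


def read_edge_list(path: str | Path) -> RegulatoryNetwork:
    """Read a TSV edge list with header ``regulator<TAB>gene`` (deduplicated)."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        cols = reader.fieldnames or []
        if "regulator" not in cols or "gene" not in cols:
            raise NetworkFormatError(
                f"{path}: edge list needs columns 'regulator' and 'gene', got {cols}"
            )
        edges = [(row["regulator"], row["gene"]) for row in reader]
    return RegulatoryNetwork.from_edges(dict.fromkeys(edges))


def write_network(net: RegulatoryNetwork, path: str | Path) -> None:
    """Write the network as a TSV edge list; round-trips through
    :func:`read_edge_list` (isolated nodes are not representable)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["regulator", "gene"])
        writer.writerows(net.sorted_edges())
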