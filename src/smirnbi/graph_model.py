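"""Bipartite small-molecule/miRNA network construction.

The central object is :class:`BipartiteNetwork`: an ordered set of m small
molecules S = {s_1..s_m}, an ordered set of n mature miRNAs M = {m_1..m_n},
and an unweighted incidence matrix X with X[i, j] = 1 iff s_i regulates m_j.
Each edge additionally carries a regulation-direction label (``up``, ``down``
or ``unknown``) that downstream reporting uses but the diffusion model does
not: the scoring algorithm treats the network as undirected and unlabeled.

Curated regulation records frequently contain exact duplicates (the same
molecule/miRNA/direction triple from several references) and conflicts (the
same pair reported as both up- and down-regulated). :func:`merge_duplicate_edges`
collapses duplicates and resolves conflicts by a configurable policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .net_io import Direction, RegulationRecord

__all__ = ["BipartiteNetwork", "merge_duplicate_edges", "build_adjacency"]


@dataclass
class BipartiteNetwork:
    """Deduplicated bipartite molecule-miRNA graph.

    Attributes
    ----------
    molecules, mirnas:
        Node labels in first-appearance order. Indices into these lists are
        the 0-based node indices used everywhere else.
    edges:
        Set of ``(molecule_index, mirna_index, direction)`` triples; at most
        one edge per (molecule, miRNA) pair.
    """

    molecules: list[str] = field(default_factory=list)
    mirnas: list[str] = field(default_factory=list)
    edges: set[tuple[int, int, Direction]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(set(self.molecules)) != len(self.molecules):
            raise ValueError("duplicate molecule labels")
        if len(set(self.mirnas)) != len(self.mirnas):
            raise ValueError("duplicate miRNA labels")
        pairs = {(i, j) for i, j, _ in self.edges}
        if len(pairs) != len(self.edges):
            raise ValueError("more than one edge for some (molecule, miRNA) pair")

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    @property
    def n_mirnas(self) -> int:
        return len(self.mirnas)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def molecule_index(self, label: str) -> int:
        try:
            return self.molecules.index(label)
        except ValueError:
            raise KeyError(f"unknown molecule: {label!r}") from None

    def mirna_index(self, label: str) -> int:
        try:
            return self.mirnas.index(label)
        except ValueError:
            raise KeyError(f"unknown miRNA: {label!r}") from None

    def incidence(self) -> np.ndarray:
        """The m-by-n 0/1 incidence matrix X."""
        X = np.zeros((self.n_molecules, self.n_mirnas))
        for i, j, _ in self.edges:
            X[i, j] = 1.0
        return X

    def edge_pairs(self) -> list[tuple[int, int]]:
        """Sorted (molecule_index, mirna_index) pairs, direction stripped."""
        return sorted((i, j) for i, j, _ in self.edges)

    def subnetwork(self, keep_pairs: Iterable[tuple[int, int]]) -> "BipartiteNetwork":
        """Same node sets, edges restricted to ``keep_pairs``."""
        keep = set(keep_pairs)
        return BipartiteNetwork(
            molecules=list(self.molecules),
            mirnas=list(self.mirnas),
            edges={(i, j, d) for i, j, d in self.edges if (i, j) in keep},
        )


def merge_duplicate_edges(
    records: Sequence[RegulationRecord],
    conflict_policy: str = "drop",
) -> BipartiteNetwork:
    """Collapse duplicate regulation records into a simple bipartite network.

    Identical (molecule, miRNA, direction) triples collapse to one edge. A
    pair reported as both up- and down-regulated is a conflict:

    - ``conflict_policy="drop"`` (default) removes the pair entirely; the
      nodes stay in the network and may end up isolated.
    - ``conflict_policy="keep_unknown"`` keeps one edge labelled ``unknown``.

    A pair reported with a known direction plus ``unknown`` records is not a
    conflict; the known direction wins. Node order is first-appearance order
    over the input records.
    """
    if conflict_policy not in ("drop", "keep_unknown"):
        raise ValueError(f"unknown conflict policy: {conflict_policy!r}")

    molecules: list[str] = []
    mirnas: list[str] = []
    mol_idx: dict[str, int] = {}
    mir_idx: dict[str, int] = {}
    directions: dict[tuple[int, int], set[Direction]] = {}

    for rec in records:
        if rec.molecule_id not in mol_idx:
            mol_idx[rec.molecule_id] = len(molecules)
            molecules.append(rec.molecule_id)
        if rec.mirna_id not in mir_idx:
            mir_idx[rec.mirna_id] = len(mirnas)
            mirnas.append(rec.mirna_id)
        key = (mol_idx[rec.molecule_id], mir_idx[rec.mirna_id])
        directions.setdefault(key, set()).add(rec.direction)

    edges: set[tuple[int, int, Direction]] = set()
    for (i, j), dirs in directions.items():
        known = dirs - {Direction.UNKNOWN}
        if len(known) == 2:  # both up and down reported
            if conflict_policy == "keep_unknown":
                edges.add((i, j, Direction.UNKNOWN))
            continue
        direction = known.pop() if known else Direction.UNKNOWN
        edges.add((i, j, direction))

    return BipartiteNetwork(molecules=molecules, mirnas=mirnas, edges=edges)


def build_adjacency(net: BipartiteNetwork) -> np.ndarray:
    """Initial resource matrix A = [[0, X], [X^T, 0]] of order m + n.

    Molecule nodes occupy rows/columns 0..m-1, miRNA nodes m..m+n-1. A is
    symmetric with zero diagonal blocks because the graph is bipartite.
    """
    X = net.incidence()
    m, n = X.shape
    A = np.zeros((m + n, m + n))
    A[:m, m:] = X
    A[m:, :m] = X.T
    return A
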