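"""Topological analyses: degrees, molecule projection, MCODE-style modules.

The homogeneous projection links two molecules whenever they co-regulate at
least one miRNA (edge weight = number of shared miRNAs); module detection on
that projection groups molecules that share regulated miRNAs, which in
practice tends to group molecules with a common mechanism of action.

Module detection follows the MCODE (molecular complex detection) algorithm:
vertices are weighted by the core-clustering density of their neighbourhood,
complexes grow outward from high-weight seeds admitting neighbours whose
weight stays within ``node_score_cutoff`` of the seed's, and post-processing
(2-core filter, optional haircut/fluff) cleans the result. Defaults mirror
the Cytoscape plugin: degree cutoff 2, haircut on, fluff off.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph_model import BipartiteNetwork
from .net_io import Direction

__all__ = [
    "ModuleResult",
    "node_degrees",
    "top_k_nodes",
    "project_homogeneous",
    "mcode_modules",
]


@dataclass
class ModuleResult:
    seed_node: str
    members: set[str]
    module_score: float
    rank: int


def node_degrees(net: BipartiteNetwork, mode: str = "global") -> dict[str, int]:
    """Degree K of every node, optionally restricted by edge direction.

    ``global`` counts all edges; ``up_only``/``down_only`` count only edges
    with that direction label. Every node appears in the mapping, isolated
    ones with degree 0.
    """
    if mode not in ("global", "up_only", "down_only"):
        raise ValueError(f"unknown degree mode: {mode!r}")
    wanted = {
        "global": {Direction.UP, Direction.DOWN, Direction.UNKNOWN},
        "up_only": {Direction.UP},
        "down_only": {Direction.DOWN},
    }[mode]
    degrees = {label: 0 for label in (*net.molecules, *net.mirnas)}
    for i, j, d in net.edges:
        if d in wanted:
            degrees[net.molecules[i]] += 1
            degrees[net.mirnas[j]] += 1
    return degrees


def top_k_nodes(degrees: dict[str, int], k: int) -> list[str]:
    """The k highest-degree node labels; ties broken lexicographically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(degrees, key=lambda n: (-degrees[n], n))
    return ranked[:k]


def project_homogeneous(net: BipartiteNetwork) -> nx.Graph:
    """Molecule-molecule graph linking molecules that share regulated miRNAs.

    Edge weight = number of co-regulated miRNAs. All molecules appear as
    vertices; ones sharing no miRNA with anybody stay isolated.
    """
    X = net.incidence()
    shared = X @ X.T  # shared[i, j] = number of co-regulated miRNAs
    g = nx.Graph()
    g.add_nodes_from(net.molecules)
    m = net.n_molecules
    for i in range(m):
        for j in range(i + 1, m):
            if shared[i, j] > 0:
                g.add_edge(net.molecules[i], net.molecules[j], weight=int(shared[i, j]))
    return g


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def _highest_k_core(g: nx.Graph) -> tuple[int, nx.Graph]:
    """The maximum k for which g has a non-empty k-core, and that core."""
    if g.number_of_nodes() == 0:
        return 0, g
    core_numbers = nx.core_number(g)
    k = max(core_numbers.values())
    core = g.subgraph([v for v, c in core_numbers.items() if c >= k])
    return k, core


def _vertex_weights(g: nx.Graph, degree_cutoff: int) -> dict[str, float]:
    """MCODE vertex weight: k * density of the highest k-core of N[v].

    Vertices below the degree cutoff are not scored (weight 0), matching
    the plugin's pre-filter.
    """
    weights: dict[str, float] = {}
    for v in g.nodes:
        if g.degree(v) < degree_cutoff:
            weights[v] = 0.0
            continue
        nbhd = g.subgraph([v, *g.neighbors(v)])
        k, core = _highest_k_core(nbhd)
        weights[v] = k * _density(core)
    return weights


def mcode_modules(
    graph: nx.Graph,
    node_score_cutoff: float = 0.2,
    max_depth: int = 5,
    haircut: bool = True,
    fluff: bool = False,
    fluff_threshold: float = 0.2,
    degree_cutoff: int = 2,
) -> list[ModuleResult]:
    """Detect dense modules by the seeded-growth MCODE procedure.

    Stages: (1) weight every vertex by the core-clustering density of its
    closed neighbourhood; (2) in decreasing weight order, grow a complex
    from each unseen vertex by breadth-first search up to ``max_depth``,
    admitting neighbours whose weight >= seed weight * (1 - cutoff); (3)
    drop complexes without a 2-core, then haircut (remove singly-connected
    members, on by default) and/or fluff (add dense-neighbourhood boundary
    vertices, off by default). Edge weights are ignored.

    Modules are scored by density * size of the final member subgraph and
    returned in decreasing score order; apart from fluffed vertices each
    node belongs to at most one module.
    """
    if not 0.0 <= node_score_cutoff <= 1.0:
        raise ValueError("node_score_cutoff must lie in [0, 1]")
    if graph.number_of_nodes() == 0:
        return []

    weights = _vertex_weights(graph, degree_cutoff)
    seen: set[str] = set()
    raw_modules: list[tuple[str, set[str]]] = []

    for seed in sorted(graph.nodes, key=lambda v: (-weights[v], v)):
        if seed in seen or weights[seed] <= 0:
            continue
        threshold = weights[seed] * (1.0 - node_score_cutoff)
        members = {seed}
        frontier = [seed]
        for _ in range(max_depth):
            nxt = []
            for u in frontier:
                for w in graph.neighbors(u):
                    if w not in members and w not in seen and weights[w] >= threshold:
                        members.add(w)
                        nxt.append(w)
            if not nxt:
                break
            frontier = nxt
        seen |= members
        raw_modules.append((seed, members))

    results: list[ModuleResult] = []
    for seed, members in raw_modules:
        sub = graph.subgraph(members)
        # a complex must contain at least a 2-core
        if not any(c >= 2 for c in nx.core_number(sub).values()):
            continue
        if haircut:
            members = {v for v in members if sub.degree(v) >= 2}
            sub = graph.subgraph(members)
        if fluff:
            extra = set()
            for v in list(members):
                for w in graph.neighbors(v):
                    if w in members or w in extra:
                        continue
                    nbhd = graph.subgraph([w, *graph.neighbors(w)])
                    if _density(nbhd) > fluff_threshold:
                        extra.add(w)
            members = members | extra
            sub = graph.subgraph(members)
        if seed not in members or len(members) < 2:
            continue
        results.append(
            ModuleResult(
                seed_node=seed,
                members=set(members),
                module_score=_density(sub) * len(members),
                rank=0,
            )
        )

    results.sort(key=lambda r: (-r.module_score, r.seed_node))
    for rank, r in enumerate(results, start=1):
        r.rank = rank
    return results
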