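"""Shared fixtures and independent oracles for the test suite."""

from collections import defaultdict

import numpy as np
import pytest

from smirnbi.graph_model import BipartiteNetwork, merge_duplicate_edges
from smirnbi.net_io import Direction, RegulationRecord


@pytest.fixture
def toy_t1() -> BipartiteNetwork:
    """Four-edge toy network: s1-m1, s1-m2, s2-m2, s2-m3."""
    records = [
        RegulationRecord("s1", "m1", Direction.UP),
        RegulationRecord("s1", "m2", Direction.UP),
        RegulationRecord("s2", "m2", Direction.DOWN),
        RegulationRecord("s2", "m3", Direction.UP),
    ]
    return merge_duplicate_edges(records)


def spread_resources_literally(A: np.ndarray, query: int, steps: int = 2) -> np.ndarray:
    """Independent diffusion oracle: simulate the spreading loop node by node.

    Places one unit of resource on each neighbour of the query, then
    repeatedly lets every resource-bearing node split its resource equally
    among its own neighbours. Written with explicit dict bookkeeping,
    sharing no code with the matrix implementation.
    """
    n = A.shape[0]
    resources: dict[int, float] = {}
    for j in range(n):
        if A[query, j] > 0:
            resources[j] = resources.get(j, 0.0) + 1.0
    for _ in range(steps):
        nxt: dict[int, float] = defaultdict(float)
        for node, amount in resources.items():
            neighbours = [k for k in range(n) if A[node, k] > 0]
            if not neighbours:
                continue
            share = amount / len(neighbours)
            for k in neighbours:
                nxt[k] += share
        resources = dict(nxt)
    out = np.zeros(n)
    for node, amount in resources.items():
        out[node] = amount
    return out


def random_bipartite(rng: np.random.Generator, max_side: int = 15,
                     p_lo: float = 0.2, p_hi: float = 0.6) -> BipartiteNetwork:
    """Small random bipartite network for oracle comparisons."""
    m = int(rng.integers(2, max_side + 1))
    n = int(rng.integers(2, max_side + 1))
    p = float(rng.uniform(p_lo, p_hi))
    mask = rng.random((m, n)) < p
    edges = {
        (i, j, Direction.UP if rng.random() < 0.5 else Direction.DOWN)
        for i, j in zip(*np.nonzero(mask))
    }
    return BipartiteNetwork(
        molecules=[f"s{i}" for i in range(m)],
        mirnas=[f"m{j}" for j in range(n)],
        edges={(int(i), int(j), d) for i, j, d in edges},
    )
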