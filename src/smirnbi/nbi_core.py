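"""Two-step resource-diffusion scoring on the bipartite network.

The model is the resource-allocation / network-based-inference recommender
applied to the molecule-miRNA graph. For a query node, one unit of resource
is placed on each of its neighbours; every node then splits its resource
equally among its own neighbours (crossing the bipartition), and the
receiving nodes immediately redistribute once more. After the two spreading
steps, the resource landing on each opposite-class node is the association
score between it and the query.

In matrix form, with A the (m+n)-order adjacency and B the row-stochastic
transfer matrix B(i, j) = A(i, j) / sum_l A(i, l), the final resource
matrix is F = A B^2; row i of F holds the scores for query node i. Scores
are conservative: row i of F sums to the degree of node i, because each
normalisation step redistributes but never destroys resource.

Per query, raw scores over the opposite class are min-max standardised to
[0, 1] (known links included, so the top score is typically a known link),
and novel candidates are ranked by standardised score. Direction labels
play no role here: the diffusion is undirected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph_model import BipartiteNetwork, build_adjacency

__all__ = [
    "TransferMatrix",
    "Candidate",
    "ScoreTable",
    "build_transfer_matrix",
    "diffuse",
    "standardize_scores",
    "score_query",
    "score_all_queries",
    "filter_by_threshold",
]


@dataclass(frozen=True)
class TransferMatrix:
    """Row-normalised transfer matrix; zero rows for isolated nodes."""

    B: np.ndarray


@dataclass(frozen=True)
class Candidate:
    candidate_id: str
    raw_score: float
    std_score: float
    known_link: bool
    rank: int  # 1..k over novel candidates; 0 for known links


@dataclass
class ScoreTable:
    """Diffusion scores of one query node over the whole opposite class."""

    query_id: str
    query_class: str  # "molecule" or "mirna"
    candidates: list[Candidate] = field(default_factory=list)
    unpredictable: bool = False  # query had zero degree: no resource to spread
    degenerate: bool = False  # all raw scores equal: standardisation collapsed


def build_transfer_matrix(A: np.ndarray) -> TransferMatrix:
    """B(i, j) = A(i, j) / row-sum; rows of an isolated node stay all-zero.

    A zero row means no resource ever leaves that node, which is exactly the
    behaviour wanted for isolated molecules/miRNAs: their queries come back
    empty instead of dividing by zero.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {A.shape}")
    if (A < 0).any():
        raise ValueError("adjacency entries must be non-negative")
    row_sums = A.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        B = np.where(row_sums > 0, A / row_sums, 0.0)
    return TransferMatrix(B=B)


def diffuse(A: np.ndarray, B: TransferMatrix | np.ndarray) -> np.ndarray:
    """Final resource matrix F = A B^2.

    F[i, :] is the resource distribution reached from query node i after the
    two spreading steps; for a molecule row all mass sits on miRNA columns
    and vice versa (an even number of steps returns to the opposite side of
    the start's neighbours).
    """
    Bm = B.B if isinstance(B, TransferMatrix) else np.asarray(B, dtype=float)
    A = np.asarray(A, dtype=float)
    if A.shape != Bm.shape:
        raise ValueError(f"shape mismatch: A {A.shape} vs B {Bm.shape}")
    return A @ Bm @ Bm


def standardize_scores(raw: np.ndarray) -> tuple[np.ndarray, bool]:
    """Min-max rescale raw scores to [0, 1].

    Returns ``(standardized, degenerate)``. When every raw score is equal
    (including the all-zero case) there is no spread to rescale; all
    standardized scores are set to 0 and the degeneracy flag is raised.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        return raw.copy(), False
    if (raw < 0).any():
        raise ValueError("raw scores must be non-negative")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.zeros_like(raw), True
    return (raw - lo) / (hi - lo), False


def _locate(net: BipartiteNetwork, query_id: str) -> tuple[str, int]:
    if query_id in net.molecules:
        return "molecule", net.molecules.index(query_id)
    if query_id in net.mirnas:
        return "mirna", net.mirnas.index(query_id)
    raise KeyError(f"query {query_id!r} is not a node of the network")


def score_query(net: BipartiteNetwork, F: np.ndarray, query_id: str) -> ScoreTable:
    """Extract, standardise and rank the scores of one query node.

    Known links (existing edges of the query) are flagged and carry rank 0;
    novel candidates get ranks 1..k by decreasing standardized score, ties
    broken by candidate label so output order is deterministic. A
    zero-degree query is flagged ``unpredictable`` and returns no
    candidates: with no topological links there is nothing to diffuse from.
    """
    query_class, idx = _locate(net, query_id)
    m = net.n_molecules
    X = net.incidence()

    if query_class == "molecule":
        raw = np.asarray(F[idx, m:], dtype=float)
        labels = net.mirnas
        known = X[idx, :] > 0
    else:
        raw = np.asarray(F[m + idx, :m], dtype=float)
        labels = net.molecules
        known = X[:, idx] > 0

    if not known.any():
        return ScoreTable(query_id=query_id, query_class=query_class, unpredictable=True)

    std, degenerate = standardize_scores(raw)

    novel = [k for k in range(len(labels)) if not known[k]]
    order = sorted(novel, key=lambda k: (-std[k], labels[k]))
    rank_of = {k: r for r, k in enumerate(order, start=1)}

    candidates = [
        Candidate(
            candidate_id=labels[k],
            raw_score=float(raw[k]),
            std_score=float(std[k]),
            known_link=bool(known[k]),
            rank=rank_of.get(k, 0),
        )
        for k in range(len(labels))
    ]
    return ScoreTable(
        query_id=query_id,
        query_class=query_class,
        candidates=candidates,
        degenerate=degenerate,
    )


def score_all_queries(net: BipartiteNetwork, query_class: str = "molecule") -> list[ScoreTable]:
    """Score every node of one class in a single diffusion pass."""
    if query_class not in ("molecule", "mirna"):
        raise ValueError(f"unknown query class: {query_class!r}")
    A = build_adjacency(net)
    F = diffuse(A, build_transfer_matrix(A))
    labels = net.molecules if query_class == "molecule" else net.mirnas
    return [score_query(net, F, label) for label in labels]


def filter_by_threshold(
    tables: list[ScoreTable], threshold: float = 0.1
) -> list[tuple[str, str, float]]:
    """Novel predictions at or above a standardized-score threshold.

    Returns ``(query_id, candidate_id, std_score)`` triples for every
    candidate that is not a known link and scores >= threshold. The default
    0.1 is the operating point used to call a candidate a novel regulation.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    out: list[tuple[str, str, float]] = []
    for table in tables:
        for c in table.candidates:
            if not c.known_link and c.std_score >= threshold:
                out.append((table.query_id, c.candidate_id, c.std_score))
    return out
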