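"""Repeated k-fold edge-holdout cross-validation with ROC/AUC.

Protocol: the known edges are shuffled and split into k near-equal folds;
each fold in turn is hidden, the diffusion model is refit on the remaining
edges (same node sets), and the hidden edges are scored against every pair
absent from the *full* network. AUC summarises how highly the hidden true
edges rank among those never-observed pairs. The whole split-and-score
cycle is repeated (default 100 times of 10-fold) to average out the
sampling noise of the fold assignment.

Both prediction directions are evaluated: ranking candidate miRNAs for a
molecule reads molecule rows of F, ranking candidate molecules for a miRNA
reads miRNA rows; the two give different scores because the transfer matrix
is row- not symmetrically-normalised.

Raw diffusion scores are used for AUC. Per-query min-max standardisation is
rank-preserving within a query but not across the pooled queries of a fold,
so standardising first would silently change the pooled statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve

from .graph_model import BipartiteNetwork, build_adjacency
from .nbi_core import build_transfer_matrix, diffuse

logger = logging.getLogger(__name__)

__all__ = ["CVConfig", "CVResult", "split_edges_kfold", "run_cv", "roc_auc"]

DIRECTIONS = ("mirna_for_molecule", "molecule_for_mirna")


@dataclass(frozen=True)
class CVConfig:
    folds: int = 10
    repeats: int = 100
    seed: int = 0
    direction: str = "both"  # mirna_for_molecule | molecule_for_mirna | both
    pooling: str = "pooled"  # pooled | per_query

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.direction not in (*DIRECTIONS, "both"):
            raise ValueError(f"unknown direction: {self.direction!r}")
        if self.pooling not in ("pooled", "per_query"):
            raise ValueError(f"unknown pooling: {self.pooling!r}")

    @property
    def directions(self) -> tuple[str, ...]:
        return DIRECTIONS if self.direction == "both" else (self.direction,)


@dataclass
class CVResult:
    """Per-run AUCs plus per-direction aggregates and pooled ROC curves."""

    per_run_auc: list[tuple[int, int, str, float]] = field(default_factory=list)
    mean_auc: dict[str, float] = field(default_factory=dict)
    sd_auc: dict[str, float] = field(default_factory=dict)
    roc_points: dict[str, list[tuple[float, float]]] = field(default_factory=dict)

    def aucs(self, direction: str) -> list[float]:
        return [a for _, _, d, a in self.per_run_auc if d == direction]


def roc_auc(
    pos_scores: np.ndarray, neg_scores: np.ndarray
) -> tuple[float, list[tuple[float, float]]]:
    """AUC with the tie convention of the Mann-Whitney statistic.

    AUC = (#{pos > neg} + 0.5 * #{pos = neg}) / (|pos| * |neg|), computed by
    rank sums so large lists stay O(N log N). Also returns the vertices of
    the empirical ROC staircase.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")

    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    auc = (ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size)

    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    fpr, tpr, _ = roc_curve(y, np.concatenate([pos, neg]))
    return float(auc), list(zip(fpr.tolist(), tpr.tolist()))


def split_edges_kfold(
    net: BipartiteNetwork, folds: int, rng_seed: int
) -> list[np.ndarray]:
    """Shuffle edge indices and cut into ``folds`` parts of near-equal size.

    Partitions are disjoint, cover every edge, and differ in size by at most
    one; the shuffle is driven solely by ``rng_seed``. Indices refer to the
    sorted ``net.edge_pairs()`` order.
    """
    n_edges = net.n_edges
    if n_edges < folds:
        raise ValueError(f"need at least {folds} edges, network has {n_edges}")
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(n_edges)
    return [np.sort(part) for part in np.array_split(perm, folds)]


def _fold_scores(
    net: BipartiteNetwork,
    test_pairs: list[tuple[int, int]],
    neg_pairs: tuple[np.ndarray, np.ndarray],
    directions: tuple[str, ...],
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]:
    """Refit on training edges, return (pos, neg, pos_query, neg_query) scores per direction."""
    all_pairs = net.edge_pairs()
    train = net.subnetwork(set(all_pairs) - set(test_pairs))
    A = build_adjacency(train)
    F = diffuse(A, build_transfer_matrix(A))

    m = net.n_molecules
    pos_i = np.array([i for i, _ in test_pairs], dtype=int)
    pos_j = np.array([j for _, j in test_pairs], dtype=int)
    neg_i, neg_j = neg_pairs

    out = {}
    for direction in directions:
        if direction == "mirna_for_molecule":
            pos = F[pos_i, m + pos_j]
            neg = F[neg_i, m + neg_j]
            pq, nq = pos_i, neg_i
        else:
            pos = F[m + pos_j, pos_i]
            neg = F[m + neg_j, neg_i]
            pq, nq = pos_j, neg_j
        out[direction] = (pos, neg, pq, nq)
    return out


def _per_query_auc(pos, neg, pos_q, neg_q) -> float:
    """Mean AUC over query nodes holding at least one test positive.

    Queries with no negatives (all their pairs are known edges) contribute
    nothing; a fold where no query is scorable yields NaN and is ignored by
    the NaN-aware aggregation.
    """
    vals = []
    for q in np.unique(pos_q):
        p = pos[pos_q == q]
        n = neg[neg_q == q]
        if p.size and n.size:
            vals.append(roc_auc(p, n)[0])
    return float(np.mean(vals)) if vals else float("nan")


def run_cv(net: BipartiteNetwork, cfg: CVConfig) -> CVResult:
    """Run the repeated k-fold edge-holdout protocol on a network.

    Positives of a fold are its held-out edges; negatives are all pairs
    absent from the full network (exhaustive, not sampled, so the AUC is
    deterministic given the fold split). Training edges are never scored. A
    test edge whose query lost all its training links scores 0 — the
    diffusion has no path to it — and stays in the positive pool; dropping
    it would flatter the model.

    Each repeat draws its fold split from an independent RNG stream derived
    from ``(cfg.seed, repeat)``, so any single repeat is reproducible on its
    own.
    """
    if net.n_edges < cfg.folds:
        raise ValueError("network has fewer edges than folds")

    X = net.incidence()
    neg_i, neg_j = np.nonzero(X == 0)
    if neg_i.size == 0:
        raise ValueError("complete bipartite network has no negatives to rank against")

    all_pairs = net.edge_pairs()
    result = CVResult()
    pooled: dict[str, tuple[list[np.ndarray], list[np.ndarray]]] = {
        d: ([], []) for d in cfg.directions
    }

    for repeat in range(cfg.repeats):
        ss = np.random.SeedSequence([cfg.seed, repeat])
        repeat_seed = int(ss.generate_state(1)[0] % (2**31))
        folds = split_edges_kfold(net, cfg.folds, repeat_seed)
        for fold_idx, test_idx in enumerate(folds):
            test_pairs = [all_pairs[t] for t in test_idx]
            scores = _fold_scores(net, test_pairs, (neg_i, neg_j), cfg.directions)
            for direction, (pos, neg, pq, nq) in scores.items():
                n_dead = int((pos == 0).sum())
                if n_dead:
                    logger.debug(
                        "repeat %d fold %d %s: %d test positives scored 0 "
                        "(query isolated in training)",
                        repeat, fold_idx, direction, n_dead,
                    )
                if cfg.pooling == "pooled":
                    auc, _ = roc_auc(pos, neg)
                else:
                    auc = _per_query_auc(pos, neg, pq, nq)
                result.per_run_auc.append((repeat, fold_idx, direction, auc))
                pooled[direction][0].append(pos)
                pooled[direction][1].append(neg)

    for direction in cfg.directions:
        aucs = np.array(result.aucs(direction))
        result.mean_auc[direction] = float(np.nanmean(aucs))
        valid = aucs[~np.isnan(aucs)]
        result.sd_auc[direction] = float(valid.std(ddof=1)) if valid.size > 1 else 0.0
        all_pos = np.concatenate(pooled[direction][0])
        all_neg = np.concatenate(pooled[direction][1])
        _, points = roc_auc(all_pos, all_neg)
        result.roc_points[direction] = points

    return result
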