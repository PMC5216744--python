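"""miRNA-target-gene layer: evidence merging, hubs, subnetworks, enrichment.

Curated target tables carry an evidence class per record: ``strong``
(low-throughput validation — reporter assay, western blot, qPCR) or
``weak`` (high-throughput — microarray, CLIP, sequencing). After merging,
each (miRNA, gene) pair appears once, labelled strong if any supporting
record was strong. Gene degree (number of distinct targeting miRNAs) drives
hub-gene selection, and the case-study style subnetwork extraction prunes a
pair set down to its densely connected kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .graph_model import BipartiteNetwork
from .net_io import Evidence, TargetRecord

__all__ = [
    "MiRGeneNet",
    "merge_evidence",
    "hub_genes",
    "common_regulated_mirnas",
    "extract_subnetwork",
    "enrich_gene_sets",
]

Pair = tuple[str, str, Evidence]


@dataclass
class MiRGeneNet:
    """Deduplicated miRNA-gene evidence network (strong dominates weak)."""

    pairs: set[Pair] = field(default_factory=set)

    def __post_init__(self) -> None:
        keys = {(m, g) for m, g, _ in self.pairs}
        if len(keys) != len(self.pairs):
            raise ValueError("more than one evidence label for some (miRNA, gene) pair")

    @property
    def mirnas(self) -> set[str]:
        return {m for m, _, _ in self.pairs}

    @property
    def genes(self) -> set[str]:
        return {g for _, g, _ in self.pairs}

    @property
    def gene_degree(self) -> dict[str, int]:
        deg: dict[str, int] = {}
        for _, g, _ in self.pairs:
            deg[g] = deg.get(g, 0) + 1
        return deg


def merge_evidence(records: Sequence[TargetRecord]) -> MiRGeneNet:
    """Collapse duplicate target records; strong evidence wins per pair."""
    best: dict[tuple[str, str], Evidence] = {}
    for rec in records:
        key = (rec.mirna_id, rec.gene_id)
        if rec.evidence is Evidence.STRONG or key not in best:
            best[key] = rec.evidence
    return MiRGeneNet(pairs={(m, g, e) for (m, g), e in best.items()})


def hub_genes(net: MiRGeneNet, k: int, evidence_filter: str = "all") -> list[str]:
    """Top-k genes by number of distinct targeting miRNAs.

    ``strong_only`` restricts degree counting to strongly validated pairs.
    Ties broken lexicographically.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if evidence_filter not in ("all", "strong_only"):
        raise ValueError(f"unknown evidence filter: {evidence_filter!r}")
    deg: dict[str, int] = {}
    for _, g, e in net.pairs:
        if evidence_filter == "strong_only" and e is not Evidence.STRONG:
            continue
        deg[g] = deg.get(g, 0) + 1
    return sorted(deg, key=lambda g: (-deg[g], g))[:k]


def common_regulated_mirnas(
    net: BipartiteNetwork, molecule_subset: Iterable[str], min_molecules: int
) -> list[str]:
    """miRNAs regulated (any direction) by >= min_molecules of the subset.

    Used for questions like "which miRNAs do at least three of these
    natural products co-regulate". Returned sorted by label.
    """
    subset = set(molecule_subset)
    indices = {net.molecule_index(m) for m in subset}  # raises on unknown label
    counts: dict[int, int] = {}
    for i, j, _ in net.edges:
        if i in indices:
            counts[j] = counts.get(j, 0) + 1
    return sorted(net.mirnas[j] for j, c in counts.items() if c >= min_molecules)


def extract_subnetwork(
    net: MiRGeneNet,
    mirna_subset: Iterable[str] | None = None,
    min_pairs_per_node: int = 2,
    hub_targeting_min: int | None = None,
    hubs: Iterable[str] | None = None,
    min_pairs_mirna: int | None = None,
    min_pairs_gene: int | None = None,
    single_pass: bool = False,
) -> tuple[set[str], set[str], set[Pair]]:
    """Extract a densely connected miRNA-gene subnetwork.

    Pairs are first restricted to ``mirna_subset`` (all miRNAs if None) and,
    when ``hubs`` is given, to miRNAs targeting at least ``hub_targeting_min``
    of the hub genes. Then miRNAs and genes with fewer than
    ``min_pairs_per_node`` incident pairs are dropped, by default iterating
    to a fixed point: a removal can push a surviving node below threshold,
    so a single pass does not guarantee the output honours its own
    threshold. ``single_pass=True`` gives the one-shot variant;
    ``min_pairs_mirna``/``min_pairs_gene`` override the threshold per node
    class.

    Returns ``(miRNA set, gene set, pair set)``. Idempotent: re-extracting
    from the output with the same thresholds changes nothing.
    """
    thr_mirna = min_pairs_mirna if min_pairs_mirna is not None else min_pairs_per_node
    thr_gene = min_pairs_gene if min_pairs_gene is not None else min_pairs_per_node
    if thr_mirna < 1 or thr_gene < 1:
        raise ValueError("pair thresholds must be >= 1")
    if (hubs is None) != (hub_targeting_min is None):
        raise ValueError("hubs and hub_targeting_min must be given together")

    pairs = set(net.pairs)
    if mirna_subset is not None:
        keep = set(mirna_subset)
        pairs = {p for p in pairs if p[0] in keep}

    if hubs is not None:
        hub_set = set(hubs)
        hits: dict[str, set[str]] = {}
        for m, g, _ in pairs:
            if g in hub_set:
                hits.setdefault(m, set()).add(g)
        keep_mirnas = {m for m, hs in hits.items() if len(hs) >= hub_targeting_min}
        pairs = {p for p in pairs if p[0] in keep_mirnas}

    while True:
        mir_deg: dict[str, int] = {}
        gene_deg: dict[str, int] = {}
        for m, g, _ in pairs:
            mir_deg[m] = mir_deg.get(m, 0) + 1
            gene_deg[g] = gene_deg.get(g, 0) + 1
        pruned = {
            (m, g, e)
            for m, g, e in pairs
            if mir_deg[m] >= thr_mirna and gene_deg[g] >= thr_gene
        }
        if pruned == pairs or single_pass:
            pairs = pruned
            break
        pairs = pruned

    return ({m for m, _, _ in pairs}, {g for _, g, _ in pairs}, pairs)


def enrich_gene_sets(
    genes: Iterable[str],
    universe: Iterable[str],
    sets: dict[str, set[str]],
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list against GMT sets.

    For each set, the upper-tail probability of observing at least the seen
    overlap when drawing |genes| from the universe, where the set is first
    intersected with the universe. P-values are Benjamini-Hochberg adjusted
    across sets. Returns a DataFrame (set, set_size, overlap, p, p_adj)
    sorted by p then set name.
    """
    if fdr_method != "bh":
        raise ValueError(f"unsupported FDR method: {fdr_method!r}")
    genes = set(genes)
    universe = set(universe)
    stray = genes - universe
    if stray:
        raise ValueError(f"genes not in universe: {sorted(stray)}")
    if not sets:
        raise ValueError("no gene sets supplied")

    rows = []
    for name in sorted(sets):
        members = sets[name] & universe
        overlap = len(genes & members)
        # P(X >= overlap), X ~ Hypergeom(N=|universe|, K=|set|, n=|genes|)
        p = float(hypergeom.sf(overlap - 1, len(universe), len(members), len(genes)))
        rows.append((name, len(members), overlap, min(p, 1.0)))

    df = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"])
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    return df.sort_values(["p", "set"], ignore_index=True)
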