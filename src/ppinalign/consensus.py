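"""Steps 4-5: merge cluster alignments into a local alignment, then extend
it iteratively into a consistent global alignment.

The selected cluster-pair alignments may be mutually inconsistent (two of
them can map the same protein differently). Each one is viewed as a
weighted hyperarc from its domain to its image in the disjoint union of
the two node sets, and the weighted bipartite hypergraph assignment
problem is solved greedily by decreasing weight: pairs from heavier arcs
win, later conflicting pairs are dropped, and the result is an injective
partial map — the local alignment. The extension stage removes already
aligned nodes, re-scores the restricted cluster alignments, re-runs the
cluster matching and assignment on what is left, and repeats until no
positive-score alignment touches an unaligned node.

The exact hypergraph assignment problem is NP-hard; the greedy
decreasing-weight strategy keeps the "best-scored first" semantics and is
cross-checked against an exhaustive solver on small instances in the test
suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

from .cluster_align import ClusterAlignment, align_cluster_pair
from .clustering import DistanceOracle, build_clustering, similarity_matrix
from .io import BitScoreTable, GlobalAlignment, Network, normalize_bit_scores
from .matching import ClusteringMatch, match_clusterings, score_alignment

logger = logging.getLogger("ppinalign")


@dataclass(frozen=True)
class Hyperarc:
    """A cluster alignment seen as a weighted arc from its (still
    unaligned) domain to its (still unaligned) image."""

    source_center: str
    target_center: str
    weight: float
    payload: Tuple[Tuple[str, str], ...]

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("hyperarc weight must be positive")
        tgts = [w for _, w in self.payload]
        if len(tgts) != len(set(tgts)):
            raise ValueError("hyperarc payload must be injective")


def select_best_scored(selected: ClusteringMatch,
                       scores: Dict[Tuple[str, str], float]) -> List[ClusterAlignment]:
    """Greedy best-scored subset R of the matched cluster alignments.

    Repeatedly add the highest-scoring mapping whose source center is not
    yet covered by the domains already in R, until every node occurring in
    some domain is covered. Ties break lexicographically on the center pair.
    A picked center counts as covered even if its restricted domain no
    longer contains it (this can happen during the global extension), which
    guarantees termination.
    """
    cands = sorted(selected.mappings.values(),
                   key=lambda a: (-scores[a.key], a.source_center, a.target_center))
    universe = {v for a in cands for v in a.domain}
    covered: set = set()
    picked_centers: set = set()
    chosen: List[ClusterAlignment] = []
    while not universe <= covered:
        pick = next((a for a in cands
                     if a.source_center not in covered
                     and a.source_center not in picked_centers), None)
        if pick is None:
            break
        chosen.append(pick)
        covered.update(pick.domain)
        picked_centers.add(pick.source_center)
    return chosen


def hypergraph_assign(arcs: Iterable[Hyperarc]) -> Dict[str, str]:
    """Greedy solution of the weighted bipartite hypergraph assignment.

    Arcs are processed in decreasing weight (ties lexicographic on the
    center pair); every payload pair whose source and target are both still
    unassigned is accepted, so the result is injective.
    """
    order = sorted(arcs, key=lambda a: (-a.weight, a.source_center, a.target_center))
    assigned: Dict[str, str] = {}
    used_targets: set = set()
    for arc in order:
        for v, w in sorted(arc.payload):
            if v not in assigned and w not in used_targets:
                assigned[v] = w
                used_targets.add(w)
    return assigned


def extend_to_global(local: GlobalAlignment,
                     all_alignments: Sequence[ClusterAlignment],
                     B: BitScoreTable,
                     max_rounds: int | None = None) -> GlobalAlignment:
    """Iteratively extend the local alignment to a global one.

    Each round restricts every cluster alignment to still-unaligned nodes
    (both coordinates), recomputes its score, re-runs the cluster matching
    and the best-scored selection on the positive-score survivors, solves
    the hypergraph assignment on the unaligned nodes, and merges the new
    pairs (tagged ``extension-k``). Stops when no positive-score alignment
    touches an unaligned node. A safety cap (one round per source node)
    turns silent non-progress into an error.
    """
    mapping = dict(local.mapping)
    stage = dict(local.stage)
    cap = max_rounds if max_rounds is not None else max(
        1, len({v for a in all_alignments for v in a.domain}))
    for rnd in range(1, cap + 1):
        aligned_src = set(mapping)
        aligned_tgt = set(mapping.values())
        restricted = []
        for a in all_alignments:
            kept = [(v, w) for v, w in a.pairs
                    if v not in aligned_src and w not in aligned_tgt]
            if kept:
                restricted.append(ClusterAlignment(a.source_center, a.target_center, kept))
        if not restricted:
            break
        maxdom = max(len(a) for a in restricted)
        scores = {a.key: score_alignment(a, B, maxdom) for a in restricted}
        cmatch = match_clusterings(restricted, scores)
        best = select_best_scored(cmatch, scores)
        arcs = [Hyperarc(a.source_center, a.target_center, scores[a.key],
                         tuple(a.pairs)) for a in best]
        new_pairs = hypergraph_assign(arcs)
        added = 0
        for v, w in sorted(new_pairs.items()):
            if v not in mapping and w not in aligned_tgt:
                mapping[v] = w
                aligned_tgt.add(w)
                stage[v] = f"extension-{rnd}"
                added += 1
        if added == 0:
            break
        logger.debug("extension round %d: %d new pair(s)", rnd, added)
    else:
        raise RuntimeError("extension did not terminate within the round cap")
    return GlobalAlignment(mapping, stage, local.source_name, local.target_name)


@dataclass
class AlignmentResult:
    """Output bundle of the full pipeline."""

    global_alignment: GlobalAlignment
    local_alignment: GlobalAlignment
    summary: Dict[str, float]
    n_cluster_alignments: int = 0


def _cross_center_pairs(b12: BitScoreTable, v1: set, v2: set) -> List[Tuple[str, str]]:
    """All (u in G, u' in G') with positive cross bit score, from the sparse
    table; both orientations are candidates when the id sets overlap."""
    pairs = set()
    for (p, q), raw in b12.entries.items():
        if raw <= 0:
            continue
        if p in v1 and q in v2:
            pairs.add((p, q))
        if q in v1 and p in v2:
            pairs.add((q, p))
    return sorted(pairs)


def align(net1: Network, net2: Network, b11: BitScoreTable, b22: BitScoreTable,
          b12: BitScoreTable) -> AlignmentResult:
    """Run the full pipeline and return global + local alignments.

    The source is always the network with fewer nodes (inputs are swapped
    if needed). The summary reports the edge correctness of the global
    alignment and the mean cross bit score over matched pairs as the
    network-pair similarity record.
    """
    from .metrics import edge_correctness  # local import: metrics depends on io only

    if net1.n_nodes == 0 or net2.n_nodes == 0:
        raise ValueError("both networks must be non-empty")
    if net1.n_nodes > net2.n_nodes:
        net1, net2 = net2, net1
        b11, b22 = b22, b11

    b11 = b11 if b11.normalizer else normalize_bit_scores(b11)
    b22 = b22 if b22.normalizer else normalize_bit_scores(b22)
    b12 = b12 if b12.normalizer else normalize_bit_scores(b12)

    center_pairs = _cross_center_pairs(b12, net1.node_set, net2.node_set)
    empty = GlobalAlignment({}, {}, net1.name, net2.name)
    if not center_pairs:
        logger.warning("no positive cross bit score between %s and %s; empty alignment",
                       net1.name, net2.name)
        return AlignmentResult(empty, empty, {"n_aligned": 0.0}, 0)

    # Step 1: overlapping clusterings
    d1, d2 = DistanceOracle(net1), DistanceOracle(net2)
    c1 = build_clustering(net1, similarity_matrix(net1, b11, d1))
    c2 = build_clustering(net2, similarity_matrix(net2, b22, d2))

    # Step 2: cluster-pair alignments for every pair with B(u, u') > 0
    alignments: List[ClusterAlignment] = []
    for u, u2 in center_pairs:
        a = align_cluster_pair(c1[u], c2[u2], net1, net2, b12)
        if a is not None:
            alignments.append(a)
    if not alignments:
        return AlignmentResult(empty, empty, {"n_aligned": 0.0}, 0)

    # Step 3: score and match the clusterings
    maxdom = max(len(a) for a in alignments)
    scores = {a.key: score_alignment(a, b12, maxdom) for a in alignments}
    cmatch = match_clusterings(alignments, scores)

    # Step 4: best-scored subset, hypergraph assignment -> local alignment
    best = select_best_scored(cmatch, scores)
    arcs = [Hyperarc(a.source_center, a.target_center, scores[a.key],
                     tuple(a.pairs)) for a in best]
    local_map = hypergraph_assign(arcs)
    local = GlobalAlignment(dict(local_map), {v: "local" for v in local_map},
                            net1.name, net2.name)

    # Step 5: iterative extension to a global alignment
    glob = extend_to_global(local, alignments, b12)

    summary: Dict[str, float] = {"n_aligned": float(len(glob))}
    if net1.n_edges and net2.n_edges:
        summary["ec"] = edge_correctness(glob, net1, net2)
    if len(glob):
        summary["mean_matched_bitscore"] = (
            sum(b12.b(v, w) for v, w in glob.mapping.items()) / len(glob))
    return AlignmentResult(glob, local, summary, len(alignments))
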