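"""Step 3: score cluster-pair alignments and match the two clusterings.

Each cluster-pair alignment eta gets the score

    Score(eta) = mean_{v in Dom eta} B(v, eta(v))  +  |Dom eta| / maxdom,

where maxdom is the largest domain among all computed alignments, so the
score rewards both sequence similarity of the matched proteins and the
number of proteins matched. A maximum-weight bipartite matching between
the clusters of the two networks (edges = alignable cluster pairs,
weights = scores) then selects at most one partner per cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment

from .cluster_align import ClusterAlignment
from .io import BitScoreTable


def score_alignment(a: ClusterAlignment, B: BitScoreTable, maxdom: int) -> float:
    """Score(eta) in (0, 2]; the size term is 1 for the largest domain."""
    if len(a) == 0:
        raise ValueError("cannot score an alignment with an empty domain")
    if maxdom < len(a):
        raise ValueError("maxdom smaller than this alignment's domain")
    avg_b = sum(B.b(v, w) for v, w in a.pairs) / len(a)
    return avg_b + len(a) / maxdom


@dataclass
class ClusteringMatch:
    """The one-to-one cluster matching selected in Step 3."""

    pairs: List[Tuple[str, str]] = field(default_factory=list)
    mappings: Dict[Tuple[str, str], ClusterAlignment] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)


def match_clusterings(alignments: Iterable[ClusterAlignment],
                      scores: Dict[Tuple[str, str], float]) -> ClusteringMatch:
    """Maximum-total-score one-to-one matching between the two clusterings.

    ``alignments`` are the edges of the bipartite graph (cluster of G,
    cluster of G'); only alignments with a positive score participate.
    Node lists are sorted so the solver's tie-breaking is reproducible.
    """
    by_key = {}
    for a in alignments:
        if scores.get(a.key, 0.0) > 0:
            by_key[a.key] = a
    if not by_key:
        return ClusteringMatch()
    sources = sorted({u for u, _ in by_key})
    targets = sorted({w for _, w in by_key})
    weight = np.zeros((len(sources), len(targets)))
    si = {u: i for i, u in enumerate(sources)}
    ti = {w: j for j, w in enumerate(targets)}
    for (u, w), a in by_key.items():
        weight[si[u], ti[w]] = scores[(u, w)]
    ri, ci = linear_sum_assignment(weight, maximize=True)
    match = ClusteringMatch()
    for i, j in zip(ri, ci):
        key = (sources[i], targets[j])
        if key in by_key:  # skip zero-weight filler assignments
            match.pairs.append(key)
            match.mappings[key] = by_key[key]
    match.pairs.sort()
    return match
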