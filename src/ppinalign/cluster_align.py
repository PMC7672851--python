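"""Step 2: align one cluster of G with one cluster of G' center-outward.

The centers are matched first; then, repeatedly, the k-th matched pair
(v0, v0') is expanded by solving a minimum-cost assignment between the
still-unmatched cluster members adjacent to v0 and those adjacent to v0',
under the cost

    F(v, v') = |deg(v) - deg(v')| - B(v, v') + 1

with degrees taken in the full networks. The per-iteration matching is
appended to the match list in decreasing order of F (ties broken
lexicographically), so the expansion front stays layered by distance from
the centers. The result is a partial injective map between the clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment

from .clustering import Cluster
from .io import BitScoreTable, Network


def neighbor_cost(v: str, v2: str, g: Network, g2: Network, B: BitScoreTable) -> float:
    """F(v, v') = |deg(v) - deg(v')| - B(v, v') + 1; non-negative since B <= 1."""
    return abs(g.degree(v) - g2.degree(v2)) - B.b(v, v2) + 1.0


def min_cost_matching(rows: Sequence[str], cols: Sequence[str],
                      cost: np.ndarray) -> List[Tuple[str, str]]:
    """Minimum-total-cost assignment of size min(|rows|, |cols|).

    ``cost[i, j]`` is the cost of matching rows[i] with cols[j]; rectangular
    inputs are supported. Callers pass lexicographically sorted rows/cols so
    the solver's tie-breaking is reproducible.
    """
    if not rows or not cols:
        return []
    ri, ci = linear_sum_assignment(np.asarray(cost, dtype=float))
    return [(rows[i], cols[j]) for i, j in zip(ri, ci)]


@dataclass
class ClusterAlignment:
    """A center-anchored partial injective map eta: C_u -> C_u'.

    ``pairs`` is the ordered match list L (first element the center pair in
    a freshly computed alignment; restrictions taken during the global
    extension may drop it).
    """

    source_center: str
    target_center: str
    pairs: List[Tuple[str, str]] = field(default_factory=list)

    @property
    def eta(self) -> Dict[str, str]:
        return dict(self.pairs)

    @property
    def domain(self) -> Tuple[str, ...]:
        return tuple(v for v, _ in self.pairs)

    @property
    def image(self) -> Tuple[str, ...]:
        return tuple(w for _, w in self.pairs)

    @property
    def key(self) -> Tuple[str, str]:
        return (self.source_center, self.target_center)

    def __len__(self) -> int:
        return len(self.pairs)

    def restricted(self, free_sources, free_targets) -> "ClusterAlignment":
        """Copy with only the pairs whose both endpoints are still free."""
        kept = [(v, w) for v, w in self.pairs
                if v in free_sources and w in free_targets]
        return ClusterAlignment(self.source_center, self.target_center, kept)


def align_cluster_pair(cu: Cluster, cu2: Cluster, g: Network, g2: Network,
                       B: BitScoreTable,
                       frontier_order: str = "decreasing") -> ClusterAlignment | None:
    """Align ``cu`` (in g) with ``cu2`` (in g2) center-outward.

    Returns None (skip signal) when the centers have no positive cross bit
    score — such pairs are excluded from the candidate set.
    ``frontier_order`` controls how a layer's matches join the expansion
    queue: ``decreasing`` (default) expands the largest-F pair of a layer
    first, ``increasing`` the smallest; the queue already layers the
    expansion by distance from the centers, so the switch only permutes
    pairs within one layer.
    """
    if frontier_order not in ("decreasing", "increasing"):
        raise ValueError(f"unknown frontier order {frontier_order!r}")
    sign = -1.0 if frontier_order == "decreasing" else 1.0
    u, u2 = cu.center, cu2.center
    if B.b(u, u2) <= 0:
        return None
    L: List[Tuple[str, str]] = [(u, u2)]
    matched_src = {u}
    matched_tgt = {u2}
    k = 0
    while k < len(L):
        v0, v02 = L[k]
        rows = sorted((cu.members - matched_src) & g.neighbors(v0))
        cols = sorted((cu2.members - matched_tgt) & g2.neighbors(v02))
        if rows and cols:
            cost = np.empty((len(rows), len(cols)))
            for i, v in enumerate(rows):
                for j, w in enumerate(cols):
                    cost[i, j] = neighbor_cost(v, w, g, g2, B)
            matches = min_cost_matching(rows, cols, cost)
            # ties break lexicographically by (src, tgt)
            matches.sort(key=lambda p: (sign * cost[rows.index(p[0]), cols.index(p[1])],
                                        p[0], p[1]))
            for v, w in matches:
                L.append((v, w))
                matched_src.add(v)
                matched_tgt.add(w)
        k += 1
    return ClusterAlignment(u, u2, L)
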