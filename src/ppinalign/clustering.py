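"""Step 1: node similarity, quartile threshold and overlapping clustering.

The similarity between two proteins u, v of one network combines their
normalized sequence bit score with their hop distance in the graph:

    s(u, v) = 0                                    if u, v disconnected
    s(u, v) = ( B(u,v) + (D+1-d(u,v)) / (D+1) ) / 2   otherwise,

where d is the shortest-path hop distance and D the diameter (maximum
finite distance). A cluster is seeded at every node u and contains the
nodes v with s(u, v) strictly above the third quartile alpha of the
similarity distribution over all unordered distinct node pairs, so at most
25% of pairs exceed the threshold and the clustering has exactly |V|
clusters, one per node.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Tuple

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .io import BitScoreTable, Network


class DistanceOracle:
    """All-pairs hop distances within components, plus the diameter.

    Unreachable pairs report ``math.inf``; the diameter is the maximum
    finite distance (0 for edgeless graphs).
    """

    def __init__(self, g: Network) -> None:
        self.nodes = g.nodes
        self.index = {u: i for i, u in enumerate(self.nodes)}
        n = len(self.nodes)
        rows, cols = [], []
        for u, v in g.edges:
            i, j = self.index[u], self.index[v]
            rows.extend((i, j))
            cols.extend((j, i))
        adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        self.matrix = shortest_path(adj, method="D", unweighted=True)
        finite = self.matrix[np.isfinite(self.matrix)]
        self.diameter = float(finite.max()) if finite.size else 0.0

    def d(self, u: str, v: str) -> float:
        return float(self.matrix[self.index[u], self.index[v]])


def distances(g: Network) -> DistanceOracle:
    """Hop-distance oracle for every pair of nodes of ``g``."""
    return DistanceOracle(g)


def node_similarity(u: str, v: str, B: BitScoreTable, dist: DistanceOracle) -> float:
    """The Step-1 similarity of two nodes of one network; 0 if disconnected."""
    d = dist.d(u, v)
    if math.isinf(d):
        return 0.0
    D = dist.diameter
    return (B.b(u, v) + (D + 1 - d) / (D + 1)) / 2


def quartile_threshold(values: Iterable[float]) -> float:
    """Third quartile of the similarity values, by linear interpolation
    between the closest order statistics; at most 25% of the values exceed
    the returned alpha."""
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                     dtype=float)
    if arr.size == 0:
        raise ValueError("cannot take a quartile of an empty collection")
    return float(np.quantile(arr, 0.75, method="linear"))


@dataclass(frozen=True)
class Cluster:
    center: str
    members: FrozenSet[str]

    def __post_init__(self) -> None:
        if self.center not in self.members:
            raise ValueError("cluster center must belong to its member set")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class Clustering:
    """One cluster per node of the network."""

    network: str
    clusters: Dict[str, Cluster] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.clusters)

    def __getitem__(self, center: str) -> Cluster:
        return self.clusters[center]


class SimilarityMatrix:
    """Dense s(u, v) values over one network plus the threshold alpha."""

    def __init__(self, nodes: Tuple[str, ...], values: np.ndarray, alpha: float) -> None:
        self.nodes = nodes
        self.index = {u: i for i, u in enumerate(nodes)}
        self.values = values
        self.alpha = alpha

    def s(self, u: str, v: str) -> float:
        return float(self.values[self.index[u], self.index[v]])

    def pair_values(self) -> np.ndarray:
        """s over all unordered distinct node pairs (the alpha population)."""
        iu = np.triu_indices(len(self.nodes), k=1)
        return self.values[iu]


def similarity_matrix(g: Network, B: BitScoreTable,
                      dist: DistanceOracle | None = None) -> SimilarityMatrix:
    """Compute s(u, v) for every node pair of ``g`` and the threshold alpha.

    alpha is the third quartile over all unordered DISTINCT pairs
    (self-pairs excluded, disconnected pairs included with s = 0).
    """
    dist = dist if dist is not None else DistanceOracle(g)
    nodes = dist.nodes
    n = len(nodes)
    bmat = np.zeros((n, n))
    idx = dist.index
    for (u, v), raw in B.entries.items():
        i = idx.get(u)
        j = idx.get(v)
        if i is None or j is None:
            continue
        val = raw / B.normalizer if B.normalizer else 0.0
        bmat[i, j] = val
        bmat[j, i] = val
    D = dist.diameter
    with np.errstate(invalid="ignore"):
        s = (bmat + (D + 1 - dist.matrix) / (D + 1)) / 2
    s[~np.isfinite(dist.matrix)] = 0.0
    sim = SimilarityMatrix(nodes, s, 0.0)
    sim.alpha = quartile_threshold(sim.pair_values())
    return sim


def build_clustering(g: Network, sim: SimilarityMatrix) -> Clustering:
    """One cluster per node: members are the nodes with s(u, v) > alpha.

    The center is force-included even when s(u, u) <= alpha, because every
    cluster-pair alignment is seeded at the centers.
    """
    clustering = Clustering(network=g.name)
    above = sim.values > sim.alpha
    for u in g.nodes:
        i = sim.index[u]
        members = {sim.nodes[j] for j in np.nonzero(above[i])[0]}
        members.add(u)
        clustering.clusters[u] = Cluster(u, frozenset(members))
    return clustering
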