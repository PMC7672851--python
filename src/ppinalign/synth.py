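"""Synthetic PPIN pairs with a planted partial node correspondence.

The generator emulates the shape of real aligner inputs: two connected
undirected networks, three bit-score tables (within each network and
cross-network) whose cross entries are concentrated on the planted
correspondence, GO-style term sets correlated with the correspondence, and
the random add/delete edge-perturbation protocol used for robustness
studies (5% of the edges by default).

Scores are on a BLAST-like raw scale (maximum 100): a true pair scores
near 100, decoy cross-pairs score uniformly in [1, 40], so the true-pair
scores strictly exceed the decoy mean by construction. The ``noise``
fraction drives three things at once: the downward jitter on true-pair
scores, the number of decoy cross-pairs (4·noise per source node on
average), and the fraction of net2 edges rewired after copying net1's
topology. ``noise=0`` therefore yields an exactly mirrored pair.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .io import (
    AnnotationTable,
    BitScoreTable,
    GenerationError,
    Network,
    PerturbationError,
)

_RAW_MAX = 100.0  # raw score given to self-pairs and noise-free true pairs


@dataclass
class SyntheticPair:
    """A generated network pair with its ground truth and companion tables."""

    net1: Network
    net2: Network
    truth: Dict[str, str]
    bits11: BitScoreTable
    bits22: BitScoreTable
    bits12: BitScoreTable
    annotations1: AnnotationTable
    annotations2: AnnotationTable
    seed: int

    def __post_init__(self) -> None:
        images = list(self.truth.values())
        if len(images) != len(set(images)):
            raise ValueError("planted correspondence is not injective")


def random_connected_graph(n: int, n_edges: int, rng: np.random.Generator,
                           prefix: str = "p", name: str = "") -> Network:
    """A uniform-ish connected graph: random recursive tree plus extra
    edges sampled without replacement from the complement."""
    if n < 1:
        raise GenerationError("need at least one node")
    max_edges = n * (n - 1) // 2
    if n_edges < n - 1 or n_edges > max_edges:
        raise GenerationError(
            f"cannot build a connected simple graph with n={n}, m={n_edges}")
    nodes = [f"{prefix}{i:04d}" for i in range(n)]
    edges = set()
    for i in range(1, n):
        j = int(rng.integers(0, i))
        edges.add((nodes[min(i, j)], nodes[max(i, j)]))
    # top up to the requested count
    while len(edges) < n_edges:
        need = n_edges - len(edges)
        i_idx = rng.integers(0, n, size=4 * need + 8)
        j_idx = rng.integers(0, n, size=4 * need + 8)
        for i, j in zip(i_idx, j_idx):
            if i == j:
                continue
            e = (nodes[min(i, j)], nodes[max(i, j)])
            if e not in edges:
                edges.add(e)
                if len(edges) == n_edges:
                    break
    return Network(sorted(edges), nodes, name=name or f"synthetic-{prefix}")


def perturb_edges(g: Network, fraction: float, seed: int) -> Network:
    """Delete ⌊fraction·|E|⌋ uniformly chosen edges and add the same count
    of uniformly chosen non-edges of the original graph; the node set is
    unchanged and the edge-set symmetric difference is exactly 2·⌊f·|E|⌋."""
    if not 0 <= fraction <= 1:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    edges = sorted(g.edges)
    k = int(fraction * len(edges))
    if k == 0:
        return g.copy()
    nodes = g.nodes
    n = len(nodes)
    absent = [
        (nodes[i], nodes[j])
        for i, j in itertools.combinations(range(n), 2)
        if not g.has_edge(nodes[i], nodes[j])
    ]
    if len(absent) < k:
        raise PerturbationError(
            f"need {k} absent edges to add, only {len(absent)} available")
    del_idx = rng.choice(len(edges), size=k, replace=False)
    add_idx = rng.choice(len(absent), size=k, replace=False)
    kept = set(edges) - {edges[i] for i in del_idx}
    kept.update(absent[i] for i in add_idx)
    return Network(sorted(kept), nodes, name=g.name)


def _edge_count(n: int, density: float) -> int:
    return max(n - 1, int(round(density * n * (n - 1) / 2)))


def generate_pair(n1: int, n2: int, overlap: float = 1.0,
                  edge_density: float = 0.15, noise: float = 0.05,
                  seed: int = 0) -> SyntheticPair:
    """Generate a connected network pair with a planted correspondence.

    net2 starts as an isomorphic relabelled copy of net1, gains ``n2 - n1``
    extra attached nodes plus edges up to the target density, and is then
    rewired on a ``noise`` fraction of its edges. The truth map covers
    ⌊overlap·n1⌋ source nodes. Deterministic for a fixed seed.
    """
    if n1 > n2:
        raise GenerationError(f"n1 must not exceed n2 (got {n1} > {n2})")
    if n1 < 2:
        raise GenerationError("need at least 2 nodes per network")
    for nm, f in (("overlap", overlap), ("edge_density", edge_density), ("noise", noise)):
        if not 0 <= f <= 1:
            raise GenerationError(f"{nm} must be in [0, 1], got {f}")
    rng = np.random.default_rng(seed)

    net1 = random_connected_graph(n1, _edge_count(n1, edge_density), rng,
                                  prefix="a", name="net1")
    a_nodes = net1.nodes
    b_of = {a: f"b{int(a[1:]):04d}" for a in a_nodes}  # full structural rename

    # mirrored copy of net1, then extra nodes and edges up to density
    edges2 = {(min(b_of[u], b_of[v]), max(b_of[u], b_of[v])) for u, v in net1.edges}
    b_nodes = sorted(b_of.values()) + [f"b{i:04d}" for i in range(n1, n2)]
    for i in range(n1, n2):
        j = int(rng.integers(0, i))
        u, v = sorted((b_nodes[i], b_nodes[j]))
        edges2.add((u, v))
    m2 = _edge_count(n2, edge_density)
    while len(edges2) < m2:
        i, j = rng.integers(0, n2, size=2)
        if i == j:
            continue
        edges2.add((min(b_nodes[i], b_nodes[j]), max(b_nodes[i], b_nodes[j])))
    net2 = Network(sorted(edges2), b_nodes, name="net2")

    if noise > 0:
        for attempt in range(20):
            cand = perturb_edges(net2, noise, int(rng.integers(0, 2**31 - 1)))
            if cand.is_connected():
                net2 = cand
                break
        else:
            raise GenerationError("could not perturb net2 while keeping it connected")

    # planted correspondence
    k = int(overlap * n1)
    chosen = sorted(rng.choice(n1, size=k, replace=False).tolist())
    truth = {a_nodes[i]: b_of[a_nodes[i]] for i in chosen}

    # within-network tables: self-scores at the raw maximum plus a sprinkle
    # of moderate "paralog" pairs, mirrored across the two networks so that
    # a noise-free pair has identical similarity structure.
    bits11 = BitScoreTable()
    bits22 = BitScoreTable()
    for a in a_nodes:
        bits11.set(a, a, _RAW_MAX)
    for b in b_nodes:
        bits22.set(b, b, _RAW_MAX)
    for _ in range(n1 // 2):
        i, j = rng.integers(0, n1, size=2)
        if i == j:
            continue
        s = float(rng.uniform(10, 60))
        bits11.set(a_nodes[i], a_nodes[j], s)
        bits22.set(b_of[a_nodes[i]], b_of[a_nodes[j]], s)
    for _ in range((n2 - n1) // 2):
        i, j = rng.integers(0, n2, size=2)
        if i == j:
            continue
        bits22.set(b_nodes[i], b_nodes[j], float(rng.uniform(10, 60)))

    # cross-network table: true pairs high, decoys low
    bits12 = BitScoreTable()
    for a, b in truth.items():
        bits12.set(a, b, _RAW_MAX - noise * float(rng.uniform(0, 20)))
    n_decoys = int(round(4 * noise * n1))
    placed = 0
    truth_set = set(truth.items())
    for _ in range(20 * n_decoys + 8):
        if placed >= n_decoys:
            break
        i = int(rng.integers(0, n1))
        j = int(rng.integers(0, n2))
        a, b = a_nodes[i], b_nodes[j]
        if (a, b) in truth_set or bits12.raw(a, b) > 0:
            continue
        bits12.set(a, b, float(rng.uniform(1, 40)))
        placed += 1

    # annotations: a shared term per true pair, a private term per node
    ann1 = AnnotationTable()
    ann2 = AnnotationTable()
    for idx, (a, b) in enumerate(sorted(truth.items())):
        ann1.add(a, f"T{idx:05d}")
        ann2.add(b, f"T{idx:05d}")
    for a in a_nodes:
        ann1.add(a, f"P1_{a}")
    for b in b_nodes:
        ann2.add(b, f"P2_{b}")

    return SyntheticPair(net1, net2, truth, bits11, bits22, bits12,
                         ann1, ann2, seed)
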