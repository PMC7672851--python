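"""Readers, writers and in-memory containers for PPIN alignment inputs.

All external formats are plain TSV: edge lists (two columns used, ``#``
comments allowed), bit-score tables (protein, protein, non-negative score),
GO-style annotations (protein, term), protein-complex catalogs (complex id,
protein, function label) and essential-protein lists (one id per column 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Set, Tuple

import networkx as nx

logger = logging.getLogger("ppinalign")


class ParseError(ValueError):
    """A malformed line in an input file; the message names the line number."""


class EmptyNetworkError(ValueError):
    """An edge-list file that yields no nodes at all."""


class DegenerateScoresError(ValueError):
    """A bit-score table that cannot be normalized (empty or all-zero)."""


class PerturbationError(ValueError):
    """Edge perturbation cannot find enough absent edges to add."""


class GenerationError(RuntimeError):
    """Synthetic network generation failed (infeasible parameters)."""


def _pair(u: str, v: str) -> Tuple[str, str]:
    """Canonical unordered key for a protein pair."""
    return (u, v) if u <= v else (v, u)


# ---------------------------------------------------------------------------
# Network


class Network:
    """An undirected simple graph of proteins.

    Self-loops are stripped and duplicate edges collapsed at construction.
    Node identifiers are opaque case-sensitive strings; every iteration
    order exposed by this class is lexicographic, so downstream results do
    not depend on input file ordering.
    """

    def __init__(self, edges: Iterable[Tuple[str, str]] = (),
                 nodes: Iterable[str] = (), name: str = "") -> None:
        self.name = name
        g = nx.Graph()
        g.add_nodes_from(nodes)
        n_loops = 0
        for u, v in edges:
            if u == v:
                n_loops += 1
                g.add_node(u)
            else:
                g.add_edge(u, v)
        if n_loops:
            logger.debug("%s: stripped %d self-loop(s)", name or "network", n_loops)
        self._g = g

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> Tuple[str, ...]:
        return tuple(sorted(self._g.nodes))

    @property
    def node_set(self) -> Set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> Set[Tuple[str, str]]:
        return {_pair(u, v) for u, v in self._g.edges}

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def degree(self, u: str) -> int:
        return self._g.degree[u]

    def neighbors(self, u: str) -> Set[str]:
        return set(self._g.neighbors(u))

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def is_connected(self) -> bool:
        return self.n_nodes > 0 and nx.is_connected(self._g)

    def copy(self, name: str | None = None) -> "Network":
        return Network(self.edges, self.nodes, name if name is not None else self.name)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return self.node_set == other.node_set and self.edges == other.edges

    def __repr__(self) -> str:
        return f"Network({self.name!r}, n={self.n_nodes}, m={self.n_edges})"


def read_network(path: str, name: str = "") -> Network:
    """Read a TSV edge list; strip self-loops, collapse duplicate edges.

    Lines starting with ``#`` and blank lines are ignored. Each remaining
    line must carry at least two whitespace-separated tokens; extra columns
    are ignored. Loop lines ``u u`` contribute the node but no edge.
    """
    edges: List[Tuple[str, str]] = []
    nodes: List[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            toks = stripped.split()
            if len(toks) < 2:
                raise ParseError(f"{path}:{lineno}: expected at least 2 columns, got {len(toks)}")
            nodes.extend(toks[:2])
            edges.append((toks[0], toks[1]))
    if not nodes:
        raise EmptyNetworkError(f"{path}: no nodes found")
    return Network(edges, nodes, name=name or str(path))


def write_network(g: Network, path: str) -> None:
    """Write a TSV edge list. Isolated nodes are written as loop lines so
    that read_network(write_network(g)) reproduces (nodes, edges) exactly."""
    with open(path, "w") as fh:
        fh.write("# source\ttarget\n")
        for u, v in sorted(g.edges):
            fh.write(f"{u}\t{v}\n")
        covered = {x for e in g.edges for x in e}
        for u in g.nodes:
            if u not in covered:
                fh.write(f"{u}\t{u}\n")


# ---------------------------------------------------------------------------
# Bit scores


class BitScoreTable:
    """Sparse symmetric map (protein, protein) -> raw sequence bit score.

    Missing pairs read as 0. When both orientations of a pair are inserted
    the maximum raw value is kept (reciprocal BLAST hits differ; max is the
    conservative similarity). ``b(u, v)`` returns the normalized score
    B(u,v) = raw / normalizer in [0, 1]; the normalizer is set by
    :func:`normalize_bit_scores`.
    """

    def __init__(self, entries: Mapping[Tuple[str, str], float] | None = None,
                 normalizer: float | None = None) -> None:
        self.entries: Dict[Tuple[str, str], float] = {}
        if entries:
            for (u, v), s in entries.items():
                self.set(u, v, s)
        self.normalizer = normalizer

    def set(self, u: str, v: str, score: float) -> None:
        if score < 0:
            raise ValueError(f"negative bit score for ({u}, {v}): {score}")
        k = _pair(u, v)
        prev = self.entries.get(k)
        self.entries[k] = score if prev is None else max(prev, score)

    def raw(self, u: str, v: str) -> float:
        return self.entries.get(_pair(u, v), 0.0)

    def b(self, u: str, v: str) -> float:
        """Normalized bit score B(u, v) in [0, 1]."""
        if self.normalizer is None:
            raise DegenerateScoresError("table has not been normalized")
        return self.entries.get(_pair(u, v), 0.0) / self.normalizer

    def __len__(self) -> int:
        return len(self.entries)

    def items(self):
        return sorted(self.entries.items())


def read_bit_scores(path: str) -> BitScoreTable:
    """Read a 3-column TSV (protein, protein, non-negative score)."""
    t = BitScoreTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            toks = stripped.split()
            if len(toks) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns, got {len(toks)}")
            try:
                score = float(toks[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad score {toks[2]!r}") from exc
            if score < 0:
                raise ParseError(f"{path}:{lineno}: negative score {score}")
            t.set(toks[0], toks[1], score)
    return t


def write_bit_scores(t: BitScoreTable, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# protein1\tprotein2\tscore\n")
        for (u, v), s in t.items():
            fh.write(f"{u}\t{v}\t{s:.6g}\n")


def normalize_bit_scores(t: BitScoreTable) -> BitScoreTable:
    """Rescale by the maximum stored raw entry so that B lies in [0, 1]
    and at least one pair attains 1. Per-table normalization keeps each
    table's scale independent of the others."""
    if not t.entries:
        raise DegenerateScoresError("cannot normalize an empty bit-score table")
    m = max(t.entries.values())
    if m == 0:
        raise DegenerateScoresError("cannot normalize an all-zero bit-score table")
    return BitScoreTable(dict(t.entries), normalizer=m)


# ---------------------------------------------------------------------------
# Annotations / complexes / essentiality


class AnnotationTable:
    """Map protein -> set of functional term identifiers (GO-style).

    Unannotated proteins read as the empty set.
    """

    def __init__(self, terms: Mapping[str, Set[str]] | None = None) -> None:
        self.terms: Dict[str, Set[str]] = {p: set(ts) for p, ts in (terms or {}).items()}

    def add(self, protein: str, term: str) -> None:
        self.terms.setdefault(protein, set()).add(term)

    def go(self, protein: str) -> FrozenSet[str]:
        return frozenset(self.terms.get(protein, ()))

    def __len__(self) -> int:
        return len(self.terms)


def read_annotations(path: str) -> AnnotationTable:
    """Read a 2-column TSV (protein, term); repeated rows accumulate."""
    t = AnnotationTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            toks = stripped.split()
            if len(toks) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(toks)}")
            t.add(toks[0], toks[1])
    return t


def write_annotations(t: AnnotationTable, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# protein\tterm\n")
        for p in sorted(t.terms):
            for term in sorted(t.terms[p]):
                fh.write(f"{p}\t{term}\n")


@dataclass
class ProteinComplex:
    complex_id: str
    members: Set[str] = field(default_factory=set)
    labels: Set[str] = field(default_factory=set)


class ComplexCatalog:
    """Catalog of protein complexes with functional labels."""

    def __init__(self) -> None:
        self._by_id: Dict[str, ProteinComplex] = {}

    def add(self, complex_id: str, protein: str, label: str | None = None) -> None:
        c = self._by_id.setdefault(complex_id, ProteinComplex(complex_id))
        c.members.add(protein)
        if label:
            c.labels.add(label)

    @property
    def complexes(self) -> List[ProteinComplex]:
        return [self._by_id[cid] for cid in sorted(self._by_id)]

    def __len__(self) -> int:
        return len(self._by_id)


def read_complexes(path: str) -> ComplexCatalog:
    """Read a 3-column TSV (complex id, protein, function label)."""
    cat = ComplexCatalog()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            toks = stripped.split()
            if len(toks) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns, got {len(toks)}")
            cat.add(toks[0], toks[1], toks[2])
    return cat


def read_essential(path: str) -> Set[str]:
    """Read an essential-protein list (first column of each line)."""
    ess: Set[str] = set()
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            ess.add(stripped.split()[0])
    return ess


# ---------------------------------------------------------------------------
# Global alignment container + TSV round trip


@dataclass
class GlobalAlignment:
    """Partial injective map from the smaller network's nodes into the
    larger one's, with per-pair provenance (``local`` for pairs fixed by the
    hypergraph-assignment stage, ``extension-k`` for pairs added in the k-th
    extension round)."""

    mapping: Dict[str, str] = field(default_factory=dict)
    stage: Dict[str, str] = field(default_factory=dict)
    source_name: str = ""
    target_name: str = ""

    def __post_init__(self) -> None:
        images = list(self.mapping.values())
        if len(images) != len(set(images)):
            raise ValueError("alignment map is not injective")

    def __len__(self) -> int:
        return len(self.mapping)

    def items(self):
        return sorted(self.mapping.items())


def write_alignment(a: GlobalAlignment, path: str) -> None:
    """Write an alignment as TSV: source protein, target protein, stage tag."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\tstage\n")
        for u, v in a.items():
            fh.write(f"{u}\t{v}\t{a.stage.get(u, 'local')}\n")


def read_alignment(path: str) -> GlobalAlignment:
    mapping: Dict[str, str] = {}
    stage: Dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("source"):
            raise ParseError(f"{path}:1: missing alignment header")
        for lineno, line in enumerate(fh, start=2):
            stripped = line.strip()
            if not stripped:
                continue
            toks = stripped.split("\t")
            if len(toks) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            mapping[toks[0]] = toks[1]
            stage[toks[0]] = toks[2]
    return GlobalAlignment(mapping, stage)
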