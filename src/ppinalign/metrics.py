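"""Evaluation statistics for PPIN alignments.

Topological quality: edge correctness (EC), the fraction of source edges
whose images are edges of the target, over min(|E|, |E'|). Biological
quality: the functional similarity FS of a protein pair is the Jaccard
index of their GO term sets; FC averages FS over the source node set, and
FC_max is the best FC attainable by ANY injective map (a maximum-weight
bipartite matching with FS weights). Complex-level quality: each source
complex is mapped to the target complex receiving the plurality of its
aligned members; a mapped pair is coherent when the complexes share a
function label, and CFC = 100 * CP / (CP + NCP). Essential-protein
transfer is scored as a binary classifier (specificity, precision, F1,
accuracy, balanced accuracy, Matthews correlation, and the uncertainty
coefficient UC = (H(X) - H(X|Y)) / H(X) with base-2 entropies).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Sequence, Set, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io import AnnotationTable, ComplexCatalog, GlobalAlignment, Network


class MetricUndefinedError(ValueError):
    """A metric whose denominator is empty on the given inputs."""


# ---------------------------------------------------------------------------
# Topology


def edge_correctness(mu: GlobalAlignment, g: Network, g2: Network) -> float:
    """EC: preserved source edges over min(|E|, |E'|)."""
    if g.n_edges == 0 or g2.n_edges == 0:
        raise MetricUndefinedError("edge correctness needs non-empty edge sets")
    m = mu.mapping
    preserved = sum(
        1 for u, v in g.edges
        if u in m and v in m and g2.has_edge(m[u], m[v])
    )
    return preserved / min(g.n_edges, g2.n_edges)


# ---------------------------------------------------------------------------
# Function (GO term sets)


def functional_similarity(u: str, u2: str, ann1: AnnotationTable,
                          ann2: AnnotationTable) -> float:
    """FS(u, u'): Jaccard index of the two GO term sets; 0 when both empty."""
    a, b = ann1.go(u), ann2.go(u2)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def functional_coherence(mu: GlobalAlignment, ann1: AnnotationTable,
                         ann2: AnnotationTable, source_nodes: Sequence[str]) -> float:
    """FC: mean FS over the source node set; unmapped nodes contribute 0."""
    n = len(source_nodes)
    if n == 0:
        raise MetricUndefinedError("functional coherence needs a non-empty source")
    total = sum(functional_similarity(u, mu.mapping[u], ann1, ann2)
                for u in source_nodes if u in mu.mapping)
    return total / n


def fc_max(ann1: AnnotationTable, ann2: AnnotationTable,
           nodes1: Sequence[str], nodes2: Sequence[str]) -> float:
    """Best FC over all injective maps: maximum-weight bipartite matching
    on the complete FS-weighted bipartite graph, divided by the smaller
    node count."""
    if not nodes1 or not nodes2:
        raise MetricUndefinedError("fc_max needs non-empty node sets")
    n1, n2 = sorted(nodes1), sorted(nodes2)
    fs = np.empty((len(n1), len(n2)))
    for i, u in enumerate(n1):
        for j, v in enumerate(n2):
            fs[i, j] = functional_similarity(u, v, ann1, ann2)
    ri, ci = linear_sum_assignment(fs, maximize=True)
    return float(fs[ri, ci].sum()) / min(len(n1), len(n2))


# ---------------------------------------------------------------------------
# Protein complexes


@dataclass
class ComplexPairTable:
    """Outcome counts of mapping source complexes onto target complexes."""

    not_assigned: int
    coherent: int
    incoherent: int

    @property
    def cfc(self) -> float:
        return complex_cfc(self.coherent, self.incoherent)


def complex_cfc(coherent: int, incoherent: int) -> float:
    """CFC = 100 * CP / (CP + NCP)."""
    assigned = coherent + incoherent
    if assigned == 0:
        raise MetricUndefinedError("CFC undefined: no aligned complex pairs")
    return 100.0 * coherent / assigned


def complex_precision(coherent: int, incoherent: int) -> float:
    """Percentage of coherent pairs among assigned complexes."""
    assigned = coherent + incoherent
    if assigned == 0:
        raise MetricUndefinedError("precision undefined: no assigned complexes")
    return 100.0 * coherent / assigned


def complex_coherence(mu: GlobalAlignment, complexes1: ComplexCatalog,
                      complexes2: ComplexCatalog) -> ComplexPairTable:
    """Map each source complex to the target complex that receives the
    plurality of its aligned members (ties: lexicographically first target
    complex id; no aligned member landing in any target complex ->
    not assigned). A mapped pair is coherent iff the label sets intersect."""
    m = mu.mapping
    not_assigned = coherent = incoherent = 0
    targets = complexes2.complexes
    for c in complexes1.complexes:
        images = {m[p] for p in c.members if p in m}
        votes: Dict[str, int] = {}
        for t in targets:
            hits = len(images & t.members)
            if hits:
                votes[t.complex_id] = hits
        if not votes:
            not_assigned += 1
            continue
        best = max(votes.values())
        winner_id = min(cid for cid, v in votes.items() if v == best)
        winner = next(t for t in targets if t.complex_id == winner_id)
        if c.labels & winner.labels:
            coherent += 1
        else:
            incoherent += 1
    return ComplexPairTable(not_assigned, coherent, incoherent)


# ---------------------------------------------------------------------------
# Essential-protein classifier


@dataclass
class EssentialityReport:
    tp: int
    fp: int
    tn: int
    fn: int
    specificity: float
    precision: float
    f1: float
    accuracy: float
    balanced_accuracy: float
    mcc: float
    uc: float
    mcc_degenerate: bool = False

    def as_dict(self) -> Dict[str, float]:
        return {
            "specificity": self.specificity, "precision": self.precision,
            "f1": self.f1, "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "mcc": self.mcc, "uc": self.uc,
        }


def _entropy_bits(counts: Sequence[int]) -> float:
    total = sum(counts)
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            h -= p * math.log2(p)
    return h


def uncertainty_coefficient(x: Sequence[int], y: Sequence[int]) -> float:
    """UC = (H(X) - H(X|Y)) / H(X), base-2 entropies over the empirical
    joint distribution; 0 when Y carries no information, 1 when Y
    determines X."""
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    n = len(x)
    joint = {(0, 0): 0, (0, 1): 0, (1, 0): 0, (1, 1): 0}
    for xi, yi in zip(x, y):
        joint[(int(xi), int(yi))] += 1
    hx = _entropy_bits([joint[(0, 0)] + joint[(0, 1)], joint[(1, 0)] + joint[(1, 1)]])
    if hx == 0:
        raise MetricUndefinedError("UC undefined: H(X) = 0")
    hxy = 0.0
    for yv in (0, 1):
        ny = joint[(0, yv)] + joint[(1, yv)]
        if ny:
            hxy += (ny / n) * _entropy_bits([joint[(0, yv)], joint[(1, yv)]])
    return (hx - hxy) / hx


def mcc_from_counts(tp: int, fp: int, tn: int, fn: int) -> Tuple[float, bool]:
    """Matthews correlation; returns (0, degenerate=True) when any marginal
    of the confusion table is empty."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0, True
    return (tp * tn - fp * fn) / math.sqrt(denom), False


def essentiality_metrics(mu: GlobalAlignment, ess1: Set[str],
                         ess2: Set[str]) -> EssentialityReport:
    """Binary-classifier statistics for essentiality transfer.

    Over the MAPPED source proteins: X marks source essentiality, Y marks
    essentiality of the image. Labeling: TP = essential mapped to
    essential, FP = essential mapped to non-essential, TN = non-essential
    to non-essential, FN = non-essential to essential, so the positive
    class size is P = TP + FP and the negative N = TN + FN.
    """
    xs, ys = [], []
    for u, v in mu.items():
        xs.append(1 if u in ess1 else 0)
        ys.append(1 if v in ess2 else 0)
    tp = sum(1 for x, y in zip(xs, ys) if x and y)
    fp = sum(1 for x, y in zip(xs, ys) if x and not y)
    tn = sum(1 for x, y in zip(xs, ys) if not x and not y)
    fn = sum(1 for x, y in zip(xs, ys) if not x and y)
    p, n = tp + fp, tn + fn
    if p == 0 or n == 0:
        raise MetricUndefinedError(
            "essentiality metrics need both essential and non-essential mapped proteins")
    mcc, degenerate = mcc_from_counts(tp, fp, tn, fn)
    return EssentialityReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        specificity=tn / n,
        precision=tp / (tp + fp),
        f1=2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0,
        accuracy=(tp + tn) / (p + n),
        balanced_accuracy=((tp / p) + (tn / n)) / 2,
        mcc=mcc,
        uc=uncertainty_coefficient(xs, ys),
        mcc_degenerate=degenerate,
    )
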