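# Methods

## Model and assumptions

The aligner treats each PPIN as an undirected simple graph: self-loops are
stripped at load time (interaction databases report them, but they carry no
information for topological matching) and duplicate edges collapse. Protein
identifiers are opaque, case-sensitive strings; no cross-database identifier
mapping is attempted. Sequence similarity enters only through precomputed
bit-score tables; running the sequence search itself is out of scope.

The method is parameter-free in the algorithmic sense: the cluster-size
cutoff is the third quartile of the data's own similarity distribution, the
cluster-pair cost and alignment score have no weights to tune, and the CLI
consequently exposes only I/O, logging and debug switches. The only seeds
in the package belong to the synthetic generator and the perturbation
protocol; the alignment pipeline itself is deterministic.

## Numerical and procedural choices

**Bit-score normalization.** Raw scores are divided by the maximum entry of
their own table, so every table independently maps into [0, 1] with at
least one pair at 1. When the same pair appears in both orientations the
maximum raw value is kept. An empty or all-zero table is an error rather
than silently producing zeros.

**Distances and the quartile.** Hop distances are computed per component by
breadth-first search (via `scipy.sparse.csgraph`); the diameter of a
disconnected graph is the maximum *finite* distance, and disconnected pairs
have similarity 0. The threshold α is the linear-interpolation quantile
(numpy's default, which is also the default of R's `quantile`) over all
unordered distinct node pairs, disconnected pairs included, self-pairs
excluded. Cluster membership uses the strict inequality s > α. Because hop
distances are small integers, similarity values are heavily tied in
practice and the fraction of pairs above α stays at or below 25 %; for a
hypothetical all-distinct population the linear-interpolation convention
can overshoot that bound by one order statistic, which the tests document
explicitly. The cluster center is always force-included in its own cluster
(membership by s(u,u) > α alone could drop it, and every cluster-pair
alignment is seeded at the centers).

**Cluster-pair alignment.** Degrees in the cost
F(v, v′) = |deg v − deg v′| − B(v, v′) + 1 are full-network degrees, not
degrees within the cluster. The per-frontier assignment is solved exactly
with `scipy.optimize.linear_sum_assignment`, which handles rectangular
instances natively (no padding needed; surplus nodes on the larger side
simply stay unmatched). Newly matched pairs join the expansion queue in
decreasing order of F — the literal reading of the procedure; because the
queue is layered by construction, this ordering only permutes pairs within
one distance layer. F-ties and every other tie in the package break
lexicographically on (source id, target id), and all node lists are sorted
before any solver call, so results are invariant under permutations of the
input edge lists. Only the *center* pair is required to have a positive
cross bit score; zero-score pairs may be matched inside a cluster
alignment.

**Hypergraph assignment.** The exact weighted bipartite hypergraph
assignment problem is NP-hard, and nothing in the method requires an exact
optimum — the scoring already encodes "best alignments first". The solver
here is greedy: hyperarcs in decreasing weight, every payload pair whose
two endpoints are still free is accepted. The tests replay this rule with
an independent hand-trace and check injectivity under fuzzing.

**Best-scored selection and extension.** The greedy best-scored subset keys
on the source *center*: a mapping whose center already lies in the union of
selected domains is skipped even if its domain would add new nodes. During
the global extension, every cluster alignment is restricted to pairs whose
both endpoints are unaligned, its score recomputed (the max-|Dom|
normalizer is recomputed over the surviving restrictions), and the cluster
matching and selection rerun on the positive-score survivors. A restricted
mapping can lose its own center; a picked center is therefore marked
covered unconditionally, which guarantees the selection loop terminates.
The extension loop itself adds at least one pair per round or stops; a
safety cap of one round per source node converts any non-progress bug into
a hard error instead of a hang. Pairs are never re-assigned: provenance
tags record whether a pair was fixed by the local stage (`local`) or by the
k-th extension round (`extension-k`).

**Orientation.** The source of the final map is always the network with
fewer nodes; inputs are swapped internally if given in the other order.
The returned pair-level summary — the method's "similarity score" for the
two networks — is reported as the edge correctness of the global alignment
together with the mean normalized cross bit score over matched pairs.

## Evaluation statistics

EC divides preserved source edges by min(|E|, |E′|). FS is the Jaccard
index of GO term sets, with FS(∅, ∅) := 0 (the conservative choice for an
average of similarities); FC sums FS over mapped source nodes and divides
by the full source node count, so unmapped nodes dilute the score; FC_max
solves the maximum-weight bipartite matching over the complete FS-weighted
graph. Complex coherence maps each source complex to the target complex
receiving the plurality of its aligned members (lexicographic tie-break;
complexes with no aligned member are "not assigned"); a pair is coherent
when the label sets intersect, and CFC = 100·CP/(CP+NCP). Essentiality
transfer uses the labeling in which the positive class is source-protein
essentiality: TP/FP split the essential mapped proteins by image
essentiality and TN/FN the non-essential ones. Unmapped proteins are
excluded from the confusion table, so P = TP+FP and N = TN+FN. Precision is
the standard TP/(TP+FP). MCC follows the product-moment formula with a
degenerate-denominator flag (reported as 0); the uncertainty coefficient
uses base-2 entropies over the empirical joint distribution with the
0·log 0 := 0 convention, and is undefined when H(X) = 0.

## Synthetic generator

The generator emulates a cross-species alignment input at a chosen scale:
a connected source network (random recursive tree plus uniform extra edges
to the target density), a target network built as a relabelled isomorphic
copy with extra attached nodes, and three bit-score tables on a raw scale
of 100 — self-scores at the maximum, a sprinkle of moderate within-network
"paralog" pairs mirrored across the two networks, cross scores near 100 on
the planted pairs and uniform-in-[1, 40] decoys elsewhere. A single
`noise` fraction drives the downward jitter of true-pair scores, the decoy
count (4·noise per source node) and the fraction of target edges rewired
by the perturbation protocol; `noise = 0` yields an exactly mirrored pair.
Annotations give each planted pair one shared term plus one private term
per node, so FS is 1/3 on true pairs and 0 elsewhere.

The perturbation protocol deletes ⌊f·|E|⌋ uniformly chosen edges and adds
the same number of uniformly chosen non-edges of the *original* graph —
sampling additions from the original complement (rather than the
post-deletion complement) prevents a deleted edge from being re-added, so
the edge-set symmetric difference is exactly 2⌊f·|E|⌋ by construction.

What the generator does **not** emulate: scale-free degree distributions,
the size imbalance of real interactomes, correlated noise between topology
and sequence scores, incomplete/biased GO annotation, or false-positive
interactions with structure. Recovery rates on these synthetic pairs are
therefore an internal-consistency check (the pipeline can find a planted
signal through its own clustering, matching and merging machinery), not a
forecast of accuracy on real interactomes.

## Problem sizes used in the test suite

The suite exercises clustering up to 1,000 nodes, solver-vs-enumeration
oracles at 500 random assignment instances (≤ 6 per side), 200 cluster-
matching instances (≤ 7 per side) and FC_max against 3!–7! permutation
search; recovery runs use 50-node pairs over 20 seeds and the dispersion
study uses ten 5 %-perturbed replicates of a 100-node pair. These sizes
make every oracle exhaustive or every statistic stable while keeping the
whole suite in the seconds range.

## Known limitations

- The greedy hypergraph assignment is a heuristic; a pathological weight
  pattern could make it arbitrarily worse than the exact optimum, although
  the score structure (weights in (0, 2], payloads internally consistent)
  makes this unlikely in practice.
- The O(|V|²) similarity matrix is materialized densely; tens of thousands
  of nodes will need the optional TSV cache or a sparse refactor.
- FC_max is an exact assignment on the complete bipartite graph and is
  quadratic in memory, cubic in time; the CLI declines to compute it above
  ~2,000×2,000 proteins.
- Only Jaccard similarity of term sets is implemented — no GO-DAG ancestor
  closure or semantic similarity measures.
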