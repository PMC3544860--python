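# Methods

## Model and definitions

Genes evolve inside a rooted species tree *S*. A gene family's history is a
rooted gene tree whose internal nodes are *speciation* or *duplication*
events; leaves are extant genes, each belonging to one extant species. For
a taxonomic range *X* (internal node of *S*, identified with its set of
leaf species), the *group roots* are the maximal speciation nodes whose
subtrees — after pruning the gene tree to leaves with species in *X* and
suppressing unary nodes — lie entirely within *X*. Each group root's pruned
leaf set is one hierarchical orthologous group (HOG) at *X*; pruned leaves
covered by no in-range speciation node are singletons and form no group.
Group roots are emitted by descending from each pruned root through
duplication nodes, which guarantees maximality: a speciation ancestor of an
emitted node necessarily reaches species outside *X* (otherwise it would
have been emitted instead). Groups at a child range are always subsets of
exactly one group at the parent range; the hierarchy container enforces
this and assigns dot-path ids (`3`, `3.1`) so nesting is visible in flat
output.

Pairwise relations follow Fitch: a gene pair is orthologous when its last
common ancestor in the gene tree is a speciation, paralogous when a
duplication. The *perfect orthology graph* has exactly the ortholog pairs
as edges. Two consequences drive the algorithm: at any range the connected
components of the induced perfect subgraph coincide with the HOGs, and each
component has diameter ≤ 2 (it contains the complete bipartite graph
between the two sides of the group root's speciation).

## Inference

`infer_hogs` recurses top-down over the internal nodes of *S*. At the
current range it induces the subgraph on the range's species, drops
singletons, and partitions it with `divide_graph`; each part is one group.
It then recurses into each child clade *within each part* — the subgraph
carries the cuts already made, so an edge removed at an ancestral range can
never resurface below, and nesting holds by construction on arbitrary
(noisy) input. The alternative — re-inducing each child range from the
original graph — can contradict ancestral cut decisions; a regression test
covers a graph where the two strategies differ.

`divide_graph` splits into connected components, keeps any component with
≤ 2 nodes or whose two-step reachability statistic reaches the stringency
ε, and otherwise removes the component's minimum cut and recurses on both
sides (re-dropping singletons). Setting ε = 0 reduces the method to the
transitive closure (pure connected components); ε = 1 demands the
error-free ideal and, on perfect input, never cuts.

The reachability statistic samples `min(sample_size, |V|)` start nodes
without replacement and averages, over start nodes, the fraction of the
other |V|−1 nodes within graph distance 2 (depth-2 BFS with early exit).
With exhaustive sampling the value is exact; on a diameter-≤2 component the
mean is a sum of exact 1.0 terms, so the ε = 1 comparison is safe in
floating point.

The minimum cut is the Karger–Stein recursive contraction: contract random
edges — probability proportional to weight in weighted mode, uniform over
parallel unit edges otherwise — down to ⌈1 + n/√2⌉ supernodes, recurse
twice, and return the better cut; at ≤ 6 supernodes the optimum over all
bipartitions is enumerated exactly. Independent repetitions (default
3·⌈log₂ n⌉) amplify the success probability; the test suite checks the
result against brute-force enumeration and the deterministic Stoer–Wagner
algorithm on random graphs of ≤ 10 nodes. Ties keep the first cut found
under the seeded stream. In weighted mode, unweighted edges count as 1.0,
so the weighted cut degenerates gracefully to the cardinality cut.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `epsilon` | 0.65 | stringency of the reachability condition; the operating default — benchmarks treat it as a free parameter and `bench` sweeps a grid |
| `weighted` | false | guide the cut by alignment-score weights (spurious calls tend to score low) |
| `sample_size` | 20 | start nodes of the estimator; components up to this size are evaluated exhaustively, hence deterministically |
| `mincut_trials` | 3·⌈log₂ n⌉ | independent Karger–Stein repetitions |
| `seed` | 0 | master seed for every stochastic choice |
| `root_range` | tree root | start the recursion at a more specific range (large families); genes outside are ignored |

## Determinism and the refinement property

Every stochastic decision about a component (estimator subsample, cut
randomness) uses an RNG derived by hashing the master seed together with
the component's sorted gene ids. Decisions are therefore a pure function of
the component, not of the recursion path that produced it. This yields
byte-identical reruns and a clean monotonicity guarantee: at a fixed seed,
raising ε only ever refines the partition at a range, because the two runs
take identical actions on every component they share. A single shared RNG
stream would break this whenever the stricter run consumes extra draws.

## Simulator

The generator emulates the validation design of graph-based HOG inference
studies: a constant-rate birth–death species tree (default birth 0.01,
death 0.001 per unit time) conditioned on `n_taxa` surviving tips, rescaled
to root-to-leaf height `tree_height` = 150 arbitrary units (standing in for
an evolutionary-distance scale); and per family one root lineage evolving
down the tree, speciating at every species-tree node and
duplicating/dying along branches as Poisson processes with rates
`dup_rate`/`loss_rate`. The presets are order-of-magnitude emulations, not
replications: "paper-low" (30 taxa, 200 families, dup = loss = 0.001,
roughly 2–4 duplications per family) and "paper-high" (dup = loss = 0.005).
The simulator books event counts and total simulated lineage time so the
realised duplication intensity can be checked against `dup_rate × time`
(a Monte-Carlo test keeps it within 3 standard deviations).

Noise is injected at the graph level, not the sequence level: each true
edge is deleted with probability `fn_rate`; false-positive candidates are
the cross-species *paralog* pairs of the same family (exactly the
same-family non-edges), each added with probability `fp_rate`. Synthetic
alignment scores are truncated-positive normals — true edges from a
high-mean distribution (200 ± 25), spurious from a low-mean one (50 ± 25) —
mirroring the observation that spurious calls tend to score low. What this
does **not** emulate: sequence evolution (codon models, indels, rate shifts
after duplication), gene fusion/fission, horizontal transfer, and
cross-family false positives (which would merge families and belong to an
initial clustering step outside this tool's scope). Passing tests on this
generator therefore validate the graph-clustering logic under controlled
edge noise, not robustness to every artefact of real pairwise-orthology
pipelines.

## Evaluation

A hierarchy *implies* pairwise relations: for genes co-occurring in at
least one group, a cross-species pair is orthologous iff it shares a group
at the range that is the LCA of the two species, and paralogous otherwise;
co-grouped same-species pairs are paralogs (they can never be orthologs).
Precision is TP/(TP+FP) and recall TP/(TP+FN) per relation type; an empty
denominator reports 1.0 by default (a vacuous prediction makes no mistake —
configurable to `None` for "undefined"). A flag excludes within-species
pairs for protocols that score only cross-species relations.

One structural point matters when choosing the truth set: paralog pairs
whose duplication has **no speciation ancestor** in the gene tree (the
family root is a duplication) are not representable at any taxonomic range,
by any hierarchy. Benchmarks of the *hierarchy* therefore compare against
the relations induced by the true hierarchy (equivalently, Fitch relations
restricted to representable pairs), under which perfect input scores
precision = recall = 1 exactly; the `evaluate` CLI scores against whatever
truth file it is given, so scoring against raw Fitch truth shows the
corresponding recall ceiling (visible in the README example).

## Problem sizes and numerical choices

The validation suite runs 20 seeded replicates at 10 taxa × 50 families
(roughly 500 genes and 2 300 ortholog edges each) for the exactness
theorem, and 100 random ≤ 10-node graphs for the min-cut oracle; these
sizes make every oracle exhaustive (all-pairs BFS diameters, full
bipartition enumeration) while keeping the whole suite under half a minute.
Degenerate inputs are defined rather than special-cased: graphs with < 2
nodes are rejected by the estimator and the cut; empty graphs or forests
yield empty hierarchies; leaf ranges produce no groups; groups require ≥ 2
genes.

## Known limitations

Inference quality is bounded by the input graph; when noise leaves too few
or too many edges to discriminate between merge and split, the ε trade-off
decides. Very large families are expensive (the cut dominates); the
supported mitigation is `root_range`, giving up the deepest levels. Event
labels are taken as given — reconciliation or species-overlap labelling of
unlabelled gene trees is out of scope, as are OrthoXML I/O and sequence
formats.
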