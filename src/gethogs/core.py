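"""The GETHOGs inference engine.

Top-down recursion over the species tree: at each taxonomic range the
orthology subgraph induced by the range's species is partitioned into
groups, then the recursion descends into each child clade *within* each
group's subgraph, so that edges removed by cuts at an ancestral level stay
removed below and the group nesting invariant holds by construction.

On error-free input every induced component has diameter at most 2, so the
average fraction of nodes reachable within two steps of a node equals 1.
On real input spurious edges merge distinct groups into weakly connected
components; the partitioner therefore keeps splitting a component at its
(weighted) minimum cut until the two-step reachability statistic reaches
the stringency threshold epsilon.  The minimum cut is found with the
randomised recursive-contraction algorithm of Karger and Stein, repeated
over independent trials to drive the failure probability down.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .hierarchy import HogHierarchy
from .orthograph import OrthologyGraph
from .speciestree import RangeKey, SpeciesTree, SpeciesTreeNode

__all__ = [
    "GethogsParams",
    "CutResult",
    "fraction_reachable_in_two_steps",
    "minimum_cut",
    "divide_graph",
    "infer_hogs",
    "default_mincut_trials",
]


@dataclass
class GethogsParams:
    """Tunable knobs of the inference.

    epsilon
        Stringency of the two-step reachability condition, in [0, 1].
        A component is split until its statistic reaches epsilon; 1 demands
        the error-free ideal, 0 disables splitting (transitive closure).
    weighted
        Use edge weights (alignment scores) in the minimum cut, so that
        low-scoring spurious edges are preferentially cut.
    sample_size
        Number of start nodes for the reachability estimator; components
        with at most this many nodes are evaluated exhaustively (and hence
        deterministically).
    mincut_trials
        Independent Karger-Stein repetitions; ``None`` picks
        3*ceil(log2 n) per graph.
    seed
        Master seed; every stochastic choice derives from it.
    root_range
        Optional taxonomic range (internal node) at which to start the
        recursion; genes outside it are ignored.  Useful for very large
        families.
    """

    epsilon: float = 0.65
    weighted: bool = False
    sample_size: int = 20
    mincut_trials: int | None = None
    seed: int = 0
    root_range: RangeKey | str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError(f"epsilon must be in [0, 1], got {self.epsilon}")
        if self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")
        if self.mincut_trials is not None and self.mincut_trials < 1:
            raise ValueError("mincut_trials must be >= 1")


@dataclass(frozen=True)
class CutResult:
    """A bipartition of a connected graph with the removed edges."""

    side_a: frozenset[str]
    side_b: frozenset[str]
    cut_weight: float
    cut_edges: frozenset[tuple[str, str]] = field(default_factory=frozenset)


def default_mincut_trials(n_nodes: int) -> int:
    return max(1, 3 * math.ceil(math.log2(max(2, n_nodes))))


# ---------------------------------------------------------------------------
# Two-step reachability statistic
# ---------------------------------------------------------------------------


def fraction_reachable_in_two_steps(
    g: OrthologyGraph,
    sample_size: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Average fraction of other nodes within path distance 2 of a node.

    ``min(sample_size, |V|)`` start nodes are sampled uniformly without
    replacement; for each, the fraction of the remaining ``|V|-1`` nodes
    reachable in at most two steps is computed by a depth-2 breadth-first
    sweep with early exit, and the mean over start nodes is returned.
    With ``sample_size >= |V|`` (or ``None``) every node is used and the
    value is exact and deterministic.  Equals 1.0 exactly on graphs of
    diameter <= 2.
    """
    n = g.n_genes
    if n < 2:
        raise ValueError("the reachability statistic needs a graph with >= 2 nodes")
    nodes = sorted(g.genes)
    if sample_size is None or sample_size >= n:
        sample = nodes
    else:
        if rng is None:
            raise ValueError("subsampling the start nodes requires an rng")
        idx = rng.choice(n, size=sample_size, replace=False)
        sample = [nodes[i] for i in sorted(idx)]
    total = 0.0
    for v in sample:
        reached: set[str] = set()
        first = g.neighbors(v)
        reached |= first
        if len(reached - {v}) < n - 1:  # early exit otherwise
            for u in first:
                reached |= g.neighbors(u)
                if len(reached - {v}) >= n - 1:
                    break
        reached.discard(v)
        total += len(reached) / (n - 1)
    return total / len(sample)


# ---------------------------------------------------------------------------
# Karger-Stein minimum cut
# ---------------------------------------------------------------------------

_Adj = dict[str, dict[str, float]]


def _build_adj(g: OrthologyGraph, weighted: bool) -> _Adj:
    adj: _Adj = {v: {} for v in g.genes}
    for a, b in g.edges():
        w = g.weight(a, b) if weighted else 1.0
        adj[a][b] = w
        adj[b][a] = w
    return adj


def _copy_adj(adj: _Adj) -> _Adj:
    return {u: dict(nbrs) for u, nbrs in adj.items()}


def _contract_to(adj: _Adj, members: dict[str, frozenset[str]], target: int,
                 rng: np.random.Generator) -> None:
    """Contract random edges (weight-proportional) until ``target`` supernodes."""
    while len(adj) > target:
        edges = [(u, v, w) for u in adj for v, w in adj[u].items() if u < v]
        weights = np.fromiter((e[2] for e in edges), dtype=float, count=len(edges))
        r = rng.random() * weights.sum()
        i = int(np.searchsorted(np.cumsum(weights), r, side="right"))
        i = min(i, len(edges) - 1)
        u, v, _ = edges[i]
        # merge v into u (u < v keeps keys deterministic)
        members[u] = members[u] | members[v]
        del members[v]
        for x, w in adj[v].items():
            if x == u:
                continue
            adj[u][x] = adj[u].get(x, 0.0) + w
            adj[x][u] = adj[u][x]
            del adj[x][v]
        del adj[u][v]
        del adj[v]


def _enumerate_min_cut(
    adj: _Adj, members: dict[str, frozenset[str]]
) -> tuple[float, frozenset[str], frozenset[str]]:
    """Exact minimum cut over all bipartitions of <= ~12 supernodes."""
    nodes = sorted(adj)
    n = len(nodes)
    rest = nodes[1:]
    best: tuple[float, frozenset[str], frozenset[str]] | None = None
    for mask in range(1 << (n - 1)):
        side = {nodes[0]}
        for i in range(n - 1):
            if mask >> i & 1:
                side.add(rest[i])
        if len(side) == n:
            continue
        w = sum(
            wt for u in side for x, wt in adj[u].items() if x not in side
        )
        if best is None or w < best[0]:
            a = frozenset().union(*(members[u] for u in side))
            b = frozenset().union(*(members[u] for u in adj if u not in side))
            best = (w, a, b)
    assert best is not None
    return best


def _karger_stein(
    adj: _Adj, members: dict[str, frozenset[str]], rng: np.random.Generator
) -> tuple[float, frozenset[str], frozenset[str]]:
    n = len(adj)
    if n <= 6:
        return _enumerate_min_cut(adj, members)
    target = math.ceil(1 + n / math.sqrt(2))
    best: tuple[float, frozenset[str], frozenset[str]] | None = None
    for _ in range(2):
        a2, m2 = _copy_adj(adj), dict(members)
        _contract_to(a2, m2, target, rng)
        cand = _karger_stein(a2, m2, rng)
        if best is None or cand[0] < best[0]:
            best = cand
    return best


def minimum_cut(
    g: OrthologyGraph,
    weighted: bool = False,
    trials: int | None = None,
    rng: np.random.Generator | None = None,
) -> CutResult:
    """Best bipartition over independent Karger-Stein repetitions.

    Recursive contraction with weight-proportional edge sampling (uniform
    over edges when unweighted); the lowest-weight cut over ``trials`` runs
    is kept, ties resolved in favour of the first one found.  Requires a
    connected graph with at least 2 nodes.
    """
    if g.n_genes < 2:
        raise ValueError("minimum_cut needs a graph with >= 2 nodes")
    if not g.is_connected():
        raise ValueError("minimum_cut requires a connected graph; split components first")
    if rng is None:
        rng = np.random.default_rng()
    if trials is None:
        trials = default_mincut_trials(g.n_genes)
    adj = _build_adj(g, weighted)
    members = {v: frozenset([v]) for v in adj}
    best: tuple[float, frozenset[str], frozenset[str]] | None = None
    for _ in range(trials):
        cand = _karger_stein(_copy_adj(adj), dict(members), rng)
        if best is None or cand[0] < best[0]:
            best = cand
    _, side_a, side_b = best
    if min(side_b) < min(side_a):
        side_a, side_b = side_b, side_a
    cut_edges = frozenset(
        (a, b) for a, b in g.edges() if (a in side_a) != (b in side_a)
    )
    cut_weight = sum((g.weight(a, b) if weighted else 1.0) for a, b in cut_edges)
    return CutResult(side_a, side_b, cut_weight, cut_edges)


# ---------------------------------------------------------------------------
# Graph division (recursive min-cut under the reachability condition)
# ---------------------------------------------------------------------------


def _component_rng(seed: int, genes: Iterable[str]) -> np.random.Generator:
    """RNG derived from (seed, component content), independent of the path.

    Making every stochastic decision a pure function of the component keeps
    runs reproducible and makes the partition refine monotonically as
    epsilon grows: a higher-epsilon run that performs extra cuts does not
    perturb the random choices taken on the components both runs share.
    """
    h = hashlib.sha256()
    h.update(str(int(seed)).encode())
    for gid in sorted(genes):
        h.update(b"\x1f")
        h.update(gid.encode())
    return np.random.default_rng(int.from_bytes(h.digest()[:8], "little") >> 1)


def divide_graph(g: OrthologyGraph, params: GethogsParams) -> list[OrthologyGraph]:
    """Partition a graph into subgraphs satisfying the reachability condition.

    Connected components are taken first; each component is kept when it has
    at most 2 nodes or its two-step reachability statistic reaches
    ``params.epsilon``, and is otherwise split at its minimum cut (dropping
    the cut edges and any singleton so produced), recursively.  The returned
    subgraphs are connected, singleton-free, and sorted by smallest gene id.
    """
    out: list[OrthologyGraph] = []
    stack = g.drop_singletons().connected_components()
    while stack:
        comp = stack.pop()
        rng = _component_rng(params.seed, comp.genes)
        if comp.n_genes <= 2:
            out.append(comp)
            continue
        stat = fraction_reachable_in_two_steps(comp, params.sample_size, rng)
        if stat >= params.epsilon:
            out.append(comp)
            continue
        cut = minimum_cut(comp, params.weighted, params.mincut_trials, rng)
        for side in (cut.side_a, cut.side_b):
            sub = comp.subgraph_on_genes(side).drop_singletons()
            stack.extend(sub.connected_components())
    out.sort(key=lambda c: min(c.genes))
    return out


# ---------------------------------------------------------------------------
# The full top-down inference
# ---------------------------------------------------------------------------


def infer_hogs(
    g: OrthologyGraph, species_tree: SpeciesTree, params: GethogsParams | None = None
) -> HogHierarchy:
    """Infer the hierarchy of orthologous groups for every taxonomic range.

    At each internal species-tree node, the current subgraph is induced on
    the node's species (dropping singletons) and partitioned with
    :func:`divide_graph`; each resulting subgraph is one group.  The
    recursion then descends into each child clade within each group's
    post-cut subgraph, attaching child groups to their parent.  With
    epsilon such that no cuts fire (e.g. on perfect input with epsilon=1),
    the groups are exactly the connected components per range.
    """
    if params is None:
        params = GethogsParams()
    unknown = {
        g.species_of(gene) for gene in g.genes
    } - species_tree.leaf_labels
    if unknown:
        raise ValueError(
            f"genes from species absent from the species tree: {sorted(unknown)}"
        )
    if params.root_range is None:
        root = species_tree.root
    else:
        root = species_tree.node_for_range(params.root_range)
    h = HogHierarchy()
    if root.is_leaf:
        return h

    def visit(node: SpeciesTreeNode, graph: OrthologyGraph, parent_id: str | None) -> None:
        sub = graph.induced_subgraph(node.leaf_set, drop_singletons=True)
        if sub.n_genes == 0:
            return
        for part in divide_graph(sub, params):
            grp = h.add_group(node.range_key, part.genes, parent_id=parent_id)
            for child in node.children:
                if not child.is_leaf:
                    visit(child, part, grp.group_id)

    visit(root, g, None)
    return h
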