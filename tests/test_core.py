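"""The inference engine: reachability statistic, min cut, graph division,
and the full top-down recursion over the species tree."""

import itertools

import networkx as nx
import numpy as np
import pytest

from gethogs import (
    GethogsParams,
    SimulationConfig,
    SpeciesTree,
    divide_graph,
    fraction_reachable_in_two_steps,
    infer_hogs,
    minimum_cut,
    perfect_graph,
    sample_species_tree,
    simulate_gene_forest,
    true_hogs,
)

from conftest import build_graph


# -- two-step reachability ---------------------------------------------------


def test_statistic_is_one_on_diameter_two_graphs(k23):
    assert fraction_reachable_in_two_steps(k23) == 1.0


def test_statistic_on_path_of_four(path4):
    # per-node fractions: 2/3, 1, 1, 2/3
    assert fraction_reachable_in_two_steps(path4) == pytest.approx((2 / 3 + 1 + 1 + 2 / 3) / 4)


def test_statistic_on_barbell(barbell):
    # per-node: 3/5 for the four outer nodes, 1 for the two bridge endpoints
    assert fraction_reachable_in_two_steps(barbell) == pytest.approx(11 / 15)


def test_statistic_on_single_edge():
    g = build_graph([("a", "b")])
    assert fraction_reachable_in_two_steps(g) == 1.0


def test_statistic_requires_two_nodes():
    g = build_graph([("a", "b")]).induced_subgraph({"A"})
    with pytest.raises(ValueError, match=">= 2 nodes"):
        fraction_reachable_in_two_steps(g)


def test_subsampled_statistic_is_seeded_and_bounded(barbell):
    vals = {
        fraction_reachable_in_two_steps(barbell, sample_size=3,
                                        rng=np.random.default_rng(11))
        for _ in range(3)
    }
    assert len(vals) == 1  # same seed, same subsample
    assert 0.0 < vals.pop() <= 1.0


# -- minimum cut -------------------------------------------------------------


def _brute_force_cut_weight(g, weighted):
    nodes = sorted(g.genes)
    best = np.inf
    for mask in range(1, 1 << (len(nodes) - 1)):
        # non-empty proper subsets never containing the last node
        side = {nodes[i] for i in range(len(nodes) - 1) if mask >> i & 1}
        w = sum(
            (g.weight(a, b) if weighted else 1.0)
            for a, b in g.edges()
            if (a in side) != (b in side)
        )
        best = min(best, w)
    return best


def test_min_cut_path_splits_off_an_endpoint():
    g = build_graph([("a", "b"), ("b", "c")])
    cut = minimum_cut(g, rng=np.random.default_rng(0))
    assert cut.cut_weight == 1.0
    assert {len(cut.side_a), len(cut.side_b)} == {1, 2}


def test_min_cut_separates_bridged_triangles(barbell):
    cut = minimum_cut(barbell, rng=np.random.default_rng(0))
    assert cut.cut_weight == 1.0
    assert cut.cut_edges == {("a2", "c1")}
    assert {frozenset(cut.side_a), frozenset(cut.side_b)} == {
        frozenset({"a1", "b1", "c1"}), frozenset({"a2", "b2", "c2"}),
    }


def test_min_cut_weights_force_the_split():
    g = build_graph([("a", "b", 5.0), ("b", "c", 1.0)])
    cut = minimum_cut(g, weighted=True, rng=np.random.default_rng(0))
    assert cut.cut_weight == 1.0
    assert cut.side_b == frozenset({"c"})


def test_min_cut_rejects_disconnected_input():
    g = build_graph([("a1", "b1"), ("c1", "d1")])
    with pytest.raises(ValueError, match="connected"):
        minimum_cut(g, rng=np.random.default_rng(0))


def test_min_cut_sides_partition_and_cover(barbell):
    cut = minimum_cut(barbell, rng=np.random.default_rng(1))
    assert cut.side_a | cut.side_b == barbell.genes
    assert not cut.side_a & cut.side_b
    for a, b in cut.cut_edges:
        assert (a in cut.side_a) != (b in cut.side_a)


@pytest.mark.parametrize("weighted", [False, True])
def test_min_cut_matches_brute_force_on_random_graphs(weighted):
    """Karger-Stein at default trials vs exhaustive bipartition enumeration
    and the deterministic Stoer-Wagner algorithm, on 30 random connected
    graphs of <= 10 nodes; at most one stochastic miss tolerated."""
    rng = np.random.default_rng(1234)
    misses = 0
    for trial in range(30):
        n = int(rng.integers(4, 11))
        while True:
            base = nx.gnp_random_graph(n, 0.45, seed=int(rng.integers(1 << 31)))
            if base.number_of_nodes() >= 2 and nx.is_connected(base):
                break
        edges = []
        for u, v in base.edges:
            w = float(rng.integers(1, 10)) if weighted else None
            edges.append((f"g{u:02d}", f"g{v:02d}", w))
        g = build_graph(edges, species_of=lambda x: x.upper())
        expected = _brute_force_cut_weight(g, weighted)
        if weighted:
            sw_weight, _ = nx.stoer_wagner(g.to_networkx())
            assert sw_weight == pytest.approx(expected)
        cut = minimum_cut(g, weighted=weighted, rng=np.random.default_rng(trial))
        if abs(cut.cut_weight - expected) > 1e-9:
            misses += 1
    assert misses <= 1


# -- divide_graph ------------------------------------------------------------


def test_divide_keeps_conforming_graph_intact(barbell):
    # statistic 11/15 ~ 0.733 >= 0.6: kept whole
    parts = divide_graph(barbell, GethogsParams(epsilon=0.6))
    assert [sorted(p.genes) for p in parts] == [sorted(barbell.genes)]


def test_divide_cuts_bridge_at_higher_stringency(barbell):
    parts = divide_graph(barbell, GethogsParams(epsilon=0.8))
    assert {frozenset(p.genes) for p in parts} == {
        frozenset({"a1", "b1", "c1"}), frozenset({"a2", "b2", "c2"}),
    }


def test_divide_returns_complete_bipartite_intact(k23):
    parts = divide_graph(k23, GethogsParams(epsilon=1.0))
    assert len(parts) == 1 and parts[0].genes == k23.genes


def test_divided_parts_satisfy_the_condition_exhaustively():
    rng = np.random.default_rng(5)
    base = nx.gnp_random_graph(18, 0.2, seed=3)
    edges = [(f"g{u:02d}", f"g{v:02d}") for u, v in base.edges]
    g = build_graph(edges, species_of=lambda x: x.upper())
    params = GethogsParams(epsilon=0.8, seed=17)
    for part in divide_graph(g, params):
        assert part.is_connected()
        if part.n_genes > 2:
            assert fraction_reachable_in_two_steps(part) >= params.epsilon


def _partition_refines(finer, coarser):
    return all(
        any(f <= c for c in coarser) for f in finer
    )


def test_raising_epsilon_refines_the_partition():
    """With identical seeds, the partition at a higher stringency refines
    (or equals) the partition at a lower one."""
    rng = np.random.default_rng(2)
    base = nx.gnp_random_graph(16, 0.25, seed=8)
    edges = [(f"g{u:02d}", f"g{v:02d}") for u, v in base.edges]
    g = build_graph(edges, species_of=lambda x: x.upper())
    grid = [0.2, 0.4, 0.6, 0.8, 1.0]
    partitions = [
        {frozenset(p.genes) for p in divide_graph(g, GethogsParams(epsilon=e, seed=9))}
        for e in grid
    ]
    for finer, coarser in zip(partitions[1:], partitions):
        assert _partition_refines(finer, coarser)


# -- infer_hogs --------------------------------------------------------------


def test_infer_equals_truth_on_example(example_forest, example_tree):
    g = perfect_graph(example_forest)
    h = infer_hogs(g, example_tree, GethogsParams(epsilon=1.0))
    assert h == true_hogs(example_forest, example_tree)


def test_infer_on_empty_graph_is_empty(example_tree):
    from gethogs import OrthologyGraph

    h = infer_hogs(OrthologyGraph(), example_tree, GethogsParams())
    assert h.n_groups == 0


def test_infer_rejects_unknown_species(example_tree):
    g = build_graph([("x1", "y1")], species_of={"x1": "X", "y1": "Y"}.__getitem__)
    with pytest.raises(ValueError, match="absent from the species tree"):
        infer_hogs(g, example_tree, GethogsParams())


def test_infer_root_range_restricts_the_analysis(example_forest, example_tree):
    g = perfect_graph(example_forest)
    h = infer_hogs(g, example_tree, GethogsParams(epsilon=1.0, root_range=("H", "M")))
    assert h.ranges() == [("H", "M")]
    assert h.as_nested_sets()[("H", "M")] == {
        frozenset({"h1", "m1"}), frozenset({"h2", "m2"})
    }


def test_two_spurious_bridges_are_cut_and_two_groups_reported():
    """Two dense clusters joined by two spurious edges: the minimum cut
    removes exactly the two bridging edges and two groups are reported."""
    cluster1 = [(a, b) for a, b in itertools.combinations(
        ["a1", "b1", "c1", "d1"], 2)]
    cluster2 = [(a, b) for a, b in itertools.combinations(
        ["a2", "b2", "c2", "d2"], 2)]
    bridges = [("a1", "b2"), ("c1", "d2")]
    g = build_graph(cluster1 + cluster2 + bridges)
    parts = divide_graph(g, GethogsParams(epsilon=0.9))
    assert {frozenset(p.genes) for p in parts} == {
        frozenset({"a1", "b1", "c1", "d1"}), frozenset({"a2", "b2", "c2", "d2"}),
    }
    tree = SpeciesTree.from_newick("((A,B),(C,D));")
    h = infer_hogs(g, tree, GethogsParams(epsilon=0.9))
    root_groups = h.as_nested_sets()[("A", "B", "C", "D")]
    assert root_groups == {
        frozenset({"a1", "b1", "c1", "d1"}), frozenset({"a2", "b2", "c2", "d2"}),
    }


@pytest.mark.parametrize("seed", [21, 22, 23])
def test_infer_equals_truth_on_simulated_perfect_data(seed):
    """On error-free simulated input with epsilon=1 the inferred hierarchy
    equals the true one at every range (connected-component correspondence
    end to end)."""
    rng = np.random.default_rng(seed)
    cfg = SimulationConfig(n_taxa=8, n_families=25, dup_rate=0.002,
                           loss_rate=0.002, seed=seed)
    tree = sample_species_tree(cfg, rng)
    forest = simulate_gene_forest(tree, cfg, rng)
    g = perfect_graph(forest)
    h = infer_hogs(g, tree, GethogsParams(epsilon=1.0))
    assert h == true_hogs(forest, tree)
    h.validate(tree)


def test_cut_edges_stay_removed_in_descendant_ranges():
    """An edge cut at an ancestral range must not resurface below: the
    child-range groups are computed within the parent groups' post-cut
    subgraphs."""
    # two K4 clusters, one gene per species each, one spurious bridge a1-a2
    cluster1 = [(a, b) for a, b in itertools.combinations(
        ["a1", "b1", "c1", "d1"], 2)]
    cluster2 = [(a, b) for a, b in itertools.combinations(
        ["a2", "b2", "c2", "d2"], 2)]
    g = build_graph(cluster1 + cluster2 + [("a1", "a2")])
    tree = SpeciesTree.from_newick("((A,B),(C,D));")
    # merged root statistic (2 + 6*4/7)/8 = 19/28 < 0.7: the bridge is cut.
    # At range (A,B) the *uncut* induced subgraph would be the path
    # b1-a1-a2-b2 with statistic 5/6 >= 0.7, i.e. one merged group; the cut
    # edge staying removed must yield the two pairs instead.
    h = infer_hogs(g, tree, GethogsParams(epsilon=0.7))
    assert h.as_nested_sets()[("A", "B", "C", "D")] == {
        frozenset({"a1", "b1", "c1", "d1"}), frozenset({"a2", "b2", "c2", "d2"}),
    }
    assert h.as_nested_sets()[("A", "B")] == {
        frozenset({"a1", "b1"}), frozenset({"a2", "b2"}),
    }
    h.validate(tree)


def test_infer_is_deterministic_for_a_fixed_seed():
    rng = np.random.default_rng(31)
    cfg = SimulationConfig(n_taxa=8, n_families=20, dup_rate=0.003,
                           loss_rate=0.002, fp_rate=0.02, fn_rate=0.05, seed=31)
    tree = sample_species_tree(cfg, rng)
    forest = simulate_gene_forest(tree, cfg, rng)
    from gethogs import fitch_relations, perturb_graph

    g = perturb_graph(perfect_graph(forest), fitch_relations(forest), cfg, rng)
    params = GethogsParams(epsilon=0.65, weighted=True, seed=31)
    h1 = infer_hogs(g, tree, params)
    h2 = infer_hogs(g, tree, params)
    assert h1 == h2
    assert [g_.group_id for g_ in h1.all_groups()] == [
        g_.group_id for g_ in h2.all_groups()
    ]
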