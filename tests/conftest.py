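"""Shared fixtures: hand-built gene trees and graphs used across the suite."""

import pytest

from gethogs import OrthologyGraph, SpeciesTree
from gethogs.truth import parse_labeled_forest

#: species of each gene in the worked example family
EXAMPLE_SPECIES = {"h1": "H", "h2": "H", "m1": "M", "m2": "M", "f1": "F"}

#: one family: a duplication before the human/mouse split, one fish gene.
EXAMPLE_NEWICK = (
    "(((h1,m1)[&&NHX:Ev=spec],(h2,m2)[&&NHX:Ev=spec])[&&NHX:Ev=dup],f1)"
    "[&&NHX:Ev=spec];"
)


def build_graph(edges, species_of=None):
    """OrthologyGraph from (a, b[, w]) tuples; species defaults to the
    upper-cased first character of the gene id."""
    if species_of is None:
        species_of = lambda g: g[0].upper()  # noqa: E731
    g = OrthologyGraph()
    for row in edges:
        a, b = row[0], row[1]
        w = row[2] if len(row) > 2 else None
        for gene in (a, b):
            if gene not in g:
                g.add_gene(gene, species_of(gene))
        g.add_edge(a, b, w)
    return g


@pytest.fixture
def example_forest():
    return parse_labeled_forest(EXAMPLE_NEWICK, species_of=EXAMPLE_SPECIES)


@pytest.fixture
def example_tree():
    return SpeciesTree.from_newick("((H,M),F);")


@pytest.fixture
def barbell():
    """Two triangles joined by a single bridge edge (c1-a2)."""
    return build_graph(
        [("a1", "b1"), ("a1", "c1"), ("b1", "c1"),
         ("a2", "b2"), ("a2", "c2"), ("b2", "c2"),
         ("c1", "a2")]
    )


@pytest.fixture
def path4():
    """The path a-b-c-d on four species."""
    return build_graph([("a", "b"), ("b", "c"), ("c", "d")])


@pytest.fixture
def k23():
    """Complete bipartite graph on {a1,a2} x {b1,b2,b3}."""
    return build_graph(
        [(a, b) for a in ("a1", "a2") for b in ("b1", "b2", "b3")]
    )
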