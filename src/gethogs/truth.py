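"""Event-labelled gene trees as ground truth.

A labelled gene forest is a set of rooted gene trees whose internal nodes
carry an event label — *speciation* or *duplication*.  From it follow, by
Fitch's definitions, the true pairwise ortholog/paralog relations (by the
event at each pair's last common ancestor), the true hierarchical
orthologous groups for every taxonomic range (via group roots: the maximal
speciation nodes lying entirely within the range after pruning), and the
perfect orthology graph whose edges are exactly the ortholog pairs.

The group-root construction: prune each tree to the leaves whose species
belong to the range, suppressing unary internal nodes; then descend from
the pruned root through duplication nodes and emit every maximal speciation
node.  Leaves reached without crossing a speciation node are singletons and
contribute no group.  No emitted node has a strict ancestor that is a
speciation within the range (the emitted set is minimal/maximal in that
sense), and emitted nodes correspond one-to-one with groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import dendropy

from .hierarchy import HogHierarchy
from .orthograph import OrthologyGraph
from .relations import RelationSet
from .speciestree import RangeKey, SpeciesTree

__all__ = [
    "Gene",
    "GeneTreeNode",
    "LabeledGeneForest",
    "GroupRoot",
    "read_labeled_forest",
    "write_labeled_forest",
    "group_roots",
    "true_hogs",
    "fitch_relations",
    "perfect_graph",
]

SPECIATION = "spec"
DUPLICATION = "dup"
_EVENTS = (SPECIATION, DUPLICATION)


class Gene(NamedTuple):
    gene_id: str
    species_id: str


class GeneTreeNode:
    """Node of an event-labelled gene tree.

    Leaves carry a :class:`Gene`; internal nodes carry ``event`` in
    {"spec", "dup"} and at least two children.
    """

    __slots__ = ("event", "gene", "children", "parent")

    def __init__(
        self,
        event: str | None = None,
        gene: Gene | None = None,
        children: Iterable["GeneTreeNode"] = (),
    ) -> None:
        self.event = event
        self.gene = gene
        self.children: list[GeneTreeNode] = []
        self.parent: GeneTreeNode | None = None
        for c in children:
            self.add_child(c)

    @classmethod
    def leaf(cls, gene_id: str, species_id: str) -> "GeneTreeNode":
        return cls(gene=Gene(gene_id, species_id))

    def add_child(self, child: "GeneTreeNode") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["GeneTreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["GeneTreeNode"]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_genes(self) -> frozenset[str]:
        return frozenset(n.gene.gene_id for n in self.leaves())

    def leaf_species(self) -> frozenset[str]:
        return frozenset(n.gene.species_id for n in self.leaves())

    def is_ancestor_of(self, other: "GeneTreeNode") -> bool:
        node = other.parent
        while node is not None:
            if node is self:
                return True
            node = node.parent
        return False

    def __repr__(self) -> str:  # pragma: no cover
        if self.is_leaf:
            return f"GeneTreeNode(leaf={self.gene.gene_id})"
        return f"GeneTreeNode({self.event}, {len(self.children)} children)"


class LabeledGeneForest:
    """A set of rooted event-labelled gene trees with globally unique leaves."""

    def __init__(self, trees: Iterable[GeneTreeNode], stats: dict | None = None) -> None:
        self.trees = list(trees)
        #: optional simulator bookkeeping (event counts, lineage time)
        self.stats = stats or {}
        self._validate()

    def _validate(self) -> None:
        seen: set[str] = set()
        for i, tree in enumerate(self.trees):
            for node in tree.preorder():
                if node.is_leaf:
                    if node.gene is None:
                        raise ValueError(f"tree {i}: leaf without a gene")
                    if node.gene.gene_id in seen:
                        raise ValueError(
                            f"gene {node.gene.gene_id!r} appears in more than one place"
                        )
                    seen.add(node.gene.gene_id)
                else:
                    if node.event not in _EVENTS:
                        raise ValueError(
                            f"tree {i}: internal node with missing/unknown event label "
                            f"{node.event!r} (leaves below: {sorted(node.leaf_genes())[:3]})"
                        )
                    if len(node.children) < 2:
                        raise ValueError(f"tree {i}: internal node with <2 children")

    @property
    def genes(self) -> list[Gene]:
        return [n.gene for t in self.trees for n in t.leaves()]

    @property
    def species(self) -> frozenset[str]:
        return frozenset(g.species_id for g in self.genes)

    def species_of(self) -> dict[str, str]:
        return {g.gene_id: g.species_id for g in self.genes}

    def __len__(self) -> int:
        return len(self.trees)


# ---------------------------------------------------------------------------
# Newick I/O.  Dialect: the event is a node comment "[&&NHX:Ev=spec]" /
# "[&&NHX:Ev=dup]"; a plain internal-node label "spec"/"dup" is accepted as a
# fallback.  One tree per line; leaves are "SPECIES|gene" ids unless a
# separate mapping is handed in.
# ---------------------------------------------------------------------------


def read_labeled_forest(
    path: str | Path,
    species_of: dict[str, str] | None = None,
) -> LabeledGeneForest:
    text = Path(path).read_text()
    return parse_labeled_forest(text, species_of=species_of)


def parse_labeled_forest(
    text: str,
    species_of: dict[str, str] | None = None,
) -> LabeledGeneForest:
    tree_list = dendropy.TreeList.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
        extract_comment_metadata=False,
    )
    trees = [_convert_gene_tree(t.seed_node, species_of) for t in tree_list]
    return LabeledGeneForest(trees)


def _event_from_dendropy(dnode: dendropy.Node) -> str | None:
    for comment in dnode.comments or ():
        body = comment.strip().lstrip("&")
        if body.startswith("NHX:"):
            for item in body[4:].split(":"):
                if item.startswith("Ev="):
                    return item[3:]
    label = dnode.label
    if label in _EVENTS:
        return label
    return None


def _convert_gene_tree(
    dnode: dendropy.Node, species_of: dict[str, str] | None
) -> GeneTreeNode:
    children = dnode.child_nodes()
    if not children:
        gene_id = dnode.taxon.label if dnode.taxon is not None else dnode.label
        if not gene_id:
            raise ValueError("gene tree has an unlabelled leaf")
        if species_of is not None:
            if gene_id not in species_of:
                raise ValueError(f"gene {gene_id!r} missing from the gene-to-species map")
            species = species_of[gene_id]
        else:
            from .orthograph import species_from_gene_id

            species = species_from_gene_id(gene_id)
        return GeneTreeNode.leaf(gene_id, species)
    if len(children) == 1:
        return _convert_gene_tree(children[0], species_of)
    event = _event_from_dendropy(dnode)
    if event not in _EVENTS:
        leaves = sorted(
            (l.taxon.label if l.taxon else l.label) or "?" for l in dnode.leaf_iter()
        )
        raise ValueError(
            f"internal node above leaves {leaves[:4]} lacks a valid event label "
            f"(expected Ev=spec or Ev=dup, got {event!r})"
        )
    node = GeneTreeNode(event=event)
    for c in children:
        node.add_child(_convert_gene_tree(c, species_of))
    return node


def write_labeled_forest(forest: LabeledGeneForest, path: str | Path) -> None:
    """One annotated Newick per line, events as [&&NHX:Ev=...] comments."""

    def fmt(node: GeneTreeNode) -> str:
        if node.is_leaf:
            return node.gene.gene_id
        inner = ",".join(fmt(c) for c in node.children)
        return f"({inner})[&&NHX:Ev={node.event}]"

    with Path(path).open("w") as fh:
        for tree in forest.trees:
            fh.write(fmt(tree) + ";\n")


# ---------------------------------------------------------------------------
# Group roots and true HOGs
# ---------------------------------------------------------------------------


class GroupRoot(NamedTuple):
    """A maximal in-range speciation node with its pruned leaf genes."""

    node: GeneTreeNode  # reference into the original (unpruned) tree
    genes: frozenset[str]


class _Pruned:
    __slots__ = ("orig", "children", "gene")

    def __init__(self, orig: GeneTreeNode, children: list, gene: Gene | None) -> None:
        self.orig = orig
        self.children = children
        self.gene = gene

    def genes(self) -> frozenset[str]:
        if self.gene is not None:
            return frozenset([self.gene.gene_id])
        return frozenset().union(*(c.genes() for c in self.children))


def _prune(node: GeneTreeNode, species: frozenset[str]) -> _Pruned | None:
    """Restrict to leaves of the given species, suppressing unary nodes."""
    if node.is_leaf:
        if node.gene.species_id in species:
            return _Pruned(node, [], node.gene)
        return None
    kept = [p for c in node.children if (p := _prune(c, species)) is not None]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    return _Pruned(node, kept, None)


def group_roots(
    forest: LabeledGeneForest, taxon_range: Iterable[str]
) -> list[GroupRoot]:
    """Maximal speciation nodes whose pruned subtrees lie within the range.

    For each tree, the tree is pruned to the range and the pruned root is
    descended through duplication nodes; every maximal speciation node is
    emitted with its pruned leaf set.  Pruned leaves never covered by an
    in-range speciation node are singletons and yield nothing.
    """
    species = frozenset(taxon_range)
    out: list[GroupRoot] = []

    def descend(p: _Pruned) -> None:
        if p.gene is not None:
            return  # singleton leaf: no speciation above it within the range
        if p.orig.event == SPECIATION:
            out.append(GroupRoot(p.orig, p.genes()))
        else:
            for c in p.children:
                descend(c)

    for tree in forest.trees:
        pruned = _prune(tree, species)
        if pruned is not None:
            descend(pruned)
    out.sort(key=lambda r: min(r.genes))
    return out


def true_hogs(forest: LabeledGeneForest, species_tree: SpeciesTree) -> HogHierarchy:
    """The true hierarchy: one group per group root at every internal range.

    Nesting links are derived by the subset relation into the parent range's
    groups, which is unique because group roots correspond one-to-one with
    groups.
    """
    extra = forest.species - species_tree.leaf_labels
    if extra:
        raise ValueError(f"forest species missing from species tree: {sorted(extra)}")
    h = HogHierarchy()
    parent_of_range: dict[RangeKey, RangeKey] = {}
    for node in species_tree.internal_nodes():
        for child in node.children:
            if not child.is_leaf:
                parent_of_range[child.range_key] = node.range_key
    for node in species_tree.internal_nodes():  # preorder: parents first
        key = node.range_key
        parent_key = parent_of_range.get(key)
        for root in group_roots(forest, node.leaf_set):
            parent_id = None
            if parent_key is not None:
                for pgrp in h.groups_at(parent_key):
                    if root.genes <= pgrp.genes:
                        parent_id = pgrp.group_id
                        break
            h.add_group(key, root.genes, parent_id=parent_id)
    return h


# ---------------------------------------------------------------------------
# Fitch relations and the perfect orthology graph
# ---------------------------------------------------------------------------


def fitch_relations(forest: LabeledGeneForest) -> RelationSet:
    """Pairwise relations by the event label at each pair's LCA.

    Two leaves of the same tree are orthologs if their last common ancestor
    is a speciation node, paralogs if it is a duplication; leaves of
    different trees are unrelated.
    """
    rel = RelationSet()

    def visit(node: GeneTreeNode) -> list[str]:
        if node.is_leaf:
            return [node.gene.gene_id]
        child_sets = [visit(c) for c in node.children]
        add = rel.add_ortholog if node.event == SPECIATION else rel.add_paralog
        for i in range(len(child_sets)):
            for j in range(i + 1, len(child_sets)):
                for a in child_sets[i]:
                    for b in child_sets[j]:
                        add(a, b)
        return [g for s in child_sets for g in s]

    for tree in forest.trees:
        visit(tree)
    return rel


def perfect_graph(forest: LabeledGeneForest) -> OrthologyGraph:
    """Error-free orthology graph: edge set = Fitch orthologs, no singletons."""
    species_of = forest.species_of()
    rel = fitch_relations(forest)
    g = OrthologyGraph()
    for a, b in sorted(rel.orthologs):
        for gene in (a, b):
            if gene not in g:
                g.add_gene(gene, species_of[gene])
        g.add_edge(a, b)
    return g
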