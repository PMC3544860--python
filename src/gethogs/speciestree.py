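"""Rooted species trees and taxonomic ranges.

Every internal node of a rooted (possibly multifurcating) species tree
identifies a *taxonomic range*: the monophyletic set of leaf species beneath
it.  Ranges are the levels at which hierarchical orthologous groups are
defined.  A range is keyed canonically by the sorted tuple of its member
species, so multifurcating or unlabelled taxonomy nodes still have a stable
identifier; the Newick node label, when present, is kept as an alias.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator

import dendropy

__all__ = ["SpeciesTreeNode", "SpeciesTree", "read_species_tree", "RangeKey"]

RangeKey = tuple[str, ...]


class SpeciesTreeNode:
    """One node of a species tree; internal nodes are taxonomic ranges."""

    __slots__ = ("label", "children", "parent", "edge_length", "leaf_set")

    def __init__(self, label: str | None = None, edge_length: float | None = None) -> None:
        self.label = label
        self.children: list["SpeciesTreeNode"] = []
        self.parent: "SpeciesTreeNode" | None = None
        self.edge_length = edge_length
        self.leaf_set: frozenset[str] = frozenset()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def range_key(self) -> RangeKey:
        return tuple(sorted(self.leaf_set))

    def add_child(self, child: "SpeciesTreeNode") -> None:
        child.parent = self
        self.children.append(child)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SpeciesTreeNode({'/'.join(self.range_key)})"


class SpeciesTree:
    """Rooted species tree with precomputed per-node leaf sets."""

    def __init__(self, root: SpeciesTreeNode) -> None:
        self.root = root
        self._finalize()

    def _finalize(self) -> None:
        for node in self.postorder():
            if node.is_leaf:
                if not node.label:
                    raise ValueError("species tree has an unlabelled leaf")
                node.leaf_set = frozenset([node.label])
            else:
                if len(node.children) < 2:
                    raise ValueError(
                        "species tree has a unary internal node; "
                        "every internal node must have at least 2 children"
                    )
                node.leaf_set = frozenset().union(*(c.leaf_set for c in node.children))
        leaves = [n.label for n in self.leaf_nodes()]
        if len(leaves) < 2:
            raise ValueError("species tree must have at least 2 leaves")
        if len(set(leaves)) != len(leaves):
            dupes = sorted({l for l in leaves if leaves.count(l) > 1})
            raise ValueError(f"duplicate leaf labels in species tree: {dupes}")
        self._leaf_index = {n.label: n for n in self.leaf_nodes()}
        self._range_index: dict[RangeKey, SpeciesTreeNode] = {}
        self._label_index: dict[str, SpeciesTreeNode] = {}
        for node in self.internal_nodes():
            self._range_index[node.range_key] = node
            if node.label:
                self._label_index[node.label] = node

    # -- traversal -------------------------------------------------------

    def preorder(self) -> Iterator[SpeciesTreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[SpeciesTreeNode]:
        out: list[SpeciesTreeNode] = []
        for node in self.preorder():
            out.append(node)
        yield from reversed(out)

    def leaf_nodes(self) -> list[SpeciesTreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def internal_nodes(self) -> list[SpeciesTreeNode]:
        """Internal nodes (taxonomic ranges) in preorder, root first."""
        return [n for n in self.preorder() if not n.is_leaf]

    @property
    def leaf_labels(self) -> frozenset[str]:
        return self.root.leaf_set

    # -- lookup ----------------------------------------------------------

    def node_for_range(self, key: RangeKey | str) -> SpeciesTreeNode:
        """Find an internal node by canonical range key or Newick label."""
        if isinstance(key, str):
            if key in self._label_index:
                return self._label_index[key]
            key = tuple(sorted(key.split(",")))
        key = tuple(sorted(key))
        try:
            return self._range_index[key]
        except KeyError:
            raise KeyError(f"no internal species-tree node has range {key}") from None

    def lca(self, *species: str) -> SpeciesTreeNode:
        """Last common ancestor of a set of leaf species."""
        wanted = set(species)
        unknown = wanted - self.leaf_labels
        if unknown:
            raise KeyError(f"species not in tree: {sorted(unknown)}")
        node = self.root
        while True:
            inside = [c for c in node.children if wanted <= c.leaf_set]
            if not inside:
                return node
            node = inside[0]

    # -- serialisation ---------------------------------------------------

    def to_newick(self) -> str:
        def fmt(node: SpeciesTreeNode) -> str:
            if node.is_leaf:
                core = node.label or ""
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
                core += node.label or ""
            if node.edge_length is not None:
                core += f":{node.edge_length:g}"
            return core

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "SpeciesTree":
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as err:
            raise ValueError(f"duplicate leaf labels in species tree: {err}") from None
        return cls(_convert(dtree.seed_node))

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "SpeciesTree":
        return cls(_convert(dtree.seed_node))


def _convert(dnode: dendropy.Node) -> SpeciesTreeNode:
    """Convert a dendropy subtree, suppressing unary pass-through nodes."""
    children = dnode.child_nodes()
    if len(children) == 1:
        # fold the unary node into its only child, summing branch lengths
        child = _convert(children[0])
        if dnode.edge.length is not None:
            child.edge_length = (child.edge_length or 0.0) + dnode.edge.length
        return child
    label = dnode.taxon.label if dnode.taxon is not None else dnode.label
    node = SpeciesTreeNode(label=label, edge_length=dnode.edge.length)
    for c in children:
        node.add_child(_convert(c))
    return node


def read_species_tree(path: str | Path) -> SpeciesTree:
    """Read a rooted Newick species tree with per-node taxonomic ranges."""
    text = Path(path).read_text()
    return SpeciesTree.from_newick(text)
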