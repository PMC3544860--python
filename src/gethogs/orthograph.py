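"""Orthology graphs: pairwise orthology relations between extant genes.

An orthology graph is an undirected graph whose nodes are present-day genes
and whose edges are pairwise orthology calls (symmetric, irreflexive,
non-transitive).  Edges may carry strictly positive weights, typically
alignment scores.  A *strict* graph contains no singleton gene: every gene
takes part in at least one orthologous relation.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "OrthologyGraph",
    "read_orthology_graph",
    "write_orthology_graph",
    "species_from_gene_id",
]


def species_from_gene_id(gene_id: str) -> str:
    """Resolve the species from a ``SPECIES|gene`` identifier."""
    if "|" not in gene_id:
        raise ValueError(
            f"gene id {gene_id!r} does not follow the 'SPECIES|gene' convention "
            "and no gene-to-species map was supplied"
        )
    species = gene_id.split("|", 1)[0]
    if not species:
        raise ValueError(f"gene id {gene_id!r} has an empty species prefix")
    return species


class OrthologyGraph:
    """Undirected graph over genes with optional positive edge weights.

    Nodes carry their species as an attribute; edges are deduplicated and
    symmetric by construction.  Self-loops and non-positive weights are
    rejected at insertion time.
    """

    def __init__(self) -> None:
        self._g = nx.Graph()

    # -- construction ----------------------------------------------------

    def add_gene(self, gene_id: str, species_id: str) -> None:
        if not species_id:
            raise ValueError(f"gene {gene_id!r}: species id must be non-empty")
        existing = self._g.nodes.get(gene_id)
        if existing is not None and existing["species"] != species_id:
            raise ValueError(
                f"gene {gene_id!r} registered with conflicting species "
                f"{existing['species']!r} and {species_id!r}"
            )
        self._g.add_node(gene_id, species=species_id)

    def add_edge(self, a: str, b: str, weight: float | None = None) -> None:
        if a == b:
            raise ValueError(f"self-loop on gene {a!r} is not a valid orthology relation")
        for g in (a, b):
            if g not in self._g:
                raise KeyError(f"unknown gene {g!r}; add genes before edges")
        if weight is not None and not weight > 0:
            raise ValueError(f"edge {a!r}-{b!r}: weight must be strictly positive, got {weight}")
        if self._g.has_edge(a, b):
            old = self._g.edges[a, b].get("weight")
            if old is not None and weight is not None and old != weight:
                raise ValueError(
                    f"duplicate edge {a!r}-{b!r} with conflicting weights {old} and {weight}"
                )
            if weight is None:
                return
        if weight is None:
            self._g.add_edge(a, b)
        else:
            self._g.add_edge(a, b, weight=float(weight))

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str] | tuple[str, str, float | None]],
        species_of: Mapping[str, str] | Callable[[str], str] = species_from_gene_id,
    ) -> "OrthologyGraph":
        resolve = species_of.__getitem__ if isinstance(species_of, Mapping) else species_of
        g = cls()
        for row in edges:
            a, b = row[0], row[1]
            w = row[2] if len(row) > 2 else None
            for gene in (a, b):
                if gene not in g._g:
                    g.add_gene(gene, resolve(gene))
            g.add_edge(a, b, w)
        return g

    def copy(self) -> "OrthologyGraph":
        out = OrthologyGraph()
        out._g = self._g.copy()
        return out

    # -- inspection ------------------------------------------------------

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self._g.nodes)

    @property
    def n_genes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def species_of(self, gene_id: str) -> str:
        return self._g.nodes[gene_id]["species"]

    @property
    def species(self) -> frozenset[str]:
        return frozenset(d["species"] for _, d in self._g.nodes(data=True))

    def edges(self) -> Iterator[tuple[str, str]]:
        """Edges as sorted (a, b) pairs, in deterministic sorted order."""
        yield from sorted(tuple(sorted(e)) for e in self._g.edges)

    def has_edge(self, a: str, b: str) -> bool:
        return self._g.has_edge(a, b)

    def weight(self, a: str, b: str, default: float = 1.0) -> float:
        """Weight of edge a-b; unweighted edges report ``default``."""
        return self._g.edges[a, b].get("weight", default)

    def degree(self, gene_id: str) -> int:
        return self._g.degree[gene_id]

    def neighbors(self, gene_id: str) -> set[str]:
        return set(self._g.neighbors(gene_id))

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OrthologyGraph):
            return NotImplemented
        if self.genes != other.genes:
            return False
        mine = {e: self._g.edges[e].get("weight") for e in self.edges()}
        theirs = {e: other._g.edges[e].get("weight") for e in other.edges()}
        if mine != theirs:
            return False
        return all(self.species_of(g) == other.species_of(g) for g in self.genes)

    def __repr__(self) -> str:  # pragma: no cover
        return f"OrthologyGraph({self.n_genes} genes, {self.n_edges} edges)"

    # -- operations ------------------------------------------------------

    def induced_subgraph(
        self, species: Iterable[str], drop_singletons: bool = False
    ) -> "OrthologyGraph":
        """Subgraph on genes whose species lies in ``species``.

        Keeps an edge only when both endpoints survive; weights are
        preserved.  With ``drop_singletons`` genes isolated in the result
        are removed, matching the strict no-singleton contract.
        """
        species = set(species)
        if not species:
            raise ValueError("species set must be non-empty")
        keep = [g for g, d in self._g.nodes(data=True) if d["species"] in species]
        out = OrthologyGraph()
        out._g = self._g.subgraph(keep).copy()
        if drop_singletons:
            out._drop_singletons_inplace()
        return out

    def subgraph_on_genes(self, genes: Iterable[str]) -> "OrthologyGraph":
        out = OrthologyGraph()
        out._g = self._g.subgraph(set(genes)).copy()
        return out

    def drop_singletons(self) -> "OrthologyGraph":
        out = self.copy()
        out._drop_singletons_inplace()
        return out

    def _drop_singletons_inplace(self) -> None:
        isolated = [g for g in self._g.nodes if self._g.degree[g] == 0]
        self._g.remove_nodes_from(isolated)

    def connected_components(self) -> list["OrthologyGraph"]:
        """Maximal connected subgraphs over non-singleton genes.

        Components are ordered by their smallest gene id so the output is
        deterministic.
        """
        comps = []
        for nodes in nx.connected_components(self._g):
            if len(nodes) < 2:
                continue
            comps.append(self.subgraph_on_genes(nodes))
        comps.sort(key=lambda c: min(c.genes))
        return comps

    def is_connected(self) -> bool:
        return self.n_genes > 0 and nx.is_connected(self._g)

    def diameter(self) -> int:
        """Exact graph diameter by all-pairs BFS (connected graphs only)."""
        return nx.diameter(self._g)

    def to_networkx(self) -> nx.Graph:
        """Read-only view of the underlying networkx graph."""
        return self._g


def read_orthology_graph(
    path: str | Path,
    species_map: str | Path | Mapping[str, str] | None = None,
) -> OrthologyGraph:
    """Read an orthology graph from a tab/whitespace-separated edge list.

    Each non-comment row holds ``gene1 gene2 [weight]``.  Species are
    resolved either through ``species_map`` (a two-column gene/species file
    or an in-memory mapping) or, by default, from the ``SPECIES|gene``
    naming convention.
    """
    path = Path(path)
    if isinstance(species_map, (str, Path)):
        species_map = _read_species_map(species_map)
    resolve: Callable[[str], str]
    if species_map is None:
        resolve = species_from_gene_id
    else:
        def resolve(gene_id: str, _m=species_map) -> str:
            try:
                return _m[gene_id]
            except KeyError:
                raise ValueError(f"gene {gene_id!r} missing from the gene-to-species map") from None

    g = OrthologyGraph()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) not in (2, 3):
                raise ValueError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(fields)}"
                )
            a, b = fields[0], fields[1]
            weight = None
            if len(fields) == 3:
                try:
                    weight = float(fields[2])
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: weight {fields[2]!r} is not a number"
                    ) from None
            try:
                for gene in (a, b):
                    if gene not in g:
                        g.add_gene(gene, resolve(gene))
                g.add_edge(a, b, weight)
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    logger.info("read %d genes and %d edges from %s", g.n_genes, g.n_edges, path)
    return g


def write_orthology_graph(g: OrthologyGraph, path: str | Path) -> None:
    """Write the edge list as TSV (gene1, gene2[, weight]), sorted."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# gene1\tgene2\tweight\n")
        for a, b in g.edges():
            w = g.to_networkx().edges[a, b].get("weight")
            if w is None:
                fh.write(f"{a}\t{b}\n")
            else:
                fh.write(f"{a}\t{b}\t{w:g}\n")


def _read_species_map(path: str | Path) -> dict[str, str]:
    mapping: dict[str, str] = {}
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'gene species', got {line!r}")
            gene, species = fields
            if gene in mapping and mapping[gene] != species:
                raise ValueError(f"{path}:{lineno}: conflicting species for gene {gene!r}")
            mapping[gene] = species
    return mapping
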