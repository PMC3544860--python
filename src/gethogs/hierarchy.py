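"""Hierarchies of orthologous groups, nested along the species tree.

For every internal species-tree node (taxonomic range) the hierarchy holds a
list of groups — disjoint sets of at least two genes from species inside the
range — and each non-root group records the group at the parent range that
contains it.  Group ids are dot-separated nesting paths ("3", "3.1",
"3.1.2"), so the parent/child invariant is checkable from the ids alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

from .speciestree import RangeKey, SpeciesTree

__all__ = ["HogGroup", "HogHierarchy", "write_hog_hierarchy", "read_hog_hierarchy"]

RANGE_SEP = ","


@dataclass(frozen=True)
class HogGroup:
    group_id: str
    range_key: RangeKey
    genes: frozenset[str]
    parent_id: str | None = None


class HogHierarchy:
    """Per-range partition of genes into nested orthologous groups."""

    def __init__(self) -> None:
        self._by_range: dict[RangeKey, list[HogGroup]] = {}
        self._by_id: dict[str, HogGroup] = {}
        self._top_counter = 0
        self._child_counters: dict[str, int] = {}

    # -- construction ----------------------------------------------------

    def add_group(
        self,
        range_key: RangeKey,
        genes: frozenset[str] | set[str],
        parent_id: str | None = None,
        group_id: str | None = None,
    ) -> HogGroup:
        genes = frozenset(genes)
        if len(genes) < 2:
            raise ValueError(f"a group needs at least 2 genes, got {sorted(genes)}")
        if parent_id is not None:
            parent = self._by_id.get(parent_id)
            if parent is None:
                raise KeyError(f"unknown parent group {parent_id!r}")
            if not genes <= parent.genes:
                raise ValueError(
                    f"group {sorted(genes)} is not a subset of its parent "
                    f"group {parent_id!r}"
                )
        if group_id is None:
            if parent_id is None:
                self._top_counter += 1
                group_id = str(self._top_counter)
            else:
                n = self._child_counters.get(parent_id, 0) + 1
                self._child_counters[parent_id] = n
                group_id = f"{parent_id}.{n}"
        if group_id in self._by_id:
            raise ValueError(f"duplicate group id {group_id!r}")
        for other in self._by_range.get(tuple(range_key), []):
            if other.genes & genes:
                raise ValueError(
                    f"groups at range {range_key} overlap: {other.group_id!r} "
                    f"and {group_id!r}"
                )
        group = HogGroup(group_id, tuple(range_key), genes, parent_id)
        self._by_range.setdefault(group.range_key, []).append(group)
        self._by_id[group_id] = group
        return group

    # -- inspection ------------------------------------------------------

    def groups_at(self, range_key: RangeKey) -> list[HogGroup]:
        return list(self._by_range.get(tuple(range_key), []))

    def all_groups(self) -> Iterator[HogGroup]:
        for key in sorted(self._by_range):
            yield from self._by_range[key]

    def ranges(self) -> list[RangeKey]:
        return sorted(self._by_range)

    @property
    def n_groups(self) -> int:
        return len(self._by_id)

    def group(self, group_id: str) -> HogGroup:
        return self._by_id[group_id]

    def gene_to_group_at(self, range_key: RangeKey) -> dict[str, str]:
        """Map gene -> group_id for one range (genes absent map to nothing)."""
        return {
            g: grp.group_id
            for grp in self._by_range.get(tuple(range_key), [])
            for g in grp.genes
        }

    def as_nested_sets(self) -> dict[RangeKey, frozenset[frozenset[str]]]:
        """Structure-only view: per range, the set of group gene-sets."""
        return {
            key: frozenset(grp.genes for grp in groups)
            for key, groups in self._by_range.items()
        }

    def parent_links(self) -> set[tuple[frozenset[str], frozenset[str]]]:
        """(child gene-set, parent gene-set) pairs, id-free for comparisons."""
        out = set()
        for grp in self.all_groups():
            if grp.parent_id is not None:
                out.add((grp.genes, self._by_id[grp.parent_id].genes))
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HogHierarchy):
            return NotImplemented
        return (
            self.as_nested_sets() == other.as_nested_sets()
            and self.parent_links() == other.parent_links()
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"HogHierarchy({self.n_groups} groups over {len(self._by_range)} ranges)"

    # -- validation ------------------------------------------------------

    def validate(self, species_tree: SpeciesTree | None = None) -> None:
        """Check the structural invariants, raising on the first violation."""
        for key, groups in self._by_range.items():
            seen: set[str] = set()
            for grp in groups:
                if len(grp.genes) < 2:
                    raise AssertionError(f"group {grp.group_id} has <2 genes")
                if seen & grp.genes:
                    raise AssertionError(f"overlapping groups at range {key}")
                seen |= grp.genes
        for grp in self.all_groups():
            if grp.parent_id is not None:
                parent = self._by_id[grp.parent_id]
                if not grp.genes <= parent.genes:
                    raise AssertionError(
                        f"group {grp.group_id} not nested in parent {parent.group_id}"
                    )
                if not set(grp.range_key) < set(parent.range_key):
                    raise AssertionError(
                        f"group {grp.group_id}: range is not strictly inside "
                        f"the parent range"
                    )
        if species_tree is not None:
            for key in self._by_range:
                node = species_tree.node_for_range(key)  # raises if unknown
                assert node.range_key == key


def write_hog_hierarchy(h: HogHierarchy, path: str | Path) -> tuple[Path, Path]:
    """Write a hierarchy as (i) a flat TSV and (ii) a nested JSON tree.

    The TSV has columns range_id, group_id, gene_id with the range encoded
    as the comma-joined sorted species tuple; the JSON mirrors the nesting
    through ``children`` lists.  ``read_hog_hierarchy`` round-trips the TSV.
    """
    path = Path(path)
    tsv_path = path.with_suffix(".tsv") if path.suffix != ".tsv" else path
    json_path = tsv_path.with_suffix(".json")
    tsv_path.parent.mkdir(parents=True, exist_ok=True)

    with tsv_path.open("w") as fh:
        fh.write("range_id\tgroup_id\tgene_id\n")
        for grp in h.all_groups():
            range_id = RANGE_SEP.join(grp.range_key)
            for gene in sorted(grp.genes):
                fh.write(f"{range_id}\t{grp.group_id}\t{gene}\n")

    def node_dict(grp: HogGroup) -> dict:
        children = [g for g in h.all_groups() if g.parent_id == grp.group_id]
        return {
            "group_id": grp.group_id,
            "range": list(grp.range_key),
            "genes": sorted(grp.genes),
            "children": [node_dict(c) for c in children],
        }

    roots = [g for g in h.all_groups() if g.parent_id is None]
    with json_path.open("w") as fh:
        json.dump([node_dict(g) for g in roots], fh, indent=1)
        fh.write("\n")
    return tsv_path, json_path


def read_hog_hierarchy(path: str | Path) -> HogHierarchy:
    """Read a hierarchy back from the flat TSV written by the writer."""
    rows: list[tuple[str, str, str]] = []
    with Path(path).open() as fh:
        header = fh.readline()
        if not header.startswith("range_id"):
            raise ValueError(f"{path}: missing range_id/group_id/gene_id header")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            rows.append((fields[0], fields[1], fields[2]))

    by_group: dict[str, tuple[RangeKey, set[str]]] = {}
    for range_id, group_id, gene in rows:
        key = tuple(sorted(range_id.split(RANGE_SEP)))
        entry = by_group.setdefault(group_id, (key, set()))
        if entry[0] != key:
            raise ValueError(f"{path}: group {group_id!r} spans two ranges")
        entry[1].add(gene)

    h = HogHierarchy()
    # parents first: dot-path ids sort parents before children by depth
    for group_id in sorted(by_group, key=lambda gid: (gid.count("."), _numeric_path(gid))):
        key, genes = by_group[group_id]
        parent_id = group_id.rsplit(".", 1)[0] if "." in group_id else None
        h.add_group(key, genes, parent_id=parent_id, group_id=group_id)
    # keep auto-id counters consistent with what was read
    tops = [int(g) for g in by_group if g.isdigit()]
    h._top_counter = max(tops, default=0)
    return h


def _numeric_path(group_id: str) -> tuple[int, ...]:
    return tuple(int(p) for p in group_id.split("."))
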