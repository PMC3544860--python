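"""Pairwise ortholog/paralog relation sets — the evaluation currency."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["Pair", "pair", "RelationSet", "read_relations", "write_relations"]

Pair = tuple[str, str]


def pair(a: str, b: str) -> Pair:
    """Canonical unordered gene pair."""
    if a == b:
        raise ValueError(f"a gene cannot be related to itself: {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass
class RelationSet:
    """Disjoint sets of unordered gene pairs labelled ortholog or paralog."""

    orthologs: set[Pair] = field(default_factory=set)
    paralogs: set[Pair] = field(default_factory=set)

    def add_ortholog(self, a: str, b: str) -> None:
        self.orthologs.add(pair(a, b))

    def add_paralog(self, a: str, b: str) -> None:
        self.paralogs.add(pair(a, b))

    def validate(self) -> None:
        overlap = self.orthologs & self.paralogs
        if overlap:
            raise AssertionError(f"pairs labelled both ortholog and paralog: {sorted(overlap)[:5]}")

    @property
    def n_relations(self) -> int:
        return len(self.orthologs) + len(self.paralogs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RelationSet):
            return NotImplemented
        return self.orthologs == other.orthologs and self.paralogs == other.paralogs


def write_relations(rel: RelationSet, path: str | Path) -> None:
    """Write as TSV: gene1, gene2, label (sorted, deterministic)."""
    with Path(path).open("w") as fh:
        fh.write("gene1\tgene2\tlabel\n")
        rows = [(a, b, "ortholog") for a, b in rel.orthologs]
        rows += [(a, b, "paralog") for a, b in rel.paralogs]
        for a, b, label in sorted(rows):
            fh.write(f"{a}\t{b}\t{label}\n")


def read_relations(path: str | Path) -> RelationSet:
    rel = RelationSet()
    with Path(path).open() as fh:
        header = fh.readline()
        if not header.startswith("gene1"):
            raise ValueError(f"{path}: missing gene1/gene2/label header")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            a, b, label = fields
            if label == "ortholog":
                rel.add_ortholog(a, b)
            elif label == "paralog":
                rel.add_paralog(a, b)
            else:
                raise ValueError(f"{path}:{lineno}: unknown relation label {label!r}")
    rel.validate()
    return rel
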