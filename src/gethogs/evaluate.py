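"""Precision/recall of pairwise relations induced by a group hierarchy.

A hierarchy implies pairwise relations: two genes co-occurring in at least
one group are related; a cross-species pair is orthologous exactly when the
two genes share a group at the taxonomic range that is the LCA of their two
species, and paralogous otherwise (different groups at that range, or
absent there but co-grouped at an ancestral range).  Two genes of the same
species can never be orthologs, so co-grouped within-species pairs are
paralogs.  These induced relations are compared to the truth as precision
TP/(TP+FP) and recall TP/(TP+FN), per relation type.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Mapping

from .hierarchy import HogHierarchy
from .relations import Pair, RelationSet
from .speciestree import SpeciesTree

__all__ = ["PrecisionRecall", "induced_relations", "precision_recall"]


@dataclass(frozen=True)
class PrecisionRecall:
    """Counts plus the two derived rates for one relation type."""

    tp: int
    fp: int
    fn: int
    precision: float | None
    recall: float | None

    @classmethod
    def from_counts(
        cls, tp: int, fp: int, fn: int, vacuous: float | None = 1.0
    ) -> "PrecisionRecall":
        """``vacuous`` is reported when a denominator is empty (default 1.0:
        an empty prediction set makes no mistake; pass None for 'undefined')."""
        precision = tp / (tp + fp) if tp + fp else vacuous
        recall = tp / (tp + fn) if tp + fn else vacuous
        return cls(tp, fp, fn, precision, recall)


def induced_relations(
    h: HogHierarchy,
    species_tree: SpeciesTree,
    species_of: Mapping[str, str] | None = None,
    include_within_species: bool = True,
) -> RelationSet:
    """Pairwise ortholog/paralog relations implied by a hierarchy.

    ``species_of`` may override the ``SPECIES|gene`` naming convention.
    ``include_within_species=False`` drops same-species (paralog) pairs,
    for protocols that score only cross-species relations.
    """
    if species_of is None:
        from .orthograph import species_from_gene_id as _sp

        def lookup(gene: str) -> str:
            return _sp(gene)
    else:
        lookup = species_of.__getitem__

    co_grouped: set[Pair] = set()
    for grp in h.all_groups():
        for a, b in combinations(sorted(grp.genes), 2):
            co_grouped.add((a, b))

    group_at_range = {key: h.gene_to_group_at(key) for key in h.ranges()}
    rel = RelationSet()
    for a, b in co_grouped:
        sa, sb = lookup(a), lookup(b)
        if sa == sb:
            if include_within_species:
                rel.add_paralog(a, b)
            continue
        lca_key = species_tree.lca(sa, sb).range_key
        at_lca = group_at_range.get(lca_key, {})
        ga, gb = at_lca.get(a), at_lca.get(b)
        if ga is not None and ga == gb:
            rel.add_ortholog(a, b)
        else:
            rel.add_paralog(a, b)
    return rel


def precision_recall(
    pred: RelationSet,
    truth: RelationSet,
    relation: Literal["ortholog", "paralog"],
    vacuous: float | None = 1.0,
) -> PrecisionRecall:
    """Compare predicted against true unordered pairs for one relation type."""
    if relation == "ortholog":
        p, t = pred.orthologs, truth.orthologs
    elif relation == "paralog":
        p, t = pred.paralogs, truth.paralogs
    else:
        raise ValueError(f"relation must be 'ortholog' or 'paralog', got {relation!r}")
    tp = len(p & t)
    return PrecisionRecall.from_counts(tp, len(p) - tp, len(t) - tp, vacuous=vacuous)
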