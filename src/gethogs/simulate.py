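"""Synthetic validation data: species trees, gene families, noisy graphs.

The generator emulates the validation design for graph-based hierarchical
group inference: a species tree sampled from a birth-death process and, for
each gene family, a single ancestral gene evolving down that tree with
Poisson gene duplications and losses along branches.  Every speciation and
duplication is recorded as a labelled internal node of the family's gene
tree, so the forest doubles as exact ground truth.  Sequence-level
evolution is not simulated: orthology-graph noise is injected directly as
false-negative edge deletions and false-positive edge insertions with
synthetic alignment-score weights (true edges drawn from a high-mean score
distribution, spurious ones from a low-mean distribution).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import yaml
from dendropy.model import birthdeath

from .orthograph import OrthologyGraph
from .relations import RelationSet
from .speciestree import SpeciesTree, SpeciesTreeNode
from .truth import DUPLICATION, SPECIATION, Gene, GeneTreeNode, LabeledGeneForest

__all__ = [
    "WeightModel",
    "SimulationConfig",
    "PRESETS",
    "sample_species_tree",
    "simulate_gene_forest",
    "perturb_graph",
    "load_config",
]


@dataclass(frozen=True)
class WeightModel:
    """Synthetic alignment-score distributions (normal, truncated > 0)."""

    true_edge_score_mean: float = 200.0
    spurious_edge_score_mean: float = 50.0
    score_sd: float = 25.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Rates are per unit branch length; the tree height (root to leaf) is
    rescaled to ``tree_height`` time units, emulating an evolutionary
    distance scale.  ``dup_rate``/``loss_rate`` govern the per-lineage
    Poisson processes of gene duplication and loss; ``fp_rate``/``fn_rate``
    are per-pair probabilities of spurious and missing orthology calls.
    """

    n_taxa: int = 30
    species_birth_rate: float = 0.01
    species_death_rate: float = 0.001
    tree_height: float = 150.0
    n_families: int = 200
    dup_rate: float = 0.001
    loss_rate: float = 0.001
    fp_rate: float = 0.0
    fn_rate: float = 0.0
    weight_model: WeightModel = field(default_factory=WeightModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        for name in ("species_birth_rate", "species_death_rate", "tree_height",
                     "dup_rate", "loss_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("fp_rate", "fn_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")


#: Emulations of the two published simulation designs: 30 taxa, 200
#: families, tree height 150 (arbitrary units standing in for 150 PAM),
#: species death rate 0.001; "paper-low" uses equal, low duplication and
#: loss rates, "paper-high" a higher duplication rate with loss 0.005.
PRESETS: dict[str, SimulationConfig] = {
    "paper-low": SimulationConfig(dup_rate=0.001, loss_rate=0.001),
    "paper-high": SimulationConfig(dup_rate=0.005, loss_rate=0.005),
}


def load_config(path: str | Path) -> SimulationConfig:
    """Read a flat key-value (YAML) config file; unknown keys are errors."""
    data: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
    wm_fields = {f for f in WeightModel.__dataclass_fields__}
    wm_kwargs = {k: data.pop(k) for k in list(data) if k in wm_fields}
    known = set(SimulationConfig.__dataclass_fields__) - {"weight_model"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    cfg = SimulationConfig(**data)
    if wm_kwargs:
        cfg = replace(cfg, weight_model=WeightModel(**wm_kwargs))
    return cfg


# ---------------------------------------------------------------------------
# Species tree sampling
# ---------------------------------------------------------------------------


def sample_species_tree(
    config: SimulationConfig, rng: np.random.Generator
) -> SpeciesTree:
    """Birth-death species tree conditioned on ``n_taxa`` extant leaves.

    The constant-rate birth-death process is run until the required number
    of surviving lineages, extinct lineages are pruned, leaf labels are
    assigned deterministically (S01, S02, ...) and branch lengths are
    rescaled so the root-to-leaf height equals ``config.tree_height``.
    """
    pyrng = random.Random(int(rng.integers(1 << 31)))
    last_err: Exception | None = None
    for _ in range(50):
        try:
            dtree = birthdeath.birth_death_tree(
                birth_rate=config.species_birth_rate,
                death_rate=config.species_death_rate,
                num_extant_tips=config.n_taxa,
                rng=pyrng,
                repeat_until_success=False,
            )
            break
        except Exception as err:  # total extinction; retry with same stream
            last_err = err
    else:
        raise RuntimeError(
            f"birth-death simulation went extinct 50 times in a row: {last_err}"
        )
    tree = SpeciesTree.from_dendropy(dtree)
    # deterministic relabelling in leaf appearance order
    width = max(2, len(str(config.n_taxa)))
    for i, leaf in enumerate(tree.leaf_nodes(), start=1):
        leaf.label = f"S{i:0{width}d}"
    _rescale_height(tree, config.tree_height)
    return SpeciesTree(tree.root)  # re-finalise indices with new labels


def _rescale_height(tree: SpeciesTree, height: float) -> None:
    def depth(node: SpeciesTreeNode) -> float:
        d = 0.0
        while node.parent is not None:
            d += node.edge_length or 0.0
            node = node.parent
        return d

    current = max(depth(leaf) for leaf in tree.leaf_nodes())
    if current <= 0:
        raise ValueError("sampled species tree has zero height; cannot rescale")
    factor = height / current
    for node in tree.preorder():
        if node.edge_length is not None:
            node.edge_length *= factor
    tree.root.edge_length = None


# ---------------------------------------------------------------------------
# Gene family simulation (duplication-loss along the species tree)
# ---------------------------------------------------------------------------


def simulate_gene_forest(
    species_tree: SpeciesTree,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> LabeledGeneForest:
    """Evolve ``n_families`` independent gene families down the species tree.

    Each family starts as a single gene lineage at the species-tree root.
    At every species-tree node each surviving lineage speciates into one
    copy per child branch (a labelled speciation node); along each branch a
    lineage duplicates at rate ``dup_rate`` (labelled duplication node,
    both copies continue) and is lost at rate ``loss_rate``.  Dead
    branches are removed and unary nodes suppressed, so internal nodes of
    the returned trees always have >= 2 children.  Families with no
    surviving gene are dropped.

    Event counts and the total simulated lineage time are recorded in
    ``forest.stats`` so rate calibration can be checked against the
    realised process.
    """
    stats = {"dup_events": 0, "loss_events": 0, "lineage_time": 0.0, "lost_families": 0}
    dup, loss = config.dup_rate, config.loss_rate
    total_rate = dup + loss

    def resolve_at(snode: SpeciesTreeNode, fam: str,
                   counters: dict[str, int]) -> GeneTreeNode | None:
        """A lineage sitting at a species-tree node: speciate or terminate."""
        if snode.is_leaf:
            counters[snode.label] = counters.get(snode.label, 0) + 1
            gene_id = f"{snode.label}|{fam}_g{counters[snode.label]}"
            return GeneTreeNode(gene=Gene(gene_id, snode.label))
        kids = []
        for child in snode.children:
            sub = evolve_branch(child.edge_length or 0.0, child, fam, counters)
            if sub is not None:
                kids.append(sub)
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        return GeneTreeNode(event=SPECIATION, children=kids)

    def evolve_branch(remaining: float, snode: SpeciesTreeNode, fam: str,
                      counters: dict[str, int]) -> GeneTreeNode | None:
        """One lineage travelling down a branch towards ``snode``."""
        while True:
            wait = rng.exponential(1.0 / total_rate) if total_rate > 0 else np.inf
            if wait >= remaining:
                stats["lineage_time"] += remaining
                return resolve_at(snode, fam, counters)
            stats["lineage_time"] += wait
            remaining -= wait
            if rng.random() < dup / total_rate:
                stats["dup_events"] += 1
                kids = []
                for _ in range(2):
                    sub = evolve_branch(remaining, snode, fam, counters)
                    if sub is not None:
                        kids.append(sub)
                if not kids:
                    return None
                if len(kids) == 1:
                    return kids[0]
                return GeneTreeNode(event=DUPLICATION, children=kids)
            stats["loss_events"] += 1
            return None

    trees = []
    width = len(str(config.n_families))
    for i in range(1, config.n_families + 1):
        fam = f"fam{i:0{width}d}"
        counters: dict[str, int] = {}
        root = resolve_at(species_tree.root, fam, counters)
        if root is None:
            stats["lost_families"] += 1
        else:
            trees.append(root)
    return LabeledGeneForest(trees, stats=stats)


# ---------------------------------------------------------------------------
# Graph perturbation (false positives / false negatives, synthetic weights)
# ---------------------------------------------------------------------------


def _positive_normal(mean: float, sd: float, rng: np.random.Generator) -> float:
    """Normal draw truncated to > 0 by redrawing."""
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > 0:
            return float(x)
    raise RuntimeError("weight model keeps producing non-positive scores")


def perturb_graph(
    g: OrthologyGraph,
    truth: RelationSet,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> OrthologyGraph:
    """Inject false negatives and false positives into a perfect graph.

    Every true edge is dropped independently with probability ``fn_rate``.
    False-positive candidates are the cross-species *paralog* pairs of the
    same family (same-family non-edges): each is added with probability
    ``fp_rate``.  When a weight model is configured, surviving true edges
    get scores from the high-mean distribution and spurious edges from the
    low-mean one, truncated positive.  Genes left without any edge are
    dropped, preserving the strict no-singleton contract.
    """
    wm = config.weight_model
    out = OrthologyGraph()
    for gene in sorted(g.genes):
        out.add_gene(gene, g.species_of(gene))
    for a, b in g.edges():
        if rng.random() < config.fn_rate:
            continue
        w = _positive_normal(wm.true_edge_score_mean, wm.score_sd, rng) if wm else None
        out.add_edge(a, b, w)
    candidates = sorted(
        p for p in truth.paralogs
        if p[0] in out and p[1] in out
        and g.species_of(p[0]) != g.species_of(p[1])
        and not g.has_edge(*p)
    )
    for a, b in candidates:
        if rng.random() < config.fp_rate:
            w = _positive_normal(wm.spurious_edge_score_mean, wm.score_sd, rng) if wm else None
            out.add_edge(a, b, w)
    out = out.drop_singletons()
    for a, b in out.edges():  # orthology calls are cross-species by construction
        assert out.species_of(a) != out.species_of(b)
    return out
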