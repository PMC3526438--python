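"""Duplication/loss history simulation along a species tree.

The generator produces true histories under the single-retainer
hypothesis — after every duplication exactly one copy (chosen uniformly
between source and sink) preserves the parental function — and derives
from each history the three objects a reconciliation study would touch:

* the true **phylogeny** (the history with loss leaves pruned);
* the true **isorthogroups** (retainer components of the history);
* the **gene tree** a sequence-based method would infer when functional
  constraint dominates the signal: each isorthogroup appears as a clean
  subtree whose internal topology matches the species tree restricted
  to the group's species, and groups attach outside one another in
  order of duplication age (oldest most basal).  This realizes the
  isolocalization property by construction.

Events follow a per-edge model: on each species-tree edge every gene
lineage independently acquires ``Poisson(dup_rate)`` duplications
(applied sequentially) and each resulting copy is then lost with
probability ``loss_prob``; at species nodes every surviving lineage
speciates.  A continuous-time birth-death process would realize the
same configurations; the per-edge form keeps replication trivially
reproducible from a single integer seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional

from .history import (
    DUPLICATION,
    GENE_LEAF,
    LOSS_LEAF,
    SPECIATION,
    History,
    HistoryNode,
    IsorthologyPartition,
    isorthogroups_of,
    prune_losses,
)
from .trees import GeneTree, Node, SpeciesTree

__all__ = [
    "SimConfig",
    "SimResult",
    "simulate_history",
    "derive_isolocalization_gene_tree",
    "simulate",
]


@dataclass(frozen=True)
class SimConfig:
    """Generator knobs.

    dup_rate
        Expected duplications per gene lineage per species-tree edge
        (Poisson mean).  Default 0.3: with edge-level losses this keeps
        family sizes in the handful-of-copies range typical of curated
        gene families.
    loss_prob
        Per-lineage per-edge loss probability, in [0, 1).  Default 0.2.
    seed
        Integer seed; identical configs reproduce identical histories.
    require_full_coverage
        Resample until every extant species retains at least one gene
        (the standard assumption for a gene family under study).
    max_resamples
        Attempts before giving up when coverage keeps failing.
    """

    dup_rate: float = 0.3
    loss_prob: float = 0.2
    seed: int = 0
    require_full_coverage: bool = True
    max_resamples: int = 1000

    def __post_init__(self):
        if self.dup_rate < 0:
            raise ValueError("dup_rate must be >= 0")
        if not (0 <= self.loss_prob < 1):
            raise ValueError("loss_prob must lie in [0, 1)")


@dataclass(frozen=True)
class SimResult:
    history: History
    phylogeny: GeneTree
    gene_tree: GeneTree
    isorthogroups: IsorthologyPartition
    provenance: SimConfig


class _CoverageError(RuntimeError):
    pass


def simulate_history(species_tree: SpeciesTree, config: SimConfig) -> History:
    """Sample one retainer-marked history consistent with the species tree."""
    rng = random.Random(config.seed)
    last_error: Optional[str] = None
    for _ in range(config.max_resamples):
        history = _sample_once(species_tree, rng, config)
        genes = history.gene_labels()
        if not genes:
            last_error = "gene family went extinct"
            continue
        if config.require_full_coverage:
            covered = set(history.species_of_genes().values())
            if covered != set(species_tree.species):
                last_error = "some species retained no gene"
                continue
        return history
    raise _CoverageError(
        f"no admissible history in {config.max_resamples} attempts "
        f"({last_error}); lower loss_prob or relax require_full_coverage"
    )


def _sample_once(
    species_tree: SpeciesTree, rng: random.Random, config: SimConfig
) -> History:
    counter = [0]

    def gene_label(species: str) -> str:
        counter[0] += 1
        return f"g{counter[0]}_{species}"

    def poisson(mean: float) -> int:
        # Knuth's method; means used here are small.
        if mean <= 0:
            return 0
        import math

        limit = math.exp(-mean)
        k, p = 0, 1.0
        while True:
            p *= rng.random()
            if p <= limit:
                return k
            k += 1

    def arrive(v: Node) -> HistoryNode:
        """A surviving copy reaches species node v."""
        if v.is_leaf:
            return HistoryNode(GENE_LEAF, v, gene=gene_label(v.label))
        node = HistoryNode(SPECIATION, v)
        for child in v.children:
            node.add_child(descend_edge(child))
        return node

    def edge_end(v: Node) -> HistoryNode:
        """End-of-edge fate for one copy: loss check, then arrival."""
        if rng.random() < config.loss_prob:
            return HistoryNode(LOSS_LEAF, v)
        return arrive(v)

    def descend_edge(v: Node) -> HistoryNode:
        """One copy enters the edge leading into species node v."""
        k = poisson(config.dup_rate)
        # k sequential duplications form a chain; sinks created on this
        # edge face the same end-of-edge loss but do not re-duplicate.
        def chain(remaining: int) -> HistoryNode:
            if remaining == 0:
                return edge_end(v)
            dup = HistoryNode(
                DUPLICATION, v, retainer_index=rng.randint(0, 1)
            )
            dup.add_child(chain(remaining - 1))  # the source, continuing
            dup.add_child(edge_end(v))  # the sink
            return dup

        return chain(k)

    # the single ancestral copy enters at the root (stem events allowed)
    root = descend_edge(species_tree.root)
    return History(root, species_tree)


def _duplication_age_key(history: History):
    """Total order on duplications: shallower in the event tree = older;
    ties broken by the smallest gene label under the mutant side."""

    def key(dup: HistoryNode):
        labels = sorted(
            n.gene for n in dup.mutant.postorder() if n.kind == GENE_LEAF
        )
        return (dup.depth, labels[0] if labels else "")

    return key


def derive_isolocalization_gene_tree(history: History) -> GeneTree:
    """The gene tree that sequence clustering would recover when within-
    group divergence is negligible next to between-group divergence.

    Each isorthogroup becomes a subtree congruent with the species tree
    restricted to the group's species; a group born at a duplication
    attaches as outgroup directly above the (smallest current) clade of
    its parent group, processing duplications oldest-first so that
    older offshoots end up more basal.  The between-group nesting is a
    convention: under the infinite rate-ratio abstraction the gene
    sequences carry no usable signal above the groups.
    """
    species_tree = history.species_tree
    species_of = history.species_of_genes()

    def group_subtree(genes: frozenset) -> Node:
        by_species = {species_of[g]: g for g in genes}
        root = species_tree.restricted_root(by_species)
        for leaf in root.leaves():
            leaf.label = by_species[leaf.label]
        return root

    # components and parent links
    from .history import _component_ids  # shared with isorthogroups_of

    comp = _component_ids(history)
    genes_of: dict[int, set] = {}
    for leaf in history.gene_leaves():
        genes_of.setdefault(comp[id(leaf)], set()).add(leaf.gene)

    root_cid = comp[id(history.root)]
    dups = sorted(
        (n for n in history.postorder() if n.kind == DUPLICATION),
        key=_duplication_age_key(history),
    )

    def nearest_populated(cid: int, parent_of: dict[int, int]) -> Optional[int]:
        while cid not in genes_of:
            if cid not in parent_of:
                return None
            cid = parent_of[cid]
        return cid

    parent_of: dict[int, int] = {}
    for dup in dups:
        parent_of[comp[id(dup.mutant)]] = comp[id(dup)]

    # assemble: start from the oldest populated component
    order: list[tuple[int, Optional[int]]] = []
    seen: set[int] = set()
    if root_cid in genes_of:
        order.append((root_cid, None))
        seen.add(root_cid)
    for dup in dups:
        cid = comp[id(dup.mutant)]
        if cid in genes_of and cid not in seen:
            seen.add(cid)
            parent = nearest_populated(parent_of.get(cid, root_cid), parent_of)
            order.append((cid, parent if parent != cid else None))
    if not order:
        raise ValueError("history has no gene leaves")

    base_cid, _ = order[0]
    tree_root = group_subtree(frozenset(genes_of[base_cid]))
    placed: dict[int, frozenset] = {base_cid: frozenset(genes_of[base_cid])}

    def smallest_clade_containing(root: Node, genes: frozenset) -> Node:
        node = root
        while True:
            for child in node.children:
                if genes <= child.leaf_labels():
                    node = child
                    break
            else:
                return node

    for cid, parent in order[1:]:
        sub = group_subtree(frozenset(genes_of[cid]))
        if parent is None or parent not in placed:
            target = tree_root
        else:
            target = smallest_clade_containing(tree_root, placed[parent])
        joint = Node(None)
        if target.parent is None:
            joint.add_child(target)
            joint.add_child(sub)
            tree_root = joint
        else:
            up = target.parent
            slot = up.children.index(target)
            joint.add_child(target)
            joint.add_child(sub)
            up.children[slot] = joint
            joint.parent = up
        placed[cid] = frozenset(genes_of[cid])

    return GeneTree(tree_root, species_of)


def simulate(species_tree: SpeciesTree, config: SimConfig) -> SimResult:
    """One full replicate: history, phylogeny, gene tree, isorthogroups."""
    history = simulate_history(species_tree, config)
    return SimResult(
        history=history,
        phylogeny=prune_losses(history),
        gene_tree=derive_isolocalization_gene_tree(history),
        isorthogroups=isorthogroups_of(history),
        provenance=config,
    )
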