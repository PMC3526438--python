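"""Isorthology-respecting histories (IRH).

When functional constraint makes isorthologs cluster in the gene tree
(the isolocalization property), reconciliation systematically misplaces
duplications towards the root.  The alternative developed here trusts
only the isorthology signal: a history is *isorthology respecting* for a
pair ``(G, S)`` when each of its isorthogroups is the leaf set of a
speciation subtree of ``G`` (a subtree whose internal nodes are all
labeled speciations by the LCA mapping).

The minimum-duplication IRH is governed by the forest ``F`` of maximal
speciation subtrees of ``G``: a partition into ``n`` isorthogroups needs
exactly ``n - 1`` duplications to join its blocks into a single history,
and the coarsest admissible partition is given by ``F``.  Hence the
minimum duplication cost is ``|F| - 1``, computable in linear time.
"""

from __future__ import annotations

import itertools
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
from .reconciliation import LcaMap, lca_mapping
from .trees import GeneTree, Node, SpeciesTree, TreeError

__all__ = [
    "Forest",
    "speciation_forest",
    "mirh_duplication_cost",
    "build_mirh",
    "check_isolocalization",
    "validate_irh",
    "validate_trh",
    "brute_force_mirh",
]


class Forest:
    """The ordered maximal speciation subtrees of a labeled gene tree."""

    def __init__(self, gene_tree: GeneTree, roots: list[Node], lmap: LcaMap):
        self.gene_tree = gene_tree
        self.roots = roots
        self.lmap = lmap
        self.blocks: list[frozenset] = [r.leaf_labels() for r in roots]

    def __len__(self) -> int:
        return len(self.roots)

    def partition(self) -> IsorthologyPartition:
        return IsorthologyPartition(self.blocks)

    def __repr__(self) -> str:
        inner = ", ".join("{" + ",".join(sorted(b)) + "}" for b in self.blocks)
        return f"Forest([{inner}])"


def speciation_forest(gene_tree: GeneTree, species_tree: SpeciesTree) -> Forest:
    """Decompose ``G`` into its maximal speciation subtrees.

    Three linear passes: (1) label nodes by the LCA mapping; (2) mark
    every ancestor of a duplication in postorder; (3) collect as forest
    roots the unmarked non-duplication nodes whose parent is a
    duplication or an ancestor of one (the whole tree when no
    duplication exists).  Leaves count as trivial speciation subtrees.
    """
    lmap = lca_mapping(gene_tree, species_tree)
    anc_of_dup: set[int] = set()
    for node in gene_tree.postorder():
        if node.is_leaf:
            continue
        if any(
            lmap.is_duplication(c) or id(c) in anc_of_dup for c in node.children
        ):
            anc_of_dup.add(id(node))

    def excluded(node: Node) -> bool:
        return (not node.is_leaf and lmap.is_duplication(node)) or id(node) in anc_of_dup

    roots: list[Node] = []
    for node in gene_tree.preorder():
        if excluded(node):
            continue
        if node.parent is None or excluded(node.parent):
            roots.append(node)
    # preorder guarantees maximality: a collected node's ancestors are all
    # excluded, so nothing below an earlier root is revisited as a root.
    roots = [r for r in roots if r.parent is None or excluded(r.parent)]
    return Forest(gene_tree, roots, lmap)


def mirh_duplication_cost(gene_tree: GeneTree, species_tree: SpeciesTree) -> int:
    """Duplication cost of a minimum isorthology-respecting history:
    ``|F| - 1`` for the maximal speciation-subtree forest ``F``."""
    return len(speciation_forest(gene_tree, species_tree)) - 1


# ---------------------------------------------------------------------------
# Validators
# ---------------------------------------------------------------------------


def check_isolocalization(
    gene_tree: GeneTree, partition: IsorthologyPartition
) -> Optional[tuple[str, str, str]]:
    """Check the isolocalization property of ``G`` against a partition.

    Returns ``None`` when, for every pair of same-block genes, the
    subtree they span contains only genes of that block; otherwise a
    witness ``(a1, a2, offender)`` where the subtree spanned by ``a1``
    and ``a2`` contains the foreign gene ``offender``.
    """
    if partition.genes != gene_tree.genes:
        raise TreeError("partition does not cover the gene tree leaves")
    for block in partition.blocks:
        if len(block) < 2:
            continue
        top = gene_tree.lca(block)
        spanned = top.leaf_labels()
        foreign = spanned - block
        if not foreign:
            continue
        # exhibit a concrete violating pair: two block genes on opposite
        # sides of the shallowest node (below `top`) covering a foreigner.
        offender = min(foreign)
        left, right = top.children
        in_left = block & left.leaf_labels()
        in_right = block & right.leaf_labels()
        a1 = min(in_left) if in_left else min(block)
        a2 = min(in_right) if in_right else max(block)
        return (a1, a2, offender)
    return None


def _speciation_subtree_blocks(
    gene_tree: GeneTree, lmap: LcaMap
) -> set[frozenset]:
    """Leaf sets of all (not only maximal) speciation subtrees of G."""
    ok: set[frozenset] = set()
    clean: dict[int, bool] = {}
    for node in gene_tree.postorder():
        if node.is_leaf:
            clean[id(node)] = True
        else:
            clean[id(node)] = not lmap.is_duplication(node) and all(
                clean[id(c)] for c in node.children
            )
        if clean[id(node)]:
            ok.add(node.leaf_labels())
    return ok


def validate_irh(
    history: History, gene_tree: GeneTree, species_tree: SpeciesTree
) -> bool:
    """Is ``history`` an isorthology-respecting history for ``(G, S)``?

    True iff every isorthogroup induced by the (retainer-marked) history
    is the leaf set of a speciation subtree of ``G``.
    """
    if history.gene_labels() != gene_tree.genes:
        raise TreeError("history and gene tree have different gene sets")
    partition = isorthogroups_of(history)
    lmap = lca_mapping(gene_tree, species_tree)
    admissible = _speciation_subtree_blocks(gene_tree, lmap)
    return all(block in admissible for block in partition.blocks)


def _triplet_shape(tree: GeneTree, a: str, b: str, c: str) -> frozenset:
    """The cherry of the rooted triplet on {a, b, c} (as a frozenset)."""
    sub = tree.restricted_root({a, b, c})
    for child in sub.children:
        labels = child.leaf_labels()
        if len(labels) == 2:
            return labels
    raise TreeError("restricted triplet is not binary")


def validate_trh(
    history: History, gene_tree: GeneTree, species_tree: SpeciesTree
) -> bool:
    """Is ``history`` a triplet-respecting history for ``(G, S)``?

    Requires the IRH property, and additionally that for every triplet
    of genes drawn from three distinct isorthogroups the gene tree and
    the loss-pruned history agree on the rooted triplet topology.
    Instances with fewer than three isorthogroups satisfy the triplet
    clause vacuously.
    """
    if not validate_irh(history, gene_tree, species_tree):
        return False
    partition = isorthogroups_of(history)
    if len(partition) < 3:
        return True
    pruned = prune_losses(history)
    for blocks in itertools.combinations(partition.blocks, 3):
        for a, b, c in itertools.product(*[sorted(b) for b in blocks]):
            if _triplet_shape(gene_tree, a, b, c) != _triplet_shape(pruned, a, b, c):
                return False
    return True


# ---------------------------------------------------------------------------
# MIRH construction
# ---------------------------------------------------------------------------


def _embed_block(
    block_root: Node,
    lmap: LcaMap,
    species_tree: SpeciesTree,
    top: Node,
) -> HistoryNode:
    """Embed a speciation subtree of G into S, starting at species node
    ``top`` (an ancestor-or-equal of the subtree's LCA-map image)."""
    target = lmap.m(block_root)
    if top is not target:
        onpath = next(c for c in top.children if species_tree.is_ancestor(c, target))
        offpath = next(c for c in top.children if c is not onpath)
        node = HistoryNode(SPECIATION, top)
        node.add_child(_embed_block(block_root, lmap, species_tree, onpath))
        node.add_child(HistoryNode(LOSS_LEAF, offpath))
        return node
    if block_root.is_leaf:
        return HistoryNode(GENE_LEAF, target, gene=block_root.label)
    node = HistoryNode(SPECIATION, target)
    for child in block_root.children:
        ctop = next(
            c for c in target.children if species_tree.is_ancestor(c, lmap.m(child))
        )
        node.add_child(_embed_block(child, lmap, species_tree, ctop))
    return node


def _min_gene_label(node: HistoryNode) -> str:
    labels = [n.gene for n in node.postorder() if n.kind == GENE_LEAF]
    return min(labels) if labels else "￿"


def _within_block_losses(block_root: Node, lmap: LcaMap, species_tree: SpeciesTree) -> int:
    """Losses forced inside one isorthogroup's copy: the species-tree
    branches its span covers but its genes do not reach."""
    total = 0
    for node in block_root.postorder():
        if node.is_leaf:
            continue
        for child in node.children:
            total += species_tree.edge_distance(lmap.m(node), lmap.m(child)) - 1
    return total


def _mutation_optimal_blocks(
    gene_tree: GeneTree, lmap: LcaMap, species_tree: SpeciesTree
) -> list[Node]:
    """Partition of G into speciation-subtree blocks minimizing
    ``(#blocks - 1) + sum of within-block losses``.

    A coarser-than-maximal block keeps duplications low but pays a loss
    for every species branch its copy spans without retaining a gene;
    splitting trades one extra duplication against those losses.  The
    recurrence walks G once: a clean subtree is either kept whole or cut
    at its root.  Ties prefer the coarser partition, so on trees where
    no split pays off this reduces to the maximal forest.
    """
    clean: dict[int, bool] = {}
    for node in gene_tree.postorder():
        if node.is_leaf:
            clean[id(node)] = True
        else:
            clean[id(node)] = not lmap.is_duplication(node) and all(
                clean[id(c)] for c in node.children
            )
    best: dict[int, tuple[int, tuple[Node, ...]]] = {}
    for node in gene_tree.postorder():
        options: list[tuple[int, tuple[Node, ...]]] = []
        if clean[id(node)]:
            options.append((1 + _within_block_losses(node, lmap, species_tree), (node,)))
        if not node.is_leaf:
            left, right = node.children
            lc, lb = best[id(left)]
            rc, rb = best[id(right)]
            options.append((lc + rc, lb + rb))
        best[id(node)] = min(options, key=lambda o: (o[0], len(o[1])))
    return list(best[id(gene_tree.root)][1])


def build_mirh(
    gene_tree: GeneTree,
    species_tree: SpeciesTree,
    cost: str = "duplication",
) -> History:
    """Construct a minimum isorthology-respecting history for ``(G, S)``.

    With ``cost="duplication"`` the isorthogroups are the maximal
    speciation-subtree forest ``F``: the duplication-optimal partition,
    giving exactly ``|F| - 1`` duplications.  With ``cost="mutation"``
    the partition itself is optimized: refining a block costs one more
    duplication but can spare the losses its over-wide copy would force
    (the coarsest partition minimizes duplications but not necessarily
    mutations).

    Either way the seed block is the one whose species-tree anchor (the
    LCA of its species) is closest to the root; each remaining block, in
    order of increasing anchor depth, is attached by a single
    duplication onto an existing lineage, at the deepest point above its
    anchor that the history already reaches.  The pre-existing lineage
    is marked retainer and the newly attached block mutant, so the
    history's isorthogroups are exactly the chosen blocks.
    """
    if cost not in ("duplication", "mutation"):
        raise ValueError(f"cost must be 'duplication' or 'mutation', got {cost!r}")
    forest = speciation_forest(gene_tree, species_tree)
    lmap = forest.lmap
    if cost == "duplication":
        return _build_from_blocks(gene_tree, species_tree, lmap, forest.roots)
    # mutation mode: the refined partition trades duplications for the
    # losses over-wide blocks force.  The estimate ignores connection
    # losses, so build both candidates and keep the cheaper history
    # (ties go to the coarser, duplication-optimal partition).
    refined = _mutation_optimal_blocks(gene_tree, lmap, species_tree)
    coarse_history = _build_from_blocks(gene_tree, species_tree, lmap, forest.roots)
    if [id(r) for r in refined] == [id(r) for r in forest.roots]:
        return coarse_history
    refined_history = _build_from_blocks(gene_tree, species_tree, lmap, refined)
    from .history import history_costs

    if history_costs(refined_history).mutation < history_costs(coarse_history).mutation:
        return refined_history
    return coarse_history


def _build_from_blocks(
    gene_tree: GeneTree,
    species_tree: SpeciesTree,
    lmap: LcaMap,
    block_roots: list[Node],
) -> History:
    def anchor(root: Node) -> Node:
        return lmap.m(root)

    ordered = sorted(
        block_roots,
        key=lambda r: (anchor(r).depth, min(r.leaf_labels())),
    )
    seed, rest = ordered[0], ordered[1:]
    root = _embed_block(seed, lmap, species_tree, anchor(seed))

    # index history nodes by species location for attachment lookups
    nodes_at: dict[int, list[HistoryNode]] = {}

    def register(hnode: HistoryNode) -> None:
        for n in hnode.postorder():
            nodes_at.setdefault(id(n.location), []).append(n)

    register(root)

    def chain_down(top: Node, target: Node, payload: HistoryNode) -> HistoryNode:
        """Speciation/loss chain from species node ``top`` to ``target``,
        ending in ``payload`` (already located at ``target``)."""
        if top is target:
            return payload
        onpath = next(c for c in top.children if species_tree.is_ancestor(c, target))
        offpath = next(c for c in top.children if c is not onpath)
        node = HistoryNode(SPECIATION, top)
        node.add_child(chain_down(onpath, target, payload))
        node.add_child(HistoryNode(LOSS_LEAF, offpath))
        return node

    for block_root in rest:
        a = anchor(block_root)
        # deepest species node on the path root..a where a lineage exists
        host_loc = a
        while host_loc is not None and id(host_loc) not in nodes_at:
            host_loc = host_loc.parent
        if host_loc is None:
            # the block lies outside everything built so far: lift the
            # history with a stem duplication at the joint ancestor
            w = species_tree.lca_nodes(root.location, a)
            lifted = chain_down(w, root.location, root)
            payload = _embed_block(block_root, lmap, species_tree, a)
            graft = chain_down(w, a, payload)
            dup = HistoryNode(DUPLICATION, w, retainer_index=0)
            dup.add_child(lifted)   # retainer: the pre-existing history
            dup.add_child(graft)    # mutant: the new block
            root = dup
            nodes_at.clear()
            register(root)
            continue
        candidates = nodes_at[id(host_loc)]
        host = min(candidates, key=_min_gene_label)
        payload = _embed_block(block_root, lmap, species_tree, a)
        graft = chain_down(host_loc, a, payload)
        dup = HistoryNode(DUPLICATION, host_loc, retainer_index=0)
        parent = host.parent
        if parent is not None:
            slot = parent.children.index(host)
        dup.add_child(host)  # retainer: the pre-existing lineage
        dup.add_child(graft)  # mutant: the new block
        if parent is None:
            root = dup
        else:
            parent.children[slot] = dup
            dup.parent = parent
        register(graft)
        nodes_at[id(host_loc)].append(dup)

    history = History(root, species_tree)
    return history


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------


def brute_force_mirh(
    gene_tree: GeneTree,
    species_tree: SpeciesTree,
    max_leaves: int = 10,
) -> tuple[int, list[IsorthologyPartition]]:
    """Enumerate every isorthology-respecting partition of ``G`` and
    return the minimum join cost with all partitions achieving it.

    Each block of an admissible partition must be the leaf set of a
    speciation subtree; joining ``n`` blocks into one history costs
    ``n - 1`` duplications.  Exponential: refuses trees above
    ``max_leaves`` leaves.  Serves as an independent oracle for the
    linear-time forest computation.
    """
    if len(gene_tree.leaf_labels) > max_leaves:
        raise TreeError(
            f"brute_force_mirh limited to {max_leaves} leaves "
            f"(got {len(gene_tree.leaf_labels)})"
        )
    lmap = lca_mapping(gene_tree, species_tree)
    clean: dict[int, bool] = {}
    for node in gene_tree.postorder():
        if node.is_leaf:
            clean[id(node)] = True
        else:
            clean[id(node)] = not lmap.is_duplication(node) and all(
                clean[id(c)] for c in node.children
            )

    def partitions(node: Node) -> list[tuple[frozenset, ...]]:
        """All ways to cut G_node into speciation-subtree blocks."""
        options: list[tuple[frozenset, ...]] = []
        if clean[id(node)]:
            options.append((node.leaf_labels(),))
        if not node.is_leaf:
            left, right = (partitions(c) for c in node.children)
            for lp in left:
                for rp in right:
                    combined = lp + rp
                    if clean[id(node)] and len(combined) == 1:
                        continue  # already covered by the whole-subtree option
                    options.append(combined)
        return options

    best = None
    witnesses: list[IsorthologyPartition] = []
    for parts in partitions(gene_tree.root):
        cost = len(parts) - 1
        if best is None or cost < best:
            best = cost
            witnesses = [IsorthologyPartition(parts)]
        elif cost == best:
            witnesses.append(IsorthologyPartition(parts))
    assert best is not None
    # deduplicate (different cut orders can yield the same partition)
    uniq: list[IsorthologyPartition] = []
    seen = set()
    for w in witnesses:
        if w.as_sets() not in seen:
            seen.add(w.as_sets())
            uniq.append(w)
    return best, uniq
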