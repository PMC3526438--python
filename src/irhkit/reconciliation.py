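"""LCA-mapping reconciliation.

The LCA mapping sends each gene-tree node to the lowest species-tree
node containing all of its leaf species.  An internal node ``x`` is a
duplication exactly when one of its children maps to the same species
node as ``x`` itself; every other internal node is a speciation.  The
induced reconciliation embeds the gene tree into the species tree,
inserting loss leaves wherever a lineage skips past a species-tree
bifurcation, and it minimizes the duplication, loss and mutation costs
over all reconciliations of the pair.
"""

from __future__ import annotations

from typing import Optional

from .history import (
    DUPLICATION,
    GENE_LEAF,
    LOSS_LEAF,
    SPECIATION,
    CostReport,
    History,
    HistoryNode,
)
from .trees import GeneTree, Node, SpeciesTree, TreeError

__all__ = ["LcaMap", "lca_mapping", "loss_count", "reconcile"]


class LcaMap:
    """The LCA mapping ``m()`` plus duplication/speciation labels."""

    def __init__(self, gene_tree: GeneTree, species_tree: SpeciesTree):
        self.gene_tree = gene_tree
        self.species_tree = species_tree
        self._m: dict[int, Node] = {}
        self._label: dict[int, str] = {}
        for node in gene_tree.postorder():
            if node.is_leaf:
                species = gene_tree.species_of[node.label]
                try:
                    self._m[id(node)] = species_tree.node_for(species)
                except TreeError:
                    raise TreeError(
                        f"species {species!r} of gene {node.label!r} is absent "
                        "from the species tree"
                    ) from None
            else:
                left, right = node.children
                m = species_tree.lca_nodes(self._m[id(left)], self._m[id(right)])
                self._m[id(node)] = m
                is_dup = self._m[id(left)] is m or self._m[id(right)] is m
                self._label[id(node)] = DUPLICATION if is_dup else SPECIATION

    def m(self, node: Node) -> Node:
        return self._m[id(node)]

    def label(self, node: Node) -> str:
        """``duplication`` or ``speciation`` for an internal gene-tree node."""
        return self._label[id(node)]

    def is_duplication(self, node: Node) -> bool:
        return self._label.get(id(node)) == DUPLICATION

    def duplication_nodes(self) -> list[Node]:
        return [
            n
            for n in self.gene_tree.postorder()
            if self._label.get(id(n)) == DUPLICATION
        ]

    def labels_by_leafset(self) -> dict[frozenset, str]:
        """Convenience view keyed by clade leaf sets (for reports)."""
        out = {}
        for node in self.gene_tree.postorder():
            if not node.is_leaf:
                out[node.leaf_labels()] = self._label[id(node)]
        return out


def lca_mapping(gene_tree: GeneTree, species_tree: SpeciesTree) -> LcaMap:
    """Compute the LCA mapping and the duplication/speciation labeling."""
    return LcaMap(gene_tree, species_tree)


def loss_count(
    lmap: LcaMap,
    gene_tree: Optional[GeneTree] = None,
    species_tree: Optional[SpeciesTree] = None,
) -> int:
    """Loss cost of the LCA reconciliation, by the per-edge rule.

    For every gene-tree edge (u, v) with ``d = dist_S(m(u), m(v))`` the
    edge contributes ``d - 1`` losses when u is a speciation and ``d``
    when u is a duplication.  This equals the number of loss leaves that
    explicit embedding inserts (a lineage lost before further speciation
    counts once).
    """
    gene_tree = gene_tree or lmap.gene_tree
    species_tree = species_tree or lmap.species_tree
    total = 0
    for node in gene_tree.postorder():
        if node.is_leaf:
            continue
        mu = lmap.m(node)
        dup = lmap.is_duplication(node)
        for child in node.children:
            d = species_tree.edge_distance(mu, lmap.m(child))
            total += d if dup else d - 1
    return total


def reconcile(
    gene_tree: GeneTree, species_tree: SpeciesTree
) -> tuple[History, CostReport]:
    """Build the LCA reconciliation as an explicit history.

    The returned history prunes back to the gene tree, its duplication
    nodes are exactly the LCA-map duplications, and loss leaves are
    inserted so that the event tree is consistent with the species tree.
    Retainer/mutant marks are *not* assigned: a reconciliation carries no
    functional information.
    """
    lmap = lca_mapping(gene_tree, species_tree)

    def embed(x: Node, top: Node) -> HistoryNode:
        """History subtree for gene node x, whose lineage starts at
        species node ``top`` (an ancestor-or-equal of m(x))."""
        target = lmap.m(x)
        if top is not target:
            # walk one species edge towards the target; the sibling copy
            # of this speciation is lost.
            onpath = next(c for c in top.children if species_tree.is_ancestor(c, target))
            offpath = next(c for c in top.children if c is not onpath)
            node = HistoryNode(SPECIATION, top)
            node.add_child(embed(x, onpath))
            node.add_child(HistoryNode(LOSS_LEAF, offpath))
            return node
        if x.is_leaf:
            return HistoryNode(GENE_LEAF, target, gene=x.label)
        if lmap.is_duplication(x):
            node = HistoryNode(DUPLICATION, target)
            for child in x.children:
                node.add_child(embed(child, target))
            return node
        node = HistoryNode(SPECIATION, target)
        for child in x.children:
            ctop = next(
                c for c in target.children if species_tree.is_ancestor(c, lmap.m(child))
            )
            node.add_child(embed(child, ctop))
        return node

    root = embed(gene_tree.root, lmap.m(gene_tree.root))
    history = History(root, species_tree)
    dups = sum(1 for n in history.postorder() if n.kind == DUPLICATION)
    losses = sum(1 for n in history.postorder() if n.kind == LOSS_LEAF)
    return history, CostReport(duplications=dups, losses=losses)
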