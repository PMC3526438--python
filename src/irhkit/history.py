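"""Explicit duplication/loss/speciation histories.

A history is a rooted binary event tree describing the evolution of a
gene family from a single ancestral copy.  Every node carries an event
kind and a *location*: the species-tree node where the event takes
place.  The location invariants are:

* a **speciation** node at species node ``v`` has two children located at
  the two species children of ``v``;
* a **duplication** node at ``v`` has both children located at ``v``;
* a **gene leaf** is located at a species leaf;
* a **loss leaf** may sit at any species node — a loss at an internal
  node records the loss of a whole lineage copy before any further
  speciation, and counts as a single loss event.

Duplication nodes may carry a retainer/mutant assignment: exactly one
child preserves the parental function (the retainer), the other does not
(the mutant).  This is the information needed to read isorthogroups off
a history; operations that need it refuse to run on unmarked histories
rather than guess.

Histories serialize to annotated Newick, with per-node bracket comments
``[&kind=...,loc=...,retainer=...]``; locations of internal species
nodes are written as the ``+``-joined set of species labels below them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import dendropy

from .trees import GeneTree, Node, SpeciesTree

__all__ = [
    "HistoryError",
    "HistoryNode",
    "History",
    "CostReport",
    "IsorthologyPartition",
    "validate_consistency",
    "prune_losses",
    "history_costs",
    "isorthogroups_of",
    "surviving_nodes",
    "confounding_condition",
    "parse_history",
]

SPECIATION = "speciation"
DUPLICATION = "duplication"
GENE_LEAF = "gene_leaf"
LOSS_LEAF = "loss_leaf"

_KINDS = (SPECIATION, DUPLICATION, GENE_LEAF, LOSS_LEAF)


class HistoryError(ValueError):
    """Raised for structurally unusable histories."""


@dataclass(frozen=True)
class CostReport:
    """Event counts of a history: the three parsimony criteria."""

    duplications: int
    losses: int

    @property
    def mutation(self) -> int:
        return self.duplications + self.losses

    def as_dict(self) -> dict:
        return {
            "duplications": self.duplications,
            "losses": self.losses,
            "mutation": self.mutation,
        }


class IsorthologyPartition:
    """A partition of gene leaves into isorthogroups."""

    def __init__(self, blocks):
        self.blocks: list[frozenset] = [frozenset(b) for b in blocks]
        seen: set = set()
        for block in self.blocks:
            if not block:
                raise ValueError("empty isorthogroup")
            if block & seen:
                raise ValueError("isorthogroups overlap")
            seen |= block
        self.genes = frozenset(seen)

    def block_of(self, gene: str) -> frozenset:
        for block in self.blocks:
            if gene in block:
                return block
        raise KeyError(gene)

    def as_sets(self) -> frozenset:
        return frozenset(self.blocks)

    def __len__(self) -> int:
        return len(self.blocks)

    def __eq__(self, other) -> bool:
        if isinstance(other, IsorthologyPartition):
            return self.as_sets() == other.as_sets()
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.as_sets())

    def __repr__(self) -> str:
        inner = ", ".join(
            "{" + ",".join(sorted(b)) + "}"
            for b in sorted(self.blocks, key=lambda b: sorted(b))
        )
        return f"IsorthologyPartition([{inner}])"


class HistoryNode:
    __slots__ = ("kind", "location", "children", "parent", "gene", "retainer_index", "depth")

    def __init__(
        self,
        kind: str,
        location: Node,
        gene: Optional[str] = None,
        retainer_index: Optional[int] = None,
    ):
        if kind not in _KINDS:
            raise ValueError(f"unknown event kind: {kind!r}")
        self.kind = kind
        self.location = location  # a node of the companion species tree
        self.children: list["HistoryNode"] = []
        self.parent: Optional["HistoryNode"] = None
        self.gene = gene
        self.retainer_index = retainer_index  # 0/1 index into children
        self.depth = 0

    def add_child(self, child: "HistoryNode") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def retainer(self) -> "HistoryNode":
        if self.kind != DUPLICATION or self.retainer_index is None:
            raise HistoryError("retainer requested on an unmarked node")
        return self.children[self.retainer_index]

    @property
    def mutant(self) -> "HistoryNode":
        if self.kind != DUPLICATION or self.retainer_index is None:
            raise HistoryError("mutant requested on an unmarked node")
        return self.children[1 - self.retainer_index]

    def postorder(self) -> Iterator["HistoryNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["HistoryNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))


class History:
    """An event tree tied to a species tree."""

    def __init__(self, root: HistoryNode, species_tree: SpeciesTree):
        self.root = root
        self.species_tree = species_tree
        for node in self.root.preorder():
            node.depth = 0 if node.parent is None else node.parent.depth + 1

    def postorder(self) -> Iterator[HistoryNode]:
        return self.root.postorder()

    def preorder(self) -> Iterator[HistoryNode]:
        return self.root.preorder()

    def gene_leaves(self) -> list[HistoryNode]:
        return [n for n in self.postorder() if n.kind == GENE_LEAF]

    def gene_labels(self) -> frozenset:
        return frozenset(n.gene for n in self.gene_leaves())

    def species_of_genes(self) -> dict[str, str]:
        return {n.gene: n.location.label for n in self.gene_leaves()}

    @property
    def has_retainer_marks(self) -> bool:
        return all(
            n.retainer_index is not None
            for n in self.postorder()
            if n.kind == DUPLICATION
        )

    def lca(self, a: HistoryNode, b: HistoryNode) -> HistoryNode:
        while a is not b:
            if a.depth >= b.depth:
                a = a.parent
            else:
                b = b.parent
        return a

    # -- serialization -------------------------------------------------

    def _loc_token(self, location: Node) -> str:
        if location.is_leaf:
            return location.label
        return "+".join(sorted(location.leaf_labels()))

    def newick(self) -> str:
        def render(node: HistoryNode) -> str:
            parts = [f"kind={node.kind}", f"loc={self._loc_token(node.location)}"]
            if node.kind == DUPLICATION and node.retainer_index is not None:
                parts.append(f"retainer={node.retainer_index}")
            comment = "[&" + ",".join(parts) + "]"
            if node.is_leaf:
                label = node.gene if node.kind == GENE_LEAF else "LOSS"
                return f"{label}{comment}"
            inner = ",".join(render(c) for c in node.children)
            return f"({inner}){comment}"

        return render(self.root) + ";"


def parse_history(text: str, species_tree: SpeciesTree) -> History:
    """Read an annotated-Newick history written by :meth:`History.newick`."""
    dtree = dendropy.Tree.get(
        data=text,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
        suppress_leaf_node_taxa=True,  # loss leaves all carry the label LOSS
        extract_comment_metadata=False,
    )

    def node_comment(dnode) -> dict:
        comments = list(dnode.comments)
        if dnode.taxon is not None:
            comments.extend(dnode.taxon.comments)
        for comment in comments:
            body = comment.lstrip("&")
            fields = {}
            for item in body.split(","):
                if "=" in item:
                    key, value = item.split("=", 1)
                    fields[key.strip()] = value.strip()
            if "kind" in fields:
                return fields
        raise HistoryError("history node without a [&kind=...] annotation")

    def resolve_location(token: str) -> Node:
        labels = token.split("+")
        node = species_tree.lca(labels)
        return node

    def build(dnode) -> HistoryNode:
        fields = node_comment(dnode)
        kind = fields["kind"]
        location = resolve_location(fields["loc"])
        gene = None
        if kind == GENE_LEAF:
            gene = dnode.taxon.label if dnode.taxon is not None else dnode.label
        retainer = fields.get("retainer")
        node = HistoryNode(
            kind,
            location,
            gene=gene,
            retainer_index=int(retainer) if retainer is not None else None,
        )
        for child in dnode.child_nodes():
            node.add_child(build(child))
        return node

    return History(build(dtree.seed_node), species_tree)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def validate_consistency(history: History) -> list[str]:
    """Check the location invariants; returns violations (empty if ok)."""
    violations: list[str] = []
    s = history.species_tree
    for node in history.postorder():
        loc = node.location
        where = history._loc_token(loc)
        if node.kind in (GENE_LEAF, LOSS_LEAF):
            if node.children:
                violations.append(f"{node.kind} at {where} has children")
            if node.kind == GENE_LEAF and not loc.is_leaf:
                violations.append(
                    f"gene leaf {node.gene!r} located at internal species node {where}"
                )
            continue
        if len(node.children) != 2:
            violations.append(f"{node.kind} at {where} is not binary")
            continue
        if node.kind == DUPLICATION:
            for child in node.children:
                if child.location is not loc:
                    violations.append(
                        f"duplication at {where} has a child located at "
                        f"{history._loc_token(child.location)}"
                    )
        else:  # speciation
            if loc.is_leaf:
                violations.append(f"speciation at species leaf {where}")
                continue
            child_locs = [c.location for c in node.children]
            expected = list(loc.children)
            if set(map(id, child_locs)) != set(map(id, expected)):
                violations.append(
                    f"speciation at {where} has children at "
                    f"{[history._loc_token(c) for c in child_locs]}, expected the two "
                    f"species children"
                )
    # gene labels must be unique
    labels = [n.gene for n in history.gene_leaves()]
    if len(labels) != len(set(labels)):
        violations.append("duplicate gene leaf labels")
    return violations


def prune_losses(history: History) -> GeneTree:
    """Remove loss leaves (suppressing the freed internal nodes); the
    result is the phylogeny of the extant gene family."""

    def build(node: HistoryNode) -> Optional[Node]:
        if node.kind == LOSS_LEAF:
            return None
        if node.kind == GENE_LEAF:
            return Node(node.gene)
        kept = [c for c in (build(ch) for ch in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        new = Node(None)
        for c in kept:
            new.add_child(c)
        return new

    root = build(history.root)
    if root is None:
        raise HistoryError("history has no gene leaves: nothing survives pruning")
    return GeneTree(root, history.species_of_genes())


def history_costs(history: History) -> CostReport:
    dups = sum(1 for n in history.postorder() if n.kind == DUPLICATION)
    losses = sum(1 for n in history.postorder() if n.kind == LOSS_LEAF)
    return CostReport(duplications=dups, losses=losses)


def _component_ids(history: History) -> dict[int, int]:
    """Map id(node) -> retainer-component id.

    Components follow the retainer decomposition: walking down the
    history, a new component starts exactly when crossing from a
    duplication into its mutant child.
    """
    if not history.has_retainer_marks:
        raise HistoryError(
            "history has unmarked duplications: retainer/mutant assignment "
            "is required to read isorthogroups"
        )
    comp: dict[int, int] = {}
    counter = 0
    stack = [(history.root, 0)]
    counter = 1
    while stack:
        node, cid = stack.pop()
        comp[id(node)] = cid
        if node.kind == DUPLICATION:
            stack.append((node.retainer, cid))
            stack.append((node.mutant, counter))
            counter += 1
        else:
            for child in node.children:
                stack.append((child, cid))
    return comp


def isorthogroups_of(history: History) -> IsorthologyPartition:
    """The isorthogroups induced by a retainer-marked history.

    Two gene leaves are isorthologous exactly when every duplication on
    the path between them keeps both on its retainer side; the resulting
    components partition the gene leaves.
    """
    comp = _component_ids(history)
    blocks: dict[int, set] = {}
    for leaf in history.gene_leaves():
        blocks.setdefault(comp[id(leaf)], set()).add(leaf.gene)
    if not blocks:
        raise HistoryError("history has no gene leaves")
    return IsorthologyPartition(blocks.values())


def surviving_nodes(history: History) -> tuple[set, set]:
    """Surviving duplications and speciations.

    A duplication survives when it is the history-LCA of a pair of gene
    leaves (both its child subtrees retain a gene); a speciation survives
    when it is the LCA of a pair of *isorthologs*.
    Returns ``(surviving_duplications, surviving_speciations)`` as sets
    of :class:`HistoryNode`.
    """
    comp = _component_ids(history)
    # per-node: set of component ids of gene leaves below, and gene count
    genes_below: dict[int, int] = {}
    comps_below: dict[int, frozenset] = {}
    for node in history.postorder():
        if node.kind == GENE_LEAF:
            genes_below[id(node)] = 1
            comps_below[id(node)] = frozenset((comp[id(node)],))
        elif node.kind == LOSS_LEAF:
            genes_below[id(node)] = 0
            comps_below[id(node)] = frozenset()
        else:
            genes_below[id(node)] = sum(genes_below[id(c)] for c in node.children)
            comps_below[id(node)] = frozenset().union(
                *(comps_below[id(c)] for c in node.children)
            )
    dups: set = set()
    specs: set = set()
    for node in history.postorder():
        if node.kind == DUPLICATION:
            if all(genes_below[id(c)] > 0 for c in node.children):
                dups.add(node)
        elif node.kind == SPECIATION:
            left, right = node.children
            if comps_below[id(left)] & comps_below[id(right)]:
                specs.add(node)
    return dups, specs


def mutant_dead_duplications(history: History) -> list[HistoryNode]:
    """Duplications whose mutant subtree retains no gene leaf.

    A parsimonious history never contains such an event (the duplication
    could simply be dropped), so a non-empty result flags the history as
    non-parsimonious.  Simulated true histories may legitimately contain
    them.
    """
    dead = []
    for node in history.postorder():
        if node.kind == DUPLICATION:
            if not any(n.kind == GENE_LEAF for n in node.mutant.postorder()):
                dead.append(node)
    return dead


def confounding_condition(history: History) -> bool:
    """True when some surviving duplication has a surviving-speciation
    proper ancestor — the configuration under which the loss-pruned
    history cannot respect the isolocalization property."""
    dups, specs = surviving_nodes(history)
    spec_ids = {id(s) for s in specs}
    for d in dups:
        node = d.parent
        while node is not None:
            if id(node) in spec_ids:
                return True
            node = node.parent
    return False
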