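"""Rooted binary trees for reconciliation analyses.

Species trees and gene trees are strictly binary, rooted, and uniquely
leaf-labeled.  A gene tree additionally carries a total map from gene
labels to species labels (the function ``s(.)``), resolved either from a
two-column TSV sidecar or from the leaf-name convention in which the
species identifier is the token following the last underscore
(``IL1_Human`` -> ``Human``).

All algorithms in this package are topology-only: branch lengths present
in Newick input are parsed and discarded.
"""

from __future__ import annotations

import io
from typing import Callable, Iterable, Iterator, Mapping, Optional, Sequence

import dendropy

__all__ = [
    "TreeError",
    "Node",
    "SpeciesTree",
    "GeneTree",
    "parse_newick",
    "read_gene_species_map",
    "write_gene_species_map",
    "species_from_label",
    "contract_single_species_subtrees",
]


class TreeError(ValueError):
    """Raised for malformed trees or unresolvable labels."""


class Node:
    """A node of a rooted binary tree.

    Children are kept in the order they were written; every algorithm is
    required to be invariant to that order.
    """

    __slots__ = ("label", "children", "parent", "depth", "index")

    def __init__(self, label: Optional[str] = None):
        self.label = label
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None
        self.depth: int = 0
        self.index: int = -1  # postorder position, set by the owning tree

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    def postorder(self) -> Iterator["Node"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> Iterator["Node"]:
        for node in self.postorder():
            if node.is_leaf:
                yield node

    def leaf_labels(self) -> frozenset:
        return frozenset(leaf.label for leaf in self.leaves())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.label or self.newick()}>"

    def newick(self) -> str:
        if self.is_leaf:
            return _quote(self.label)
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner})"


def _quote(label: str) -> str:
    if label is None:
        return ""
    specials = set("(),:;[]' \t\n")
    if any(ch in specials for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


class Phylogeny:
    """Shared machinery for rooted binary leaf-labeled trees."""

    def __init__(self, root: Node):
        self.root = root
        self._reindex()

    def _reindex(self) -> None:
        self.leaf_by_label: dict[str, Node] = {}
        self._postorder: list[Node] = []
        for i, node in enumerate(self.root.postorder()):
            node.index = i
            self._postorder.append(node)
            if node.is_leaf:
                if node.label is None:
                    raise TreeError("unlabeled leaf")
                if node.label in self.leaf_by_label:
                    raise TreeError(f"duplicate leaf label: {node.label!r}")
                self.leaf_by_label[node.label] = node
            elif len(node.children) != 2:
                raise TreeError(
                    "non-binary tree: internal node with "
                    f"{len(node.children)} children"
                )
        for node in self.root.preorder():
            node.depth = 0 if node.parent is None else node.parent.depth + 1

    # -- basic queries -------------------------------------------------

    @property
    def leaf_labels(self) -> frozenset:
        return frozenset(self.leaf_by_label)

    def postorder(self) -> Iterator[Node]:
        return iter(self._postorder)

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def node_for(self, label: str) -> Node:
        try:
            return self.leaf_by_label[label]
        except KeyError:
            raise TreeError(f"unknown leaf label: {label!r}") from None

    def lca_nodes(self, a: Node, b: Node) -> Node:
        while a is not b:
            if a.depth >= b.depth:
                a = a.parent
            else:
                b = b.parent
        return a

    def lca(self, labels: Iterable[str]) -> Node:
        """Lowest common ancestor of a nonempty set of leaf labels."""
        it = iter(labels)
        try:
            node = self.node_for(next(it))
        except StopIteration:
            raise TreeError("lca of an empty leaf set") from None
        for label in it:
            node = self.lca_nodes(node, self.node_for(label))
        return node

    def is_ancestor(self, anc: Node, node: Node) -> bool:
        """True if ``anc`` is ``node`` or an ancestor of it."""
        while node is not None and node.depth >= anc.depth:
            if node is anc:
                return True
            node = node.parent
        return False

    def edge_distance(self, anc: Node, desc: Node) -> int:
        """Number of edges from ``anc`` down to its descendant ``desc``."""
        if not self.is_ancestor(anc, desc):
            raise TreeError("edge_distance requires an ancestor/descendant pair")
        return desc.depth - anc.depth

    # -- construction helpers ------------------------------------------

    def _copy_topology(self, node: Node) -> Node:
        new = Node(node.label)
        for child in node.children:
            new.add_child(self._copy_topology(child))
        return new

    def restricted_root(self, labels: Iterable[str]) -> Node:
        """Topology restricted to ``labels`` (unary nodes suppressed)."""
        keep = set(labels)
        if not keep:
            raise TreeError("cannot restrict to an empty leaf set")
        missing = keep - set(self.leaf_by_label)
        if missing:
            raise TreeError(f"unknown leaf labels: {sorted(missing)}")

        def build(node: Node) -> Optional[Node]:
            if node.is_leaf:
                return Node(node.label) if node.label in keep else None
            kept = [c for c in (build(ch) for ch in node.children) if c is not None]
            if not kept:
                return None
            if len(kept) == 1:
                return kept[0]
            new = Node(node.label)
            for c in kept:
                new.add_child(c)
            return new

        root = build(self.root)
        assert root is not None
        return root

    def newick(self) -> str:
        return self.root.newick() + ";"

    def __len__(self) -> int:
        return len(self._postorder)


class SpeciesTree(Phylogeny):
    """A rooted binary phylogeny over a set of species labels (Sigma)."""

    @property
    def species(self) -> frozenset:
        return self.leaf_labels

    def restrict(self, species: Iterable[str]) -> "SpeciesTree":
        return SpeciesTree(self.restricted_root(species))

    def copy(self) -> "SpeciesTree":
        return SpeciesTree(self._copy_topology(self.root))


class GeneTree(Phylogeny):
    """A rooted binary phylogeny over gene labels with a species map."""

    def __init__(self, root: Node, species_of: Mapping[str, str]):
        super().__init__(root)
        self.species_of: dict[str, str] = {}
        for label in self.leaf_by_label:
            try:
                self.species_of[label] = species_of[label]
            except KeyError:
                raise TreeError(f"unknown species for gene {label!r}") from None

    @property
    def genes(self) -> frozenset:
        return self.leaf_labels

    def species_set(self, node: Optional[Node] = None) -> frozenset:
        node = node or self.root
        return frozenset(self.species_of[l] for l in node.leaf_labels())

    def restrict(self, genes: Iterable[str]) -> "GeneTree":
        return GeneTree(self.restricted_root(genes), self.species_of)

    def copy(self) -> "GeneTree":
        return GeneTree(self._copy_topology(self.root), self.species_of)

    def check_covers(self, species_tree: SpeciesTree) -> None:
        """Require s(.) to land in the species tree, covering every species."""
        extra = set(self.species_of.values()) - species_tree.species
        if extra:
            raise TreeError(f"unknown species in gene tree: {sorted(extra)}")
        uncovered = species_tree.species - set(self.species_of.values())
        if uncovered:
            raise TreeError(
                f"species without any gene: {sorted(uncovered)}"
            )


# ---------------------------------------------------------------------------
# Newick I/O and the gene->species map
# ---------------------------------------------------------------------------


def species_from_label(gene_label: str) -> str:
    """Leaf-name convention: species is the token after the last underscore."""
    if "_" not in gene_label:
        raise TreeError(
            f"cannot infer species for {gene_label!r}: no underscore in label "
            "(provide a gene->species map)"
        )
    return gene_label.rsplit("_", 1)[1]


def read_gene_species_map(source) -> dict[str, str]:
    """Read a two-column ``gene<TAB>species`` file (no header)."""
    if isinstance(source, str):
        handle = io.StringIO(source) if "\t" in source or "\n" in source else open(source)
    else:
        handle = source
    mapping: dict[str, str] = {}
    with handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise TreeError(f"malformed map line {lineno}: {line!r}")
            gene, species = parts
            if gene in mapping:
                raise TreeError(f"duplicate gene in map: {gene!r}")
            mapping[gene] = species
    return mapping


def write_gene_species_map(mapping: Mapping[str, str]) -> str:
    return "".join(f"{g}\t{s}\n" for g, s in sorted(mapping.items()))


def _from_dendropy(dnode: dendropy.Node) -> Node:
    if dnode.is_leaf():
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        return Node(label)
    node = Node(dnode.label)
    for child in dnode.child_nodes():
        node.add_child(_from_dendropy(child))
    return node


def parse_newick(
    text: str,
    role: str = "species",
    species_map: Optional[Mapping[str, str]] = None,
):
    """Parse a rooted Newick string into a :class:`SpeciesTree` or
    :class:`GeneTree`.

    For ``role="gene"`` every leaf must be resolvable to a species, via
    ``species_map`` when given, otherwise via the underscore convention.
    Polytomies and duplicate leaf labels are rejected.
    """
    if role not in ("species", "gene"):
        raise ValueError(f"role must be 'species' or 'gene', got {role!r}")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"malformed Newick: {exc}") from exc
    root = _from_dendropy(dtree.seed_node)
    # "(a);" style input: collapse the unary wrapper around a single leaf
    while len(root.children) == 1:
        root = root.children[0]
        root.parent = None
    if role == "species":
        return SpeciesTree(root)
    labels = [leaf.label for leaf in root.leaves()]
    if species_map is not None:
        mapping = dict(species_map)
        for label in labels:
            if label not in mapping:
                raise TreeError(f"unknown species for gene {label!r}")
    else:
        mapping = {label: species_from_label(label) for label in labels}
    return GeneTree(root, mapping)


# ---------------------------------------------------------------------------
# Single-species subtree contraction
# ---------------------------------------------------------------------------


def contract_single_species_subtrees(
    gene_tree: GeneTree,
    joiner: Optional[Callable[[Sequence[str]], str]] = None,
) -> tuple[GeneTree, dict[str, list[str]]]:
    """Replace every maximal subtree whose genes all belong to one species
    by a single leaf.

    The new leaf label is the concatenation of the member labels (in the
    order they appear in the tree), or ``joiner(members)`` when given.
    Returns the contracted tree together with a log mapping each new
    label to the member labels it replaces.  Trees without single-species
    subtrees are returned unchanged (as a copy).
    """
    if joiner is None:
        joiner = lambda members: "".join(members)
    log: dict[str, list[str]] = {}
    species_of = dict(gene_tree.species_of)

    def build(node: Node) -> Node:
        members = [leaf.label for leaf in node.leaves()]
        node_species = {species_of[m] for m in members}
        if len(node_species) == 1 and not node.is_leaf:
            label = joiner(members)
            if label in species_of and label not in members:
                raise TreeError(f"contraction label collision: {label!r}")
            log[label] = members
            species_of[label] = next(iter(node_species))
            return Node(label)
        if node.is_leaf:
            return Node(node.label)
        new = Node(node.label)
        for child in node.children:
            new.add_child(build(child))
        return new

    root = build(gene_tree.root)
    return GeneTree(root, species_of), log
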