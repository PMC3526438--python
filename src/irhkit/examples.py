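"""Bundled worked examples.

Two fixtures ship with the package:

* **Three-genome toy** — the minimal configuration on which LCA
  reconciliation provably misses the true history: species tree
  ``(1,(2,3))``, a single duplication preceding the (2,3) speciation,
  loss of the mutant copy in genome 1.  The isolocalization-respecting
  gene tree clusters the functional copies ``a_1, a_2, a_3`` together,
  and reconciliation pushes the duplication to the root, inventing a
  loss.

* **Mammalian interleukin-1 family** — seven mammals, four gene
  classes, plus a recent duplication in the human lineage (``H3p`` /
  ``H3pp``).  The trees are transcribed from the classic textbook
  analysis; the species tree uses the rodents-basal topology common in
  the 1990s literature, which is the arrangement under which the
  published event counts for this example (three root duplications, ten
  losses, the four-loss explanation of the 3/4 paralogy, triplet
  history of mutation cost 10, minimum isorthology-respecting history
  of mutation cost 7) all emerge.  A hand-annotated triplet-respecting
  history (TRH) is included, with the group-4 duplication placed on the
  group-1 lineage just above the sheep/bovine ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .history import History, parse_history
from .trees import GeneTree, SpeciesTree, parse_newick, read_gene_species_map

__all__ = ["ThreeGenomeToy", "Interleukin1", "three_genome_toy", "interleukin1"]


def _read(name: str) -> str:
    return resources.files("irhkit.data").joinpath(name).read_text()


@dataclass(frozen=True)
class ThreeGenomeToy:
    species_tree: SpeciesTree
    gene_tree: GeneTree        # isolocalization-respecting gene tree G
    phylogeny: GeneTree        # the true phylogeny P (same events as H)
    true_history: History      # the true history H, retainer-marked


def three_genome_toy() -> ThreeGenomeToy:
    """The three-genome duplication/loss toy example."""
    species = parse_newick(_read("toy_species.nwk"), role="species")
    gene = parse_newick(_read("toy_gene.nwk"), role="gene")
    phylogeny = parse_newick(_read("toy_phylogeny.nwk"), role="gene")
    history = parse_history(_read("toy_history.nwk"), species)
    return ThreeGenomeToy(species, gene, phylogeny, history)


@dataclass(frozen=True)
class Interleukin1:
    species_tree: SpeciesTree
    gene_tree: GeneTree
    gene_species_map: dict
    trh: History               # the drawn triplet-respecting history
    contracted: bool


def interleukin1(contracted: bool = False) -> Interleukin1:
    """The mammalian interleukin-1 gene family.

    With ``contracted=True`` the recent human duplication is collapsed:
    ``H3p`` and ``H3pp`` become the single leaf ``H3`` (the
    preprocessing appropriate for same-species paralogs too young to
    have formed separate isorthogroups), and the bundled TRH is the
    matching three-duplication version.  Note the full-tree TRH is
    *not* strictly isorthology-respecting for the full gene tree: its
    {M3, H3p} group is broken apart by the recent human duplication,
    which is exactly why the contraction preprocessing exists.
    """
    species = parse_newick(_read("il1_species.nwk"), role="species")
    mapping = read_gene_species_map(_read("il1_map.tsv"))
    if contracted:
        gene = parse_newick(
            _read("il1_gene_contracted.nwk"), role="gene", species_map=mapping
        )
        trh = parse_history(_read("il1_mtrh_contracted.nwk"), species)
    else:
        gene = parse_newick(
            _read("il1_gene_full.nwk"), role="gene", species_map=mapping
        )
        trh = parse_history(_read("il1_mtrh_full.nwk"), species)
    return Interleukin1(species, gene, dict(mapping), trh, contracted)
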