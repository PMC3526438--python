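import random

import pytest

from irhkit.examples import three_genome_toy, interleukin1
from irhkit.trees import GeneTree, Node, SpeciesTree, parse_newick


@pytest.fixture(scope="session")
def toy():
    return three_genome_toy()


@pytest.fixture(scope="session")
def il1_full():
    return interleukin1(contracted=False)


@pytest.fixture(scope="session")
def il1_contracted():
    return interleukin1(contracted=True)


@pytest.fixture(scope="session")
def small_species_tree():
    return parse_newick("(((A,B),(C,D)),(E,F));", role="species")


def random_topology(rng: random.Random, labels: list) -> Node:
    """Uniform-ish random rooted binary topology via sequential attachment."""
    nodes = [Node(labels[0])]
    root = nodes[0]
    for label in labels[1:]:
        target = rng.choice(nodes)
        inner = Node(None)
        leaf = Node(label)
        parent = target.parent
        inner.add_child(target)
        inner.add_child(leaf)
        if parent is None:
            root = inner
        else:
            slot = parent.children.index(target)
            parent.children[slot] = inner
            inner.parent = parent
        nodes.extend([inner, leaf])
    return root


def random_species_tree(rng: random.Random, n_species: int) -> SpeciesTree:
    labels = [str(i + 1) for i in range(n_species)]
    rng.shuffle(labels)
    return SpeciesTree(random_topology(rng, labels))


def random_gene_tree(
    rng: random.Random, species_tree: SpeciesTree, n_genes: int
) -> GeneTree:
    """Random gene tree covering every species at least once."""
    species = sorted(species_tree.species)
    assert n_genes >= len(species)
    assignment = species + [rng.choice(species) for _ in range(n_genes - len(species))]
    rng.shuffle(assignment)
    labels = [f"g{i}_{sp}" for i, sp in enumerate(assignment)]
    rng.shuffle(labels)
    return GeneTree(
        random_topology(rng, labels),
        {lab: lab.rsplit("_", 1)[1] for lab in labels},
    )
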