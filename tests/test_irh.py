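import random

import pytest

from irhkit.history import (
    DUPLICATION,
    GENE_LEAF,
    LOSS_LEAF,
    SPECIATION,
    History,
    HistoryNode,
    IsorthologyPartition,
    history_costs,
    isorthogroups_of,
    validate_consistency,
)
from irhkit.irh import (
    brute_force_mirh,
    build_mirh,
    check_isolocalization,
    mirh_duplication_cost,
    speciation_forest,
    validate_irh,
    validate_trh,
)
from irhkit.reconciliation import lca_mapping, reconcile
from irhkit.trees import TreeError, parse_newick

from conftest import random_gene_tree, random_species_tree


class TestForest:
    def test_three_genome_example(self, toy):
        f = speciation_forest(toy.gene_tree, toy.species_tree)
        assert sorted(map(sorted, f.blocks)) == [
            ["a_1", "a_2", "a_3"], ["b_2", "b_3"],
        ]
        assert mirh_duplication_cost(toy.gene_tree, toy.species_tree) == 1

    def test_duplication_free_tree_is_one_block(self):
        s = parse_newick("((1,2),(3,4));", role="species")
        g = parse_newick("((a_1,a_2),(a_3,a_4));", role="gene")
        f = speciation_forest(g, s)
        assert len(f) == 1 and f.blocks[0] == g.genes
        assert mirh_duplication_cost(g, s) == 0

    def test_interleukin_forests(self, il1_full, il1_contracted):
        # full tree: the recent human duplication shatters group 3
        f = speciation_forest(il1_full.gene_tree, il1_full.species_tree)
        assert sorted(map(sorted, f.blocks)) == [
            ["B1", "H1", "M1", "P1", "Rb1", "Rt1"],
            ["B4", "S4"],
            ["H2", "M2", "Rt2"],
            ["H3p"], ["H3pp"], ["M3"],
        ]
        # contracted: {M3, H3} fuse back into one clean subtree
        fc = speciation_forest(il1_contracted.gene_tree, il1_contracted.species_tree)
        assert sorted(map(sorted, fc.blocks)) == [
            ["B1", "H1", "M1", "P1", "Rb1", "Rt1"],
            ["B4", "S4"],
            ["H2", "M2", "Rt2"],
            ["H3", "M3"],
        ]

    def test_blocks_partition_the_leaves(self):
        rng = random.Random(23)
        for _ in range(40):
            s = random_species_tree(rng, rng.randint(2, 6))
            g = random_gene_tree(rng, s, rng.randint(len(s.species), 12))
            f = speciation_forest(g, s)
            part = f.partition()
            assert part.genes == g.genes
            lmap = f.lmap
            for root in f.roots:
                for node in root.postorder():
                    if not node.is_leaf:
                        assert not lmap.is_duplication(node)
                parent = root.parent
                if parent is not None:
                    # maximality: the parent is a duplication or sits
                    # above one, so the subtree cannot be grown upward
                    assert lmap.is_duplication(parent) or any(
                        lmap.is_duplication(n)
                        for n in parent.postorder()
                        if not n.is_leaf
                    )

    def test_spine_bound(self, il1_full, toy):
        """|F| - 1 is at least the number of LCA-map duplications: the
        MIRH trades duplications upward never downward."""
        rng = random.Random(31)
        cases = [
            (toy.gene_tree, toy.species_tree),
            (il1_full.gene_tree, il1_full.species_tree),
        ]
        for _ in range(40):
            s = random_species_tree(rng, rng.randint(2, 5))
            cases.append((random_gene_tree(rng, s, rng.randint(len(s.species), 11)), s))
        for g, s in cases:
            n_dups = len(lca_mapping(g, s).duplication_nodes())
            assert mirh_duplication_cost(g, s) >= n_dups


class TestIsolocalization:
    def test_textbook_pair(self, toy):
        blocks = IsorthologyPartition(
            [{"a_1", "a_2", "a_3"}, {"b_2", "b_3"}]
        )
        assert check_isolocalization(toy.gene_tree, blocks) is None
        witness = check_isolocalization(toy.phylogeny, blocks)
        assert witness is not None
        a1, a2, offender = witness
        assert offender.startswith("b")

    def test_singleton_blocks_always_pass(self, toy):
        singletons = IsorthologyPartition([{g} for g in toy.gene_tree.genes])
        assert check_isolocalization(toy.gene_tree, singletons) is None

    def test_partition_must_cover(self, toy):
        with pytest.raises(TreeError):
            check_isolocalization(
                toy.gene_tree, IsorthologyPartition([{"a_1"}])
            )


class TestBuildMirh:
    def test_recovers_true_history_on_toy(self, toy):
        h = build_mirh(toy.gene_tree, toy.species_tree)
        assert validate_consistency(h) == []
        assert history_costs(h).as_dict() == {
            "duplications": 1, "losses": 0, "mutation": 1,
        }
        assert isorthogroups_of(h) == isorthogroups_of(toy.true_history)
        # same event tree as the bundled true history
        assert h.newick() == toy.true_history.newick()
        assert validate_irh(h, toy.gene_tree, toy.species_tree)
        assert validate_trh(h, toy.gene_tree, toy.species_tree)

    def test_congruent_pair_gives_speciation_only_history(self):
        s = parse_newick("((1,2),(3,4));", role="species")
        g = parse_newick("((a_1,a_2),(a_3,a_4));", role="gene")
        h = build_mirh(g, s)
        assert history_costs(h).mutation == 0
        kinds = {n.kind for n in h.postorder()}
        assert kinds == {SPECIATION, GENE_LEAF}

    def test_blocks_losses_and_validity_on_random_pairs(self):
        rng = random.Random(47)
        for _ in range(50):
            s = random_species_tree(rng, rng.randint(2, 6))
            g = random_gene_tree(rng, s, rng.randint(len(s.species), 12))
            f = speciation_forest(g, s)
            h = build_mirh(g, s)
            assert validate_consistency(h) == []
            assert history_costs(h).duplications == len(f) - 1
            assert isorthogroups_of(h).as_sets() == frozenset(f.blocks)
            assert validate_irh(h, g, s)
            # mutation mode is never worse, and still a valid IRH
            hm = build_mirh(g, s, cost="mutation")
            assert validate_consistency(hm) == []
            assert history_costs(hm).mutation <= history_costs(h).mutation
            assert validate_irh(hm, g, s)

    def test_rejects_unknown_cost(self, toy):
        with pytest.raises(ValueError):
            build_mirh(toy.gene_tree, toy.species_tree, cost="loss")


class TestValidators:
    def test_true_history_and_marked_reconciliation_are_irh(self, toy):
        assert validate_irh(toy.true_history, toy.gene_tree, toy.species_tree)
        recon, _ = reconcile(toy.gene_tree, toy.species_tree)
        for n in recon.postorder():
            if n.kind == DUPLICATION:
                n.retainer_index = 0  # mark: the a-side retains function
        assert validate_irh(recon, toy.gene_tree, toy.species_tree)

    def test_histories_are_not_irh_for_the_phylogeny(self, toy):
        """Both rival histories imply a_1 ~ a_2, but in the true
        phylogeny P the subtree spanned by them is dirty."""
        assert not validate_irh(toy.true_history, toy.phylogeny, toy.species_tree)
        recon, _ = reconcile(toy.gene_tree, toy.species_tree)
        for n in recon.postorder():
            if n.kind == DUPLICATION:
                n.retainer_index = 0
        assert not validate_irh(recon, toy.phylogeny, toy.species_tree)

    def test_trh_vacuous_below_three_blocks(self, toy):
        assert validate_trh(toy.true_history, toy.gene_tree, toy.species_tree)

    def test_trh_detects_wrong_join_order(self):
        """Three blocks joined against the gene tree's own nesting:
        IRH holds (blocks are speciation subtrees) but a cross-block
        triplet disagrees."""
        s = parse_newick("((1,2),3);", role="species")
        g = parse_newick("(((a_1,a_2),(b_1,b_2)),(c_1,c_3));", role="gene")
        f = speciation_forest(g, s)
        assert sorted(map(sorted, f.blocks)) == [
            ["a_1", "a_2"], ["b_1", "b_2"], ["c_1", "c_3"],
        ]
        n12 = s.lca({"1", "2"})
        one, two, three = (s.node_for(x) for x in ("1", "2", "3"))

        def spn(loc, a, b):
            n = HistoryNode(SPECIATION, loc); n.add_child(a); n.add_child(b); return n

        def dupn(loc, ret, mut):
            n = HistoryNode(DUPLICATION, loc, retainer_index=0)
            n.add_child(ret); n.add_child(mut); return n

        def geneleaf(lab, loc):
            return HistoryNode(GENE_LEAF, loc, gene=lab)

        def block(x):
            return spn(n12, geneleaf(f"{x}_1", one), geneleaf(f"{x}_2", two))

        # c's copy speciates at the root and stays the retainer through
        # both joins; b attaches onto its (1,2) branch *below* a, so the
        # pruned shape is (((c_1,(b_1,b_2)),(a_1,a_2)),c_3) and the
        # triplet {a_1,b_1,c_1} has cherry (b_1,c_1) while G says (a_1,b_1).
        c_branch = spn(n12, geneleaf("c_1", one), HistoryNode(LOSS_LEAF, two))
        wrong = History(
            spn(s.root, dupn(n12, dupn(n12, c_branch, block("b")), block("a")),
                geneleaf("c_3", three)),
            s,
        )
        assert validate_consistency(wrong) == []
        assert validate_irh(wrong, g, s)
        assert not validate_trh(wrong, g, s)
        # the builder's own join respects the spine
        good = build_mirh(g, s)
        assert validate_trh(good, g, s)


class TestBruteForce:
    def test_left_subtree_has_three_configurations(self, toy):
        """The all-speciation 3-leaf subtree admits exactly three
        isorthogroup configurations."""
        sub = toy.gene_tree.restrict({"a_1", "a_2", "a_3"})
        s = toy.species_tree
        cost, witnesses = brute_force_mirh(sub, s)
        assert cost == 0
        from irhkit.irh import _speciation_subtree_blocks

        lmap = lca_mapping(sub, s)
        admissible = _speciation_subtree_blocks(sub, lmap)
        partitions = set()

        def enumerate_partitions(blocks_left, acc):
            if not blocks_left:
                partitions.add(frozenset(acc))
                return
            first = min(blocks_left)
            for block in admissible:
                if first in block and block <= blocks_left:
                    enumerate_partitions(blocks_left - block, acc + [block])

        enumerate_partitions(frozenset(sub.genes), [])
        assert len(partitions) == 3

    def test_duplication_free_unique_coarsest(self):
        s = parse_newick("((1,2),(3,4));", role="species")
        g = parse_newick("((a_1,a_2),(a_3,a_4));", role="gene")
        cost, witnesses = brute_force_mirh(g, s)
        assert cost == 0
        assert any(w.as_sets() == frozenset({g.genes}) for w in witnesses)

    def test_bound_is_enforced(self):
        rng = random.Random(1)
        s = random_species_tree(rng, 4)
        g = random_gene_tree(rng, s, 12)
        with pytest.raises(TreeError, match="limited"):
            brute_force_mirh(g, s, max_leaves=10)

    def test_oracle_equivalence_on_random_instances(self):
        """Minimum duplication cost over *all* isorthology-respecting
        partitions equals |F| - 1 from the linear-time forest."""
        rng = random.Random(13)
        for _ in range(60):
            s = random_species_tree(rng, 4)
            g = random_gene_tree(rng, s, rng.randint(4, 8))
            cost, witnesses = brute_force_mirh(g, s)
            f = speciation_forest(g, s)
            assert cost == len(f) - 1
            assert any(w.as_sets() == frozenset(f.blocks) for w in witnesses)
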