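"""The four ortholog-extraction strategies, checked against independent oracles."""

import itertools

import dendropy
import pytest

from orthoprune.homolog_refine import RefinementConfig
from orthoprune.ortholog_prune import (
    OrthologTree,
    PruneConfig,
    TaxonRoles,
    extract_rooted_ingroup_clades,
    filter_1to1,
    has_taxon_duplication,
    prune_mi,
    prune_paralogs_mo,
    prune_paralogs_rt,
    run_method,
)
from orthoprune.seqio import parse_taxon
from orthoprune.simulate import simulate_gene_family, simulate_species_tree
from orthoprune.tree import TreeError, read_newick, write_newick


# ---------------------------------------------------------------------------
# Independent maximum-inclusion oracle
# ---------------------------------------------------------------------------


def brute_force_mi(newick: str, min_taxa: int) -> list[frozenset]:
    """Greedy maximum-inclusion by exhaustive bipartition enumeration.

    Uses dendropy (an independent parser) to list every edge-delimited
    side of the tree; the candidates of each round are those sides
    restricted to the remaining tips, plus the remaining set itself.
    """
    dt = dendropy.Tree.get(data=newick, schema="newick",
                           preserve_underscores=True)
    everything = frozenset(l.taxon.label for l in dt.leaf_node_iter())
    sides = set()
    for node in dt.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        sides.add(side)
        sides.add(everything - side)

    def dup_free(labels):
        taxa = [parse_taxon(x) for x in labels]
        return len(set(taxa)) == len(taxa)

    remaining = everything
    out = []
    while len(remaining) >= min_taxa:
        candidates = {side & remaining for side in sides} | {remaining}
        valid = [
            c
            for c in candidates
            if c
            and dup_free(c)
            and len({parse_taxon(x) for x in c}) >= min_taxa
        ]
        if not valid:
            break
        best = max(
            valid,
            key=lambda c: (
                len({parse_taxon(x) for x in c}),
                len(c),
                0,
                tuple(-ord(ch) for ch in "\x00".join(sorted(c))),
            ),
        )
        out.append(frozenset(best))
        remaining = remaining - best
    return out


class TestHasTaxonDuplication:
    @pytest.mark.parametrize(
        "newick,expected",
        [
            ("(A@1:1,B@1:1,C@1:1);", False),
            ("(A@1:1,A@2:1,B@1:1);", True),
            ("A@1;", False),
        ],
    )
    def test_detection(self, newick, expected):
        assert has_taxon_duplication(read_newick(newick)) is expected


class TestMaximumInclusion:
    def test_iterative_extraction_trace(self):
        tree = read_newick(
            "((A@1:.1,B@1:.1):.1,(A@2:.1,(B@2:.1,C@1:.1):.1):.1,D@1:.1);"
        )
        out = prune_mi(tree, min_taxa=2)
        assert [sorted(o.tips) for o in out] == [
            ["A@2", "B@2", "C@1", "D@1"],
            ["A@1", "B@1"],
        ]

    def test_duplication_free_tree_is_one_ortholog(self):
        tree = read_newick(
            "(((A@1:.1,B@1:.1):.1,(C@1:.1,D@1:.1):.1):.1,"
            "((E@1:.1,F@1:.1):.1,(G@1:.1,H@1:.1):.1):.1);"
        )
        out = prune_mi(tree, min_taxa=8)
        assert len(out) == 1 and out[0].tips == set(tree.tip_labels())

    def test_fully_interleaved_tree_yields_nothing(self):
        # every subtree with >= 3 taxa contains a duplicate
        tree = read_newick(
            "((A@1:.1,B@1:.1):.1,(B@2:.1,A@2:.1):.1,(A@3:.1,B@3:.1):.1);"
        )
        assert prune_mi(tree, min_taxa=3) == []

    def test_outputs_tip_disjoint_subsets_of_input(self):
        tree = read_newick(
            "((A@1:.1,B@1:.1):.1,((A@2:.1,C@1:.1):.1,(B@2:.1,D@1:.1):.1):.1);"
        )
        out = prune_mi(tree, min_taxa=2)
        all_tips = [t for o in out for t in o.tips]
        assert len(all_tips) == len(set(all_tips))
        assert set(all_tips) <= set(tree.tip_labels())

    def test_agrees_with_brute_force_on_random_trees(self):
        """MI equals greedy exhaustive extraction over 500 simulator trees."""
        species = simulate_species_tree(6, depth=0.4, seed=9)
        checked = 0
        seed = 0
        while checked < 500:
            seed += 1
            gene, _ = simulate_gene_family(species, 0.5, 0.2, seed=seed)
            if gene is None or not (3 <= gene.num_tips() <= 12):
                continue
            newick = write_newick(gene)
            mine = [frozenset(o.tips) for o in prune_mi(gene, min_taxa=2)]
            oracle = brute_force_mi(newick, min_taxa=2)
            assert mine == oracle, f"seed {seed}: {mine} != {oracle}"
            checked += 1

    def test_remainder_trimming_uses_mi_tip_cutoffs(self):
        # after the first extraction, A@1 dangles on a long branch in the
        # remainder; with trimming it is removed, shrinking the remainder
        # below min_taxa, while without trimming it is emitted
        tree = read_newick(
            "((A@1:3.0,(B@1:.1,E@1:.1):.1):.1,"
            "(A@2:.1,((B@2:.1,C@1:.1):.1,D@1:.1):.1):.1);"
        )
        trim = RefinementConfig(
            internal_branch_cutoff=1.0, tip_absolute_cutoff=0.3,
            min_subtree_taxa=2,
        )
        first = ["A@2", "B@2", "C@1", "D@1"]
        out = prune_mi(tree, min_taxa=3, tip_trim=trim)
        assert [sorted(o.tips) for o in out] == [first]
        out = prune_mi(tree, min_taxa=3)
        assert [sorted(o.tips) for o in out] == [first, ["A@1", "B@1", "E@1"]]


class TestRootedExtraction:
    def test_outgroup_oriented_extraction(self):
        tree = read_newick(
            "((A@1:.1,(B@1:.1,C@1:.1):.1):.1,O@1:.1,(A@2:.1,B@2:.1):.1);"
        )
        roles = TaxonRoles(frozenset("ABC"), frozenset("O"))
        clades = extract_rooted_ingroup_clades(tree, roles, 2)
        assert all(c.rooted for c in clades)
        # the full ingroup is one edge-delimited side of the outgroup tip
        assert sorted(sorted(c.tip_labels()) for c in clades) == [
            ["A@1", "A@2", "B@1", "B@2", "C@1"]
        ]

    def test_all_ingroup_tree_yields_nothing(self):
        tree = read_newick("((A@1:.1,B@1:.1):.1,C@1:.1,D@1:.1);")
        roles = TaxonRoles(frozenset("ABCD"), frozenset("O"))
        assert extract_rooted_ingroup_clades(tree, roles, 2) == []

    def test_single_maximal_clade(self):
        tree = read_newick("((A@1:.1,B@1:.1):.1,(O@1:.1,O2@1:.1):.1);")
        roles = TaxonRoles(frozenset("AB"), frozenset(["O", "O2"]))
        clades = extract_rooted_ingroup_clades(tree, roles, 2)
        assert [sorted(c.tip_labels()) for c in clades] == [["A@1", "B@1"]]


class TestRtPruning:
    def test_root_duplication_splits_both_sides(self):
        tree = read_newick("((A@1,(B@1,C@1)),(A@2,B@2));")
        out = prune_paralogs_rt(tree, min_taxa=2)
        assert sorted(sorted(o.tips) for o in out) == [
            ["A@1", "B@1", "C@1"],
            ["A@2", "B@2"],
        ]

    def test_duplication_free_tree_returned_whole(self):
        tree = read_newick("((A@1,B@1),(C@1,D@1));")
        out = prune_paralogs_rt(tree, min_taxa=2)
        assert [sorted(o.tips) for o in out] == [["A@1", "B@1", "C@1", "D@1"]]

    def test_tipwise_duplications_resolve_without_mixing(self):
        # duplications on terminal branches: kept tips never conflict
        tree = read_newick("((A@1,A@2),(B@1,B@2));")
        out = prune_paralogs_rt(tree, min_taxa=2)
        assert [sorted(o.tips) for o in out] == [["A@2", "B@2"]]

    def test_discard_mode_drops_pruned_sides(self):
        tree = read_newick("((A@1,(B@1,C@1)),(A@2,B@2));")
        out = prune_paralogs_rt(tree, min_taxa=2, reprocess_pruned=False)
        assert [sorted(o.tips) for o in out] == [["A@1", "B@1", "C@1"]]

    def test_unrooted_input_is_a_contract_error(self):
        with pytest.raises(TreeError, match="rooted"):
            prune_paralogs_rt(read_newick("(A@1,B@1,C@1,A@2);"), 2)


class TestMoPruning:
    ROLES = TaxonRoles(frozenset(["A", "B"]), frozenset(["O1", "O2"]))

    def test_character_tiebreak_keeps_better_copy(self):
        tree = read_newick("(((A@1,B@1),(A@2,B@2)),(O1@1,O2@1));")
        counts = {"A@1": 300, "B@1": 300, "A@2": 200, "B@2": 200,
                  "O1@1": 100, "O2@1": 100}
        out = prune_paralogs_mo(tree, self.ROLES, 2, char_counts=counts)
        assert sorted(out.tips) == ["A@1", "B@1", "O1@1", "O2@1"]
        assert out.tree.rooted

    def test_repeated_outgroup_taxon_rejected(self):
        tree = read_newick("(((A@1,B@1),(A@2,B@2)),(O1@1,O1@2));")
        assert prune_paralogs_mo(tree, self.ROLES, 2) is None

    def test_non_monophyletic_outgroup_rejected(self):
        tree = read_newick("((O1@1,(A@1,B@1)),(A@2,O2@1));")
        assert prune_paralogs_mo(tree, self.ROLES, 2) is None

    def test_no_outgroup_tips_rejected(self):
        tree = read_newick("((A@1,B@1),(A@2,B@2));")
        assert prune_paralogs_mo(tree, self.ROLES, 2) is None

    def test_single_outgroup_tip_roots_the_tree(self):
        tree = read_newick("((A@1,B@1),((A@2,B@2),O1@1));")
        out = prune_paralogs_mo(tree, self.ROLES, 2)
        assert out is not None and "O1@1" in out.tips


class Test1to1:
    def test_duplication_free_whole_tree(self):
        tree = read_newick(
            "(((A@1,B@1),(C@1,D@1)),((E@1,F@1),(G@1,H@1)));"
        )
        out = filter_1to1(tree, min_taxa=8)
        assert out is not None and out.tips == set(tree.tip_labels())

    def test_one_duplicate_disqualifies(self):
        tree = read_newick("((A@1,A@2),(B@1,C@1));")
        assert filter_1to1(tree, min_taxa=2) is None

    def test_min_taxa_boundary(self):
        tree = read_newick("(((A@1,B@1),(C@1,D@1)),((E@1,F@1),G@1));")
        assert filter_1to1(tree, min_taxa=8) is None
        assert filter_1to1(tree, min_taxa=7) is not None


class TestInvariantsAndDispatch:
    def test_ortholog_constructor_rejects_duplicates(self):
        with pytest.raises(TreeError, match="repeated taxon"):
            OrthologTree(read_newick("(A@1,A@2,B@1);"), "h", "MI")

    def test_rt_without_outgroup_keeps_only_duplication_free(self):
        dup_free = ("h1", read_newick("((A@1,B@1),(C@1,D@1));"))
        dup = ("h2", read_newick("((A@1,A@2),(B@1,C@1));"))
        roles = TaxonRoles(frozenset("ABCD"), frozenset("O"))
        orthologs, report = run_method(
            [dup_free, dup], "RT", roles, PruneConfig(min_taxa=2)
        )
        assert [sorted(o.tips) for o in orthologs] == [["A@1", "B@1", "C@1", "D@1"]]
        assert report[1]["note"].startswith("skipped")

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            run_method([], "XX", TaxonRoles(frozenset("A")), PruneConfig())

    def test_monotonicity_in_min_taxa(self):
        species = simulate_species_tree(8, depth=0.4, seed=3)
        roles = TaxonRoles(
            frozenset(f"T{i}" for i in range(3, 9)),
            frozenset(["T1", "T2"]),
        )
        for seed in range(12):
            gene, _ = simulate_gene_family(species, 0.6, 0.2, seed=seed)
            if gene is None or gene.num_tips() < 4:
                continue
            homolog = [("h", gene)]
            for method in ("MI", "RT", "MO", "1to1"):
                counts = [
                    len(run_method(homolog, method, roles,
                                   PruneConfig(min_taxa=m))[0])
                    for m in (2, 4, 6)
                ]
                assert counts == sorted(counts, reverse=True)

    def test_no_emitted_ortholog_has_duplicates_on_simulated_families(self):
        species = simulate_species_tree(10, depth=0.4, seed=17)
        roles = TaxonRoles(
            frozenset(f"T{i}" for i in range(3, 11)),
            frozenset(["T1", "T2"]),
        )
        for seed in range(40):
            gene, _ = simulate_gene_family(species, 0.5, 0.2, seed=seed)
            if gene is None or gene.num_tips() < 4:
                continue
            for method in ("MI", "RT", "MO", "1to1"):
                orthologs, _ = run_method(
                    [("h", gene)], method, roles, PruneConfig(min_taxa=2)
                )
                for orth in orthologs:
                    assert not has_taxon_duplication(orth.tree)

    def test_1to1_equals_first_mi_extraction_when_duplication_free(self):
        tree = read_newick("(((A@1,B@1),(C@1,D@1)),(E@1,F@1));")
        mi = prune_mi(tree, min_taxa=2)
        one = filter_1to1(tree, min_taxa=2)
        assert mi[0].tips == one.tips
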