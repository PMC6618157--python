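import numpy as np
import pytest

from cophylokit.errors import (
    AssociationError,
    NewickParseError,
    NormalizationError,
    TreeValidationError,
)
from cophylokit.treecore import (
    AssociationTable,
    collapse_tips_by_group,
    collapse_unary,
    graft_zero_branches,
    midpoint_root,
    normalize_branch_lengths,
    parse_newick,
    resolve_polytomies,
    write_newick,
)

from conftest import random_tree, t
from oracles import tip_path


class TestNewickIO:
    def test_basic_parse(self):
        tree = t("((A:1,B:1):1,C:2);")
        assert tree.n_tips == 3
        assert sorted(tree.tip_labels()) == ["A", "B", "C"]
        assert tree.root_height() == pytest.approx(2.0)

    def test_unary_dialect_preserved(self):
        tree = parse_newick("((A:1)S1:1,B:2);", allow_unary=True)
        unary = [n for n in tree.preorder() if n.is_unary]
        assert len(unary) == 1 and unary[0].label == "S1"

    def test_unary_collapsed_without_flag(self):
        tree = parse_newick("((A:1)S1:1,B:2);", allow_unary=False)
        assert not any(n.is_unary for n in tree.preorder())
        assert write_newick(tree) == "(A:2,B:2);"

    def test_malformed_raises(self):
        with pytest.raises(NewickParseError):
            parse_newick("((A:1,B:1):1,C:2;")

    def test_negative_length_raises(self):
        with pytest.raises(TreeValidationError):
            parse_newick("(A:-1,B:2);")

    def test_round_trip_identity(self):
        s = "((A:1,B:1):1,C:2);"
        assert write_newick(parse_newick(s)) == s

    def test_round_trip_random_trees(self, rng):
        for _ in range(20):
            tree = random_tree(list("ABCDE"), rng)
            s = write_newick(tree)
            again = parse_newick(s)
            assert write_newick(again) == s
            # lengths preserved to high relative precision
            for n1, n2 in zip(tree.preorder(), again.preorder()):
                if n1.length is not None:
                    assert n2.length == pytest.approx(n1.length, rel=1e-9)

    def test_annotated_round_trip_with_and_without_unary(self):
        s = "(((A:1)HS:1,B:2):1,C:3);"
        tree = parse_newick(s, allow_unary=True)
        assert write_newick(tree, keep_unary=True) == s
        assert write_newick(tree, keep_unary=False) == write_newick(collapse_unary(tree))


class TestCollapseUnary:
    def test_lengths_add(self):
        tree = parse_newick("((A:1)S:1,B:2);", allow_unary=True)
        assert write_newick(collapse_unary(tree)) == "(A:2,B:2);"

    def test_identity_without_unary(self):
        s = "((A:1,B:1):1,C:2);"
        assert write_newick(collapse_unary(t(s))) == s

    def test_chain_additivity(self):
        s = "((((A:1)x:1)y:1)z:1,B:4);"
        tree = parse_newick(s, allow_unary=True)
        out = collapse_unary(tree)
        (a,) = [n for n in out.tips() if n.label == "A"]
        assert a.length == pytest.approx(4.0)

    def test_path_lengths_preserved(self, rng):
        # insert unary nodes into random positions; tip paths must not move
        tree = random_tree(list("ABCDEF"), rng)
        before = {
            (a, b): tip_path(tree, a, b, weighted=True)
            for a in "ABC"
            for b in "DEF"
        }
        # split tip A's branch with a unary marker node
        from cophylokit.treecore import TreeNode

        mutated = tree.copy()
        a_tip = [n for n in mutated.tips() if n.label == "A"][0]
        parent = a_tip.parent
        marker = TreeNode(label="U", length=a_tip.length - 0.05)
        parent.children[parent.children.index(a_tip)] = marker
        marker.parent = parent
        marker.add_child(a_tip)
        a_tip.length = 0.05
        out = collapse_unary(mutated)
        after = {
            (a, b): tip_path(out, a, b, weighted=True) for a in "ABC" for b in "DEF"
        }
        for key in before:
            assert after[key] == pytest.approx(before[key], abs=1e-12)


class TestNormalize:
    def test_mean_one(self):
        tree = t("((A:1,B:2):3,C:2);")
        out = normalize_branch_lengths(tree)
        lengths = [n.length for n in out.branches()]
        assert np.mean(lengths) == pytest.approx(1.0)
        assert sorted(lengths) == pytest.approx([0.5, 1.0, 1.0, 1.5])

    def test_idempotent_on_mean_one(self):
        tree = t("((A:0.5,B:1):1.5,C:1);")
        out = normalize_branch_lengths(tree)
        assert [n.length for n in out.branches()] == pytest.approx(
            [n.length for n in tree.branches()]
        )

    def test_all_zero_errors(self):
        with pytest.raises(NormalizationError):
            normalize_branch_lengths(t("((A:0,B:0):0,C:0);"))


class TestGraft:
    def test_one_pathogen_three_hosts(self):
        host = t("(((H1:1,H2:1):1,(H3:1,H4:1):1):1,H5:3);")
        pathogen = t("((P1:1,P2:1):1,P3:2);")
        assoc = AssociationTable(
            [("H1", "P1"), ("H2", "P1"), ("H3", "P1"), ("H4", "P2"), ("H5", "P3")]
        )
        gh, gp = graft_zero_branches(host, pathogen, assoc)
        assert gh.n_tips == gp.n_tips == 5
        assert sorted(gh.tip_labels()) == sorted(gp.tip_labels())
        assert gh.total_branch_length() == pytest.approx(host.total_branch_length())
        assert gp.total_branch_length() == pytest.approx(pathogen.total_branch_length())

    def test_one_to_one_relabels_only(self):
        host = t("((H1:1,H2:1):1,H3:2);")
        pathogen = t("((P1:1,P2:1):1,P3:2);")
        assoc = AssociationTable([("H1", "P1"), ("H2", "P2"), ("H3", "P3")])
        gh, gp = graft_zero_branches(host, pathogen, assoc)
        assert sorted(gp.tip_labels()) == ["H1", "H2", "H3"]
        assert write_newick(gh) == write_newick(host)

    def test_unknown_tip_raises(self):
        host = t("(H1:1,H2:1);")
        pathogen = t("(P1:1,P2:1);")
        assoc = AssociationTable([("H1", "P1"), ("X", "P2")])
        with pytest.raises(KeyError):
            graft_zero_branches(host, pathogen, assoc)

    def test_empty_table_raises(self):
        with pytest.raises(AssociationError):
            graft_zero_branches(t("(A:1,B:1);"), t("(C:1,D:1);"), AssociationTable([]))

    def test_label_multisets_match_many_to_many(self):
        host = t("((H1:1,H2:1):1,H3:2);")
        pathogen = t("((P1:1,P2:1):1,P3:2);")
        assoc = AssociationTable(
            [("H1", "P1"), ("H1", "P2"), ("H2", "P2"), ("H3", "P3"), ("H3", "P1")]
        )
        gh, gp = graft_zero_branches(host, pathogen, assoc)
        assert sorted(gh.tip_labels()) == sorted(gp.tip_labels())
        assert len(gh.tip_labels()) == len(set(gh.tip_labels()))


class TestMidpointRoot:
    def test_three_tip_definition(self):
        # longest tip-to-tip path is A-B with length 10; midpoint 5 from A
        tree = t("((A:7,B:3):1,C:1);")
        out = midpoint_root(tree)
        depths = out.depths()
        tip_depth = {n.label: d for n, d in depths.items() if n.is_tip}
        assert tip_depth["A"] == pytest.approx(5.0)
        assert tip_depth["B"] == pytest.approx(5.0)

    def test_path_lengths_preserved(self, rng):
        tree = random_tree(list("ABCDE"), rng)
        out = midpoint_root(tree)
        for a, b in [("A", "B"), ("A", "E"), ("C", "D")]:
            assert tip_path(out, a, b, weighted=True) == pytest.approx(
                tip_path(tree, a, b, weighted=True), abs=1e-9
            )

    def test_single_tip_errors(self):
        with pytest.raises(TreeValidationError):
            midpoint_root(t("(A:1);"))


class TestCollapseTipsByGroup:
    def test_cherry_collapses(self):
        tree = t("((A1:1,A2:1):1,B:2);")
        out = collapse_tips_by_group(tree, {"A1": "A", "A2": "A", "B": "B"})
        assert sorted(out.tip_labels()) == ["A", "B"]

    def test_injective_mapping_relabels(self):
        tree = t("((A:1,B:1):1,C:2);")
        out = collapse_tips_by_group(tree, {"A": "x", "B": "y", "C": "z"})
        assert sorted(out.tip_labels()) == ["x", "y", "z"]
        assert write_newick(out) == "((x:1,y:1):1,z:2);"

    def test_missing_tip_raises(self):
        with pytest.raises(KeyError):
            collapse_tips_by_group(t("(A:1,B:1);"), {"A": "x"})


class TestResolvePolytomies:
    def test_binary_and_lengths_preserved(self):
        tree = t("((A:1,B:1,C:1,D:1):1,E:2);")
        out = resolve_polytomies(tree, seed=3)
        assert all(len(n.children) == 2 for n in out.preorder() if not n.is_tip)
        assert out.total_branch_length() == pytest.approx(tree.total_branch_length())
        # tip paths unchanged because new branches have zero length
        assert tip_path(out, "A", "E", weighted=True) == pytest.approx(
            tip_path(tree, "A", "E", weighted=True)
        )

    def test_deterministic(self):
        tree = t("((A:1,B:1,C:1,D:1):1,E:2);")
        assert write_newick(resolve_polytomies(tree, seed=5)) == write_newick(
            resolve_polytomies(tree, seed=5)
        )
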