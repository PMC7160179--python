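"""Tree container, I/O, reconciliation and measurement-error imputation."""
import numpy as np
import pandas as pd
import pytest

import oushift as ou
from oushift.traits import impute_me, read_traits, reconcile
from oushift.tree import TreeError, read_tree, write_tree


class TestParsing:
    def test_small_ultrametric_tree(self, cherry_tree):
        assert cherry_tree.n_nodes == 5
        assert cherry_tree.n_tips == 3
        assert cherry_tree.depth == pytest.approx(2.0)
        assert cherry_tree.is_ultrametric

    def test_unequal_depths_not_ultrametric(self):
        t = ou.Phylogeny.from_newick("((A:1,B:1):1,C:3);")
        assert not t.is_ultrametric

    def test_postorder_ids_root_last(self, cherry_tree):
        assert cherry_tree.root == cherry_tree.n_nodes - 1
        for v in range(cherry_tree.n_nodes):
            for c in cherry_tree.children[v]:
                assert c < v  # children precede parents in post-order

    def test_duplicate_tip_labels_rejected(self):
        with pytest.raises(TreeError, match="duplicate"):
            ou.Phylogeny.from_newick("((A:1,A:1):1,C:2);")

    def test_missing_branch_length_rejected(self):
        with pytest.raises(TreeError, match="branch length"):
            ou.Phylogeny.from_newick("((A:1,B:1):1,C);")

    def test_negative_branch_length_rejected(self):
        with pytest.raises(TreeError, match="negative"):
            ou.Phylogeny.from_newick("((A:1,B:1):-1,C:2);")

    @pytest.mark.parametrize("fmt", ["newick", "nexus"])
    def test_roundtrip_preserves_structure(self, tmp_path, fmt):
        tree = ou.simulate_tree(20, seed=5)
        path = tmp_path / f"tree.{fmt}"
        write_tree(tree, path, fmt)
        back = read_tree(path, fmt)
        assert sorted(back.tip_labels) == sorted(tree.tip_labels)
        d1 = {l: tree.tip_depths[i] for i, l in enumerate(tree.tip_labels)}
        d2 = {l: back.tip_depths[i] for i, l in enumerate(back.tip_labels)}
        for lab in d1:
            assert d2[lab] == pytest.approx(d1[lab], rel=1e-9)
        assert back.total_branch_length == pytest.approx(
            tree.total_branch_length, rel=1e-9)

    def test_mrca_and_clade_branch(self, five_tip_tree):
        node = five_tip_tree.clade_branch(["A", "B"])
        tips = five_tip_tree.subtree_tips(node)
        assert sorted(five_tip_tree.tip_labels[i] for i in tips) == ["A", "B"]


class TestPruning:
    def test_prune_preserves_retained_depths(self):
        tree = ou.simulate_tree(30, seed=2)
        keep = tree.tip_labels[:10]
        pruned = tree.prune_to(keep)
        assert sorted(pruned.tip_labels) == sorted(keep)
        orig = {l: tree.tip_depths[i] for i, l in enumerate(tree.tip_labels)}
        for i, lab in enumerate(pruned.tip_labels):
            assert pruned.tip_depths[i] == pytest.approx(orig[lab], rel=1e-12)

    def test_prune_within_one_clade_keeps_root_depth(self, five_tip_tree):
        pruned = five_tip_tree.prune_to(["A", "B"])
        # the root stem survives, so A keeps its original depth of 3
        assert pruned.tip_depths[list(pruned.tip_labels).index("A")] == pytest.approx(3.0)


def _raw_frame(species, hz, mm, site, me=None):
    return pd.DataFrame({
        "species": species, "dominant_frequency_hz": hz, "svl_mm": mm,
        "calling_site": site,
        "me_var": me if me is not None else [np.nan] * len(species),
    })


class TestReconcile:
    def test_minimum_overlap_enforced(self, five_tip_tree):
        raw = _raw_frame(["A", "B", "C"], [1000] * 3, [30] * 3, ["aquatic"] * 3)
        with pytest.raises(TreeError, match="at least 4"):
            reconcile(five_tip_tree, raw)

    def test_unmatched_names_dropped_and_logged(self, five_tip_tree, caplog):
        raw = _raw_frame(["A", "B", "C", "D", "Zeta"], [1000] * 5, [30] * 5,
                         ["terrestrial"] * 5)
        with caplog.at_level("INFO"):
            tree, table = reconcile(five_tip_tree, raw)
        assert tree.n_tips == 4
        assert "Zeta" in caplog.text
        assert "E" in caplog.text
        assert list(table.species) == list(tree.tip_labels)

    def test_idempotent(self, five_tip_tree):
        raw = _raw_frame(["A", "B", "C", "D"], [1000, 2000, 1500, 800],
                         [30, 20, 25, 50], ["arboreal"] * 4)
        t1, tab1 = reconcile(five_tip_tree, raw)
        t2, tab2 = reconcile(t1, raw)
        assert t1.to_newick() == t2.to_newick()
        np.testing.assert_allclose(tab1.log_df, tab2.log_df)

    def test_name_normalization(self, five_tip_tree):
        tree5 = ou.Phylogeny.from_newick(
            "(((Rana_a:1,Rana_b:1):1,Rana_c:2):1,(Rana_d:1.5,Rana_e:1.5):1.5);")
        raw = _raw_frame(["Rana a", "RANA_B", "rana c", "Rana_d"],
                         [1000] * 4, [30] * 4, ["terrestrial"] * 4)
        tree, table = reconcile(tree5, raw)
        assert tree.n_tips == 4

    def test_empty_intersection_errors(self, five_tip_tree):
        raw = _raw_frame(["X", "Y"], [1000, 900], [30, 31], ["aquatic"] * 2)
        with pytest.raises(TreeError, match="no species shared"):
            reconcile(five_tip_tree, raw)

    def test_log_transform_is_natural_log(self, five_tip_tree):
        raw = _raw_frame(["A", "B", "C", "D"], [np.e ** 8] * 4, [np.e ** 4] * 4,
                         ["terrestrial"] * 4)
        _, table = reconcile(five_tip_tree, raw)
        np.testing.assert_allclose(table.log_df, 8.0)
        np.testing.assert_allclose(table.log_size, 4.0)


class TestImputeME:
    def _table(self, me):
        return ou.TraitTable(species=["a", "b", "c"], log_df=[9, 9, 9],
                             log_size=[4, 4, 4], site=["aquatic"] * 3, me_var=me)

    def test_all_present_unchanged(self):
        t = impute_me(self._table([0.01, 0.02, 0.03]), "mean")
        np.testing.assert_allclose(t.me_var, [0.01, 0.02, 0.03])

    def test_mean_policy(self):
        t = impute_me(self._table([0.01, 0.03, np.nan]), "mean")
        assert t.me_var[2] == pytest.approx(0.02)

    def test_zero_policy(self):
        t = impute_me(self._table([np.nan, np.nan, np.nan]), "zero")
        np.testing.assert_allclose(t.me_var, 0.0)

    def test_fixed_policy(self):
        t = impute_me(self._table([0.01, np.nan, np.nan]), "fixed:0.005")
        np.testing.assert_allclose(t.me_var[1:], 0.005)

    def test_mean_with_nothing_observed_errors(self):
        with pytest.raises(ou.TraitError, match="zero"):
            impute_me(self._table([np.nan] * 3), "mean")

    def test_policy_recorded(self):
        t = impute_me(self._table([np.nan] * 3), "zero")
        assert t.me_policy == "zero"


def test_read_traits_roundtrip(tmp_path, five_tip_tree):
    tab = ou.TraitTable(species=["A", "B", "C", "D", "E"],
                        log_df=np.log([900, 1100, 2500, 4000, 700.0]),
                        log_size=np.log([45, 38, 22, 18, 60.0]),
                        site=np.array(["terrestrial", "aquatic", "arboreal",
                                       "terrestrial", "aquatic"], dtype=object),
                        me_var=np.array([0.01, np.nan, 0.02, np.nan, 0.005]))
    path = tmp_path / "traits.csv"
    tab.write_raw(path)
    raw = read_traits(path)
    tree, back = reconcile(five_tip_tree, raw)
    np.testing.assert_allclose(
        sorted(back.log_df), sorted(tab.log_df), rtol=1e-12)
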