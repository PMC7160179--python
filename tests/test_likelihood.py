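"""OU allometric likelihood: closed-form examples, oracles, invariants."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import multivariate_normal

import oushift as ou
from oushift.likelihood import LikelihoodError

from conftest import (oracle_hansen_weights, oracle_loglik, oracle_ou_cov,
                      random_params, random_table, random_tree_and_config)


@pytest.fixture
def single_tip():
    return ou.Phylogeny.from_newick("(A:2);")


class TestHansenWeights:
    def test_no_shift_all_weight_on_root(self, five_tip_tree):
        painting = ou.paint(five_tip_tree, ou.ShiftConfig(()))
        W = ou.hansen_weights(five_tip_tree, painting, 1.7)
        np.testing.assert_allclose(W, np.ones((5, 1)))

    def test_single_lineage_closed_form(self, single_tip):
        # depth-2 lineage, shift at time 1, alpha=1: the shifted regime gets
        # 1 - e^-1; the root regime e^-1 (segment e^-1 - e^-2 plus root pull e^-2)
        b = single_tip.clade_branch(["A"])
        config = ou.ShiftConfig.of([ou.ShiftPoint(b, 0.5)], single_tip)
        W = ou.hansen_weights(single_tip, ou.paint(single_tip, config), 1.0)
        assert W[0, 1] == pytest.approx(1 - math.exp(-1))          # 0.6321
        assert W[0, 0] == pytest.approx(math.exp(-1))
        assert W[0, 0] - math.exp(-2) == pytest.approx(
            math.exp(-1) - math.exp(-2))                           # 0.2325 segment
        assert W.sum() == pytest.approx(1.0, abs=1e-12)

    def test_large_alpha_saturates_terminal_regime(self, five_tip_tree):
        b = five_tip_tree.clade_branch(["A", "B"])
        config = ou.ShiftConfig.of([ou.ShiftPoint(b, 0.0)], five_tip_tree)
        painting = ou.paint(five_tip_tree, config)
        W = ou.hansen_weights(five_tip_tree, painting, 80.0)
        for i, r in enumerate(painting.tip_regime):
            assert W[i, r] == pytest.approx(1.0, abs=1e-12)

    def test_alpha_zero_limit(self, five_tip_tree):
        b = five_tip_tree.clade_branch(["A", "B"])
        config = ou.ShiftConfig.of([ou.ShiftPoint(b, 0.3)], five_tip_tree)
        W = ou.hansen_weights(five_tip_tree, ou.paint(five_tip_tree, config), 0.0)
        np.testing.assert_allclose(W[:, 0], 1.0)

    @given(alpha=st.floats(0.0, 50.0), seed=st.integers(0, 200))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_rows_sum_to_one(self, alpha, seed):
        tree, config = random_tree_and_config(seed)
        W = ou.hansen_weights(tree, ou.paint(tree, config), alpha)
        np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-10)

    @pytest.mark.parametrize("seed", range(12))
    def test_fast_path_matches_reference(self, seed):
        tree, config = random_tree_and_config(seed, max_tips=8, max_shifts=4)
        rng = np.random.default_rng(seed)
        alpha = float(rng.uniform(0.01, 5.0))
        W_ref = ou.hansen_weights(tree, ou.paint(tree, config), alpha)
        masks = tree.below_mask()[[s.branch for s in config.shifts]]
        W_fast = ou.fast_hansen_weights(tree.tip_depths, masks,
                                        config.shift_times(tree), alpha)
        np.testing.assert_allclose(W_fast, W_ref, atol=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_segment_oracle(self, seed):
        tree, config = random_tree_and_config(seed)
        alpha = 0.8 + 0.3 * seed
        W = ou.hansen_weights(tree, ou.paint(tree, config), alpha)
        np.testing.assert_allclose(
            W, oracle_hansen_weights(tree, config, alpha), atol=1e-12)


class TestOUCovariance:
    def test_single_tip_closed_form(self, single_tip):
        tree1 = ou.Phylogeny.from_newick("(A:1);")
        V = ou.ou_covariance(tree1, alpha=1.0, sigma2=2.0)
        assert V[0, 0] == pytest.approx(1 - math.exp(-2))  # 0.8647

    def test_bm_limit_is_shared_path_matrix(self, five_tip_tree):
        V = ou.ou_covariance(five_tip_tree, alpha=0.0, sigma2=0.7)
        np.testing.assert_allclose(V, 0.7 * five_tip_tree.shared_depths())

    def test_three_tip_entries_match_scalar_oracle(self, cherry_tree):
        V = ou.ou_covariance(cherry_tree, alpha=0.5, sigma2=1.0)
        np.testing.assert_allclose(V, oracle_ou_cov(cherry_tree, 0.5, 1.0),
                                   rtol=1e-12)

    def test_me_added_to_diagonal(self, cherry_tree):
        me = np.array([0.1, 0.2, 0.3])
        V0 = ou.ou_covariance(cherry_tree, 1.0, 1.0)
        V1 = ou.ou_covariance(cherry_tree, 1.0, 1.0, me)
        np.testing.assert_allclose(V1 - V0, np.diag(me))


class TestLogLik:
    def test_univariate_closed_form(self):
        tree1 = ou.Phylogeny.from_newick("(A:1);")
        table = ou.TraitTable(species=["A"], log_df=[0.0], log_size=[0.0],
                              site=["terrestrial"], me_var=[0.0])
        params = ou.RegimeParams(theta=[0.0], beta_size=[0.0], alpha=1.0,
                                 sigma2=2.0)
        ll = ou.loglik(tree1, table, "a", ou.ShiftConfig(()), params)
        v = 1 - math.exp(-2)
        assert ll == pytest.approx(-0.5 * math.log(2 * math.pi * v))  # -0.8463

    def test_univariate_with_me_unit_variance(self):
        tree1 = ou.Phylogeny.from_newick("(A:1);")
        v = 1 - math.exp(-2)
        table = ou.TraitTable(species=["A"], log_df=[0.0], log_size=[0.0],
                              site=["terrestrial"], me_var=[1.0 - v])
        params = ou.RegimeParams(theta=[0.0], beta_size=[0.0], alpha=1.0,
                                 sigma2=2.0)
        ll = ou.loglik(tree1, table, "a", ou.ShiftConfig(()), params)
        assert ll == pytest.approx(-0.5 * math.log(2 * math.pi))  # -0.9189

    @pytest.mark.parametrize("form", ["a", "b", "c"])
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_dense_oracle(self, form, seed):
        tree, config = random_tree_and_config(seed, max_tips=8, max_shifts=3)
        rng = np.random.default_rng(100 + seed)
        params = random_params(rng, config.k, form)
        table = random_table(tree, 200 + seed)
        ll = ou.loglik(tree, table, form, config, params)
        assert ll == pytest.approx(
            oracle_loglik(tree, table, form, config, params), rel=1e-8)

    def test_bm_limit_matches_independent_bm_likelihood(self):
        """alpha -> 0, K=0, slopes 0: reduce to plain BM; covariance built
        from dendropy's phylogenetic distance matrix as the outside path."""
        import dendropy
        tree = ou.simulate_tree(12, seed=9)
        table = random_table(tree, 3, with_me=False)
        sigma2, theta = 0.6, 8.8
        params = ou.RegimeParams(theta=[theta], beta_size=[0.0], alpha=0.0,
                                 sigma2=sigma2)
        ll = ou.loglik(tree, table, "a", ou.ShiftConfig(()), params)
        dtree = dendropy.Tree.get(data=tree.to_newick(), schema="newick",
                                  preserve_underscores=True)
        pdm = dtree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in dtree.taxon_namespace}
        n = tree.n_tips
        C = np.zeros((n, n))
        for i, li in enumerate(tree.tip_labels):
            for j, lj in enumerate(tree.tip_labels):
                d = pdm.patristic_distance(taxa[li], taxa[lj])
                C[i, j] = sigma2 * 0.5 * (tree.tip_depths[i]
                                          + tree.tip_depths[j] - d)
        ll_bm = multivariate_normal.logpdf(table.log_df, mean=np.full(n, theta),
                                           cov=C)
        assert ll == pytest.approx(ll_bm, rel=1e-8)

    def test_invariant_to_regime_relabeling(self, five_tip_tree):
        """Swapping shift-set order must not change the likelihood because
        canonicalization pairs each regime with its own parameters."""
        b1 = five_tip_tree.clade_branch(["A", "B"])
        b2 = five_tip_tree.clade_branch(["D", "E"])
        table = random_table(five_tip_tree, 4)
        c12 = ou.ShiftConfig.of([ou.ShiftPoint(b1, 0.5), ou.ShiftPoint(b2, 0.5)],
                                five_tip_tree)
        params = ou.RegimeParams(theta=[9.0, 8.0, 10.0],
                                 beta_size=[-0.4, -0.1, -0.7],
                                 alpha=1.2, sigma2=0.5)
        ll = ou.loglik(five_tip_tree, table, "a", c12, params)
        # same shifts given in the other order: canonical order re-sorts them,
        # so the same (branch -> parameters) pairing must be supplied
        c21 = ou.ShiftConfig.of([ou.ShiftPoint(b2, 0.5), ou.ShiftPoint(b1, 0.5)],
                                five_tip_tree)
        ll2 = ou.loglik(five_tip_tree, table, "a", c21, params)
        assert ll2 == pytest.approx(ll, rel=1e-12)

    def test_me_increases_variance_decreases_precision(self):
        tree1 = ou.Phylogeny.from_newick("(A:1);")
        params = ou.RegimeParams(theta=[0.0], beta_size=[0.0], alpha=1.0,
                                 sigma2=2.0)
        base = ou.TraitTable(species=["A"], log_df=[0.0], log_size=[0.0],
                             site=["terrestrial"], me_var=[0.0])
        noisy = ou.TraitTable(species=["A"], log_df=[0.0], log_size=[0.0],
                              site=["terrestrial"], me_var=[0.5])
        # zero residual: density at the mean drops as variance grows
        assert ou.loglik(tree1, noisy, "a", ou.ShiftConfig(()), params) < \
            ou.loglik(tree1, base, "a", ou.ShiftConfig(()), params)

    def test_param_config_mismatch_rejected(self, five_tip_tree):
        table = random_table(five_tip_tree, 5)
        params = ou.RegimeParams(theta=[9.0, 8.0], beta_size=[-0.4, -0.2],
                                 alpha=1.0, sigma2=0.5)
        with pytest.raises(LikelihoodError, match="regimes"):
            ou.loglik(five_tip_tree, table, "a", ou.ShiftConfig(()), params)
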