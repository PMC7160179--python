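"""rjMCMC sampler: determinism, exact small-system posteriors, prior runs."""
import numpy as np
import pytest

import oushift as ou
from oushift.priors import k_marginal_exact

from conftest import random_table


@pytest.fixture(scope="module")
def small_data():
    tree = ou.simulate_tree(20, seed=7)
    table, _ = ou.simulate_traits(tree, ou.SimConfig(n_tips=20, seed=8))
    return tree, table


class TestDeterminism:
    def test_identical_seeds_identical_traces(self, small_data):
        tree, table = small_data
        kw = dict(generations=3000, thinning=10, seed=42)
        t1 = ou.run_chain(tree, table, "a", ou.Priors(kmax=10), **kw)
        t2 = ou.run_chain(tree, table, "a", ou.Priors(kmax=10), **kw)
        assert t1.samples == t2.samples

    def test_distinct_chains_distinct_traces(self, small_data):
        tree, table = small_data
        traces = ou.run_analysis(tree, table, "a", ou.Priors(kmax=10),
                                 n_chains=3, generations=3000, thinning=10,
                                 seed=1)
        hashes = {tuple(t.scalar("loglik")) for t in traces}
        assert len(hashes) == 3
        assert len({t.meta["tree_hash"] for t in traces}) == 1

    def test_sample_count_matches_thinning(self, small_data):
        tree, table = small_data
        t = ou.run_chain(tree, table, "a", ou.Priors(kmax=5),
                         generations=5500, thinning=100, seed=0)
        assert len(t.samples) == 55

    def test_trace_file_roundtrip(self, small_data, tmp_path):
        tree, table = small_data
        t = ou.run_chain(tree, table, "b", ou.Priors(kmax=5),
                         generations=2000, thinning=20, seed=3)
        t.write(tmp_path / "trace.tsv")
        back = ou.ChainTrace.read(tmp_path / "trace.tsv")
        assert back.samples == t.samples
        assert back.form == "b"


class TestMoves:
    def test_kmax_zero_never_jumps(self, small_data):
        tree, table = small_data
        t = ou.run_chain(tree, table, "a", ou.Priors(kmax=0),
                         generations=4000, thinning=10, seed=5)
        assert set(t.k_values(burnin=False)) == {0}

    def test_kmax_caps_shift_count(self, small_data):
        tree, table = small_data
        t = ou.run_chain(tree, table, "a", ou.Priors(kmax=3),
                         generations=6000, thinning=10, seed=6, power=0.0)
        assert t.k_values(burnin=False).max() <= 3

    def test_cached_loglik_spot_check_passes(self, small_data):
        # run_chain raises if the incremental likelihood drifts from the
        # reference paint-and-weights path
        tree, table = small_data
        ou.run_chain(tree, table, "c", ou.Priors(kmax=10),
                     generations=5000, thinning=50, seed=9,
                     spot_check_every=1000)


class TestExactSmallPosterior:
    """Stationary distribution of K vs brute-force enumeration.

    On a 4-tip tree with K_max = 1 and alpha, sigma2 held fixed, theta and
    slope integrate out analytically (Gaussian linear model), and the shift
    position is a 1-D integral per branch done by quadrature.
    """

    @staticmethod
    def _marginal_datafit(tree, table, config, priors, alpha, sigma2):
        painting = ou.paint(tree, config)
        W = ou.hansen_weights(tree, painting, alpha)
        X = np.column_stack([W, W * table.log_size[:, None]])
        k1 = W.shape[1]
        m0 = np.concatenate([np.full(k1, priors.intercept_mean),
                             np.full(k1, priors.slope_mean)])
        S0 = np.diag(np.concatenate([np.full(k1, priors.intercept_sd ** 2),
                                     np.full(k1, priors.slope_sd ** 2)]))
        V = ou.ou_covariance(tree, alpha, sigma2, table.me_filled())
        C = X @ S0 @ X.T + V
        return ou.mvn_loglik(table.log_df, X @ m0, C)

    def test_k_posterior_matches_enumeration(self, quartet_tree):
        tree = quartet_tree
        table = random_table(tree, 11, with_me=False)
        alpha, sigma2 = 1.0, 0.3
        priors = ou.Priors(kmax=1, intercept_mean=9.0, intercept_sd=0.8,
                           alpha_prior=("fixed", alpha),
                           sigma2_prior=("fixed", sigma2)).resolve(table)
        # enumeration: posterior odds K=1 vs K=0
        m0 = self._marginal_datafit(tree, table, ou.ShiftConfig(()),
                                    priors, alpha, sigma2)
        nodes, weights = np.polynomial.legendre.leggauss(16)
        u = 0.5 * (nodes + 1.0)
        wq = 0.5 * weights
        L = tree.lengths[tree.branch_ids()].sum()
        total = 0.0
        for b in tree.branch_ids():
            vals = np.array([
                self._marginal_datafit(
                    tree, table,
                    ou.ShiftConfig.of([ou.ShiftPoint(int(b), float(ui))], tree),
                    priors, alpha, sigma2)
                for ui in u])
            total += tree.lengths[b] / L * float(wq @ np.exp(vals - m0))
        p1_exact = total / (1.0 + total)
        trace = ou.run_chain(tree, table, "a", priors, generations=300_000,
                             thinning=30, seed=4)
        p1_mcmc = float(np.mean(trace.k_values() == 1))
        assert p1_mcmc == pytest.approx(p1_exact, abs=0.03)


class TestPriorRuns:
    def test_data_free_k_matches_exact_prior_marginal(self, small_data):
        tree, table = small_data
        priors = ou.Priors(kmax=15)
        trace = ou.run_chain(tree, table, "a", priors, generations=200_000,
                             thinning=20, seed=21, power=0.0)
        k = trace.k_values()
        exact = k_marginal_exact(tree, priors.resolve(table))
        expected = float(exact @ np.arange(len(exact)))
        from oushift.diagnostics import ess_1d
        mcse = k.std() / np.sqrt(ess_1d(k))
        assert abs(k.mean() - expected) < 3 * max(mcse, 1e-6)

    def test_k_marginal_exact_matches_direct_enumeration(self):
        # 3 branches with lengths 1, 2, 3: k! e_k(l/L) has a closed hand value
        tree = ou.Phylogeny.from_newick("((A:1,B:2):3,C:6);")
        # branches: A(1), B(2), AB(3), C(6); L=12
        priors = ou.Priors(kmax=4, intercept_mean=0, intercept_sd=1)
        m = k_marginal_exact(tree, priors)
        f = np.array([1.0, 2.0, 3.0, 6.0]) / 12.0
        import itertools
        import math
        w = np.zeros(5)
        for k in range(5):
            tot = 0.0
            for comb in itertools.combinations(range(4), k):
                p = 1.0
                for i in comb:
                    p *= f[i]
                tot += p
            w[k] = math.factorial(k) * tot
        w /= w.sum()
        np.testing.assert_allclose(m, w, atol=1e-12)


def test_poisson_k_prior_normalized():
    priors = ou.Priors(kmax=10, k_prior=("poisson", 2.0))
    logs = np.array([priors.log_k(k) for k in range(11)])
    assert np.exp(logs).sum() == pytest.approx(1.0, abs=1e-12)
    assert priors.log_k(11) == -np.inf
    # truncated-Poisson shape: mode at lambda
    assert np.argmax(logs) == 2
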