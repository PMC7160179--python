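"""Shared fixtures and independent oracle implementations.

The oracles deliberately avoid the package's computational paths: regime
assignment by an explicit root-to-tip walk, Hansen weights by per-segment
evaluation of the exponential integral, and the likelihood through
scipy.stats.multivariate_normal on a covariance assembled entry by entry.
"""
import numpy as np
import pytest
from scipy.stats import multivariate_normal

import oushift as ou


@pytest.fixture
def cherry_tree():
    return ou.Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def quartet_tree():
    return ou.Phylogeny.from_newick("((A:0.5,B:0.5):0.5,(C:0.5,D:0.5):0.5);")


@pytest.fixture
def five_tip_tree():
    return ou.Phylogeny.from_newick(
        "(((A:1,B:1):1,C:2):1,(D:1.5,E:1.5):1.5);")


def random_tree_and_config(seed, max_tips=8, max_shifts=3):
    """Small random ultrametric tree plus a random valid shift config."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, max_tips + 1))
    tree = ou.simulate_tree(n, seed=seed)
    branches = tree.branch_ids()
    k = int(rng.integers(0, min(max_shifts, len(branches)) + 1))
    chosen = rng.choice(branches, size=k, replace=False)
    shifts = [ou.ShiftPoint(int(b), float(rng.random())) for b in chosen]
    return tree, ou.ShiftConfig.of(shifts, tree)


def tip_path_events(tree, config):
    """For each tip: shift (time, canonical regime id) events on its root
    path, found by walking parent pointers -- independent of paint()."""
    config = ou.ShiftConfig.of(config.shifts, tree)
    by_branch = {}
    for j, s in enumerate(config.shifts):
        t = tree.depths[tree.parent[s.branch]] + s.position * tree.lengths[s.branch]
        by_branch[s.branch] = (j + 1, t)
    events = []
    for tid in tree.tip_ids:
        path = []
        v = int(tid)
        while v != tree.root:
            if v in by_branch:
                path.append(by_branch[v])
            v = int(tree.parent[v])
        path.sort(key=lambda e: e[1])
        events.append(path)
    return events


def oracle_tip_regimes(tree, config):
    """Terminal regime per tip via the root-to-tip walk."""
    out = np.zeros(tree.n_tips, dtype=int)
    for i, ev in enumerate(tip_path_events(tree, config)):
        out[i] = ev[-1][0] if ev else 0
    return out


def oracle_hansen_weights(tree, config, alpha):
    """Per-tip segment-wise evaluation of the Hansen weight integrals."""
    k = config.k
    W = np.zeros((tree.n_tips, k + 1))
    if alpha < 1e-8:
        W[:, 0] = 1.0
        return W
    for i, ev in enumerate(tip_path_events(tree, config)):
        T = tree.tip_depths[i]
        bounds = [0.0] + [t for (_, t) in ev] + [T]
        regimes = [0] + [r for (r, _) in ev]
        for seg in range(len(regimes)):
            t0, t1 = bounds[seg], bounds[seg + 1]
            W[i, regimes[seg]] += np.exp(-alpha * (T - t1)) - np.exp(-alpha * (T - t0))
        W[i, 0] += np.exp(-alpha * T)
    return W


def oracle_shared_depth(tree, i, j):
    """MRCA depth of tip positions i, j via explicit ancestor sets."""
    if i == j:
        return tree.tip_depths[i]
    anc = {}
    v = int(tree.tip_ids[i])
    while v >= 0:
        anc[v] = tree.depths[v]
        v = int(tree.parent[v]) if v != tree.root else -1
    v = int(tree.tip_ids[j])
    while v not in anc:
        v = int(tree.parent[v])
    return anc[v]


def oracle_ou_cov(tree, alpha, sigma2, me=None):
    n = tree.n_tips
    V = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            s = oracle_shared_depth(tree, i, j)
            ti, tj = tree.tip_depths[i], tree.tip_depths[j]
            if alpha < 1e-8:
                V[i, j] = sigma2 * s
            else:
                V[i, j] = (sigma2 / (2 * alpha) * np.exp(-alpha * (ti + tj - 2 * s))
                           * (1 - np.exp(-2 * alpha * s)))
    if me is not None:
        V += np.diag(me)
    return V


def oracle_loglik(tree, table, form, config, params):
    """Dense multivariate-normal evaluation built from the oracles above."""
    W = oracle_hansen_weights(tree, config, params.alpha)
    mu = W @ params.theta + (W @ params.beta_size) * table.log_size
    d = table.site_dummies()
    if form in ("b", "c"):
        mu = mu + d @ params.beta_site
    if form == "c":
        mu = mu + (table.log_size[:, None] * d) @ params.beta_inter
    V = oracle_ou_cov(tree, params.alpha, params.sigma2, table.me_filled())
    return multivariate_normal.logpdf(table.log_df, mean=mu, cov=V)


def random_params(rng, k, form):
    return ou.RegimeParams(
        theta=rng.normal(9.0, 1.0, k + 1),
        beta_size=rng.normal(-0.4, 0.2, k + 1),
        alpha=float(rng.uniform(0.05, 3.0)),
        sigma2=float(rng.uniform(0.1, 1.0)),
        beta_site=rng.normal(0, 0.3, 2) if form in ("b", "c") else None,
        beta_inter=rng.normal(0, 0.1, 2) if form == "c" else None,
    )


def random_table(tree, seed, with_me=True):
    rng = np.random.default_rng(seed)
    me = rng.uniform(0, 0.05, tree.n_tips) if with_me else np.zeros(tree.n_tips)
    return ou.TraitTable(
        species=list(tree.tip_labels),
        log_df=rng.normal(9.0, 0.5, tree.n_tips),
        log_size=rng.normal(3.9, 0.8, tree.n_tips),
        site=np.array(["terrestrial", "aquatic", "arboreal"], dtype=object)[
            rng.integers(0, 3, tree.n_tips)],
        me_var=me,
    )
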