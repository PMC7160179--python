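"""Cross-chain convergence diagnostics and posterior shift summaries.

Convergence is assessed with the classic Gelman-Rubin potential scale
reduction factor computed on per-branch shift posterior probabilities: each
chain's post-burn-in trace of the 0/1 "shift present on branch b" indicator
is split into segments whose means are compared between and within chains.
Effective sample sizes for K, alpha, sigma2 and the log-likelihood come from
arviz.  Chains that converged are pooled for summarization.

A shift is *supported* when its pooled posterior probability reaches the
threshold (default 0.7) and the clade below it holds at least ``min_clade``
species (default 4, i.e. shifts covering three or fewer species are
discarded).  Regime parameter summaries are marginal posteriors over the
pooled samples whose configuration contains the supported shift branch.
"""
from __future__ import annotations

import dataclasses

import arviz as az
import numpy as np
import pandas as pd

from .sampler import ChainTrace
from .tree import Phylogeny


def psrf(chains: list) -> float:
    """Classic Gelman-Rubin potential-scale-reduction factor.

    ``chains`` is a list of 1-D arrays (one per chain, equal length).
    Returns 1.0 (with no spread) when every chain is constant.
    """
    x = np.asarray(chains, dtype=float)
    m, n = x.shape
    if m < 2 or n < 2:
        raise ValueError("psrf needs >= 2 chains with >= 2 samples each")
    means = x.mean(axis=1)
    W = x.var(axis=1, ddof=1).mean()
    if W == 0.0:
        return 1.0
    B = n * means.var(ddof=1)
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


@dataclasses.dataclass
class DiagnosticsReport:
    branch_r: dict           # branch id -> PSRF of its shift indicator
    ess: dict                # name -> effective sample size
    max_r: float
    converged: bool
    threshold: float
    notes: list

    def to_dict(self) -> dict:
        return {
            "branch_r": {str(k): v for k, v in self.branch_r.items()},
            "ess": self.ess, "max_r": self.max_r,
            "converged": self.converged, "threshold": self.threshold,
            "notes": self.notes,
        }


def _branch_indicators(trace_samples, branches):
    ind = {int(b): np.zeros(len(trace_samples)) for b in branches}
    for i, s in enumerate(trace_samples):
        for (b, _) in s.shifts:
            ind[int(b)][i] = 1.0
    return ind


def gelman_r(traces: list, tree: Phylogeny, r_threshold: float = 1.1) -> DiagnosticsReport:
    """Per-branch PSRF on shift posterior probabilities, plus scalar ESS."""
    notes = []
    if len(traces) < 2:
        return DiagnosticsReport(
            branch_r={}, ess=_scalar_ess(traces), max_r=float("nan"),
            converged=False, threshold=r_threshold,
            notes=["single chain: convergence cannot be assessed"])
    posts = [t.post_burnin() for t in traces]
    n = min(len(p) for p in posts)
    if n < 10:
        raise ValueError("need >= 10 post-burn-in samples per chain")
    posts = [p[-n:] for p in posts]
    branches = tree.branch_ids()
    per_chain = [_branch_indicators(p, branches) for p in posts]
    branch_r = {}
    for b in branches:
        series = [pc[int(b)] for pc in per_chain]
        if all(s.var() == 0 for s in series) and len({s[0] for s in series}) == 1:
            branch_r[int(b)] = 1.0
            continue
        branch_r[int(b)] = psrf(series)
    zero_var = sum(1 for v in branch_r.values() if v == 1.0)
    if zero_var:
        notes.append(f"{zero_var} branches had zero indicator variance; R set to 1")
    max_r = max(branch_r.values()) if branch_r else 1.0
    return DiagnosticsReport(
        branch_r=branch_r, ess=_scalar_ess(traces), max_r=float(max_r),
        converged=bool(max_r < r_threshold), threshold=r_threshold, notes=notes)


def _scalar_ess(traces: list) -> dict:
    out = {}
    posts = [t.post_burnin() for t in traces]
    n = min(len(p) for p in posts)
    for name in ("k", "alpha", "sigma2", "loglik"):
        arr = np.array([[getattr(s, name) for s in p[-n:]] for p in posts], float)
        if np.allclose(arr.var(), 0.0):
            out[name] = float(arr.shape[0] * arr.shape[1])
            continue
        val = az.ess(az.convert_to_dataset(arr[:, :, None]))["x"].values
        out[name] = float(np.asarray(val).ravel()[0])
    return out


def ess_1d(values: np.ndarray) -> float:
    """Effective sample size of a single chain of scalar draws."""
    arr = np.asarray(values, dtype=float)[None, :, None]
    if np.allclose(arr.var(), 0.0):
        return float(arr.size)
    val = az.ess(az.convert_to_dataset(arr))["x"].values
    return float(np.asarray(val).ravel()[0])


@dataclasses.dataclass
class RegimeSummary:
    branch: int | None        # None for the root regime
    pp: float
    n_tips: int
    theta_median: float
    theta_ci: tuple
    beta_median: float
    beta_ci: tuple
    mean_age: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class ShiftSummary:
    branch_pp: dict           # branch id -> posterior probability of a shift
    mean_k: float
    supported: list           # branch ids passing pp and clade-size filters
    supported_at: dict        # threshold -> branch list (0.5 / 0.7 / 0.9)
    regimes: list             # RegimeSummary, root first
    pp_threshold: float
    min_clade: int
    n_samples: int

    def to_frame(self) -> pd.DataFrame:
        """Regimes table: optimum, slope, mean age, species count."""
        return pd.DataFrame([
            {"regime": "root" if r.branch is None else f"branch_{r.branch}",
             "theta_df": r.theta_median, "beta_body_size": r.beta_median,
             "mean_age": r.mean_age, "n_species": r.n_tips, "pp": r.pp}
            for r in self.regimes
        ])

    def to_dict(self) -> dict:
        return {
            "branch_pp": {str(k): v for k, v in self.branch_pp.items()},
            "mean_k": self.mean_k, "supported": self.supported,
            "supported_at": {str(k): v for k, v in self.supported_at.items()},
            "regimes": [r.to_dict() for r in self.regimes],
            "pp_threshold": self.pp_threshold, "min_clade": self.min_clade,
            "n_samples": self.n_samples,
        }


def _clade_age(tree: Phylogeny, node: int | None) -> float:
    """Mean age (depth below the present) of internal nodes in a clade.

    Age of node v = tree depth - depth(v).  For the root regime the clade is
    the whole tree.  A convention: the regime's age profile is taken over the
    internal nodes of the subtree subtended by its originating branch
    (including the subtending node itself).
    """
    height = tree.depth
    if node is None:
        nodes = [v for v in range(tree.n_nodes) if tree.children[v]]
    else:
        nodes = []
        stack = [node]
        while stack:
            v = stack.pop()
            if tree.children[v]:
                nodes.append(v)
                stack.extend(tree.children[v])
        if not nodes:          # shift on a terminal branch
            nodes = [int(tree.parent[node])]
    return float(np.mean([height - tree.depths[v] for v in nodes]))


def summarize_shifts(traces: list, tree: Phylogeny, pp_threshold: float = 0.7,
                     min_clade: int = 4) -> ShiftSummary:
    """Pool post-burn-in samples and summarize shift support and regimes."""
    pooled = []
    for t in traces:
        pooled.extend(t.post_burnin())
    if not pooled:
        raise ValueError("no post-burn-in samples to summarize")
    n = len(pooled)
    counts: dict = {}
    for s in pooled:
        for (b, _) in s.shifts:
            counts[int(b)] = counts.get(int(b), 0) + 1
    branch_pp = {b: c / n for b, c in sorted(counts.items())}
    mean_k = float(np.mean([s.k for s in pooled]))

    below = tree.below_mask()

    def passing(thr):
        return [b for b, p in branch_pp.items()
                if p >= thr and int(below[b].sum()) >= min_clade]

    supported = passing(pp_threshold)
    supported_at = {thr: passing(thr) for thr in (0.5, 0.7, 0.9)}

    # root regime: marginal over all pooled samples
    theta_root = np.array([s.theta[0] for s in pooled])
    beta_root = np.array([s.beta_size[0] for s in pooled])

    def ci(v):
        return (float(np.quantile(v, 0.025)), float(np.quantile(v, 0.975)))

    regimes = [RegimeSummary(
        branch=None, pp=1.0, n_tips=tree.n_tips,
        theta_median=float(np.median(theta_root)), theta_ci=ci(theta_root),
        beta_median=float(np.median(beta_root)), beta_ci=ci(beta_root),
        mean_age=_clade_age(tree, None))]
    for b in supported:
        th, be = [], []
        for s in pooled:
            for j, (sb, _) in enumerate(s.shifts):
                if sb == b:
                    th.append(s.theta[j + 1])
                    be.append(s.beta_size[j + 1])
                    break
        th, be = np.array(th), np.array(be)
        regimes.append(RegimeSummary(
            branch=int(b), pp=branch_pp[b], n_tips=int(below[b].sum()),
            theta_median=float(np.median(th)), theta_ci=ci(th),
            beta_median=float(np.median(be)), beta_ci=ci(be),
            mean_age=_clade_age(tree, int(b))))
    return ShiftSummary(
        branch_pp=branch_pp, mean_k=mean_k, supported=supported,
        supported_at=supported_at, regimes=regimes,
        pp_threshold=pp_threshold, min_clade=min_clade, n_samples=n)


def annotated_newick(tree: Phylogeny, summary: ShiftSummary) -> str:
    """Newick with per-branch shift posterior probabilities as comments."""
    parts = [None] * tree.n_nodes
    tip_pos = {int(t): i for i, t in enumerate(tree.tip_ids)}
    for v in range(tree.n_nodes):
        pp = summary.branch_pp.get(v, 0.0)
        note = f"[&pp={pp:.4f}]" if v != tree.root else ""
        if not tree.children[v]:
            parts[v] = f"{tree.tip_labels[tip_pos[v]]}:{tree.lengths[v]:.12g}{note}"
        else:
            inner = ",".join(parts[c] for c in tree.children[v])
            if v == tree.root:
                parts[v] = f"({inner});"
            else:
                parts[v] = f"({inner}):{tree.lengths[v]:.12g}{note}"
    return parts[tree.root]


def plot_painted_tree(tree: Phylogeny, summary: ShiftSummary, path=None):
    """Minimal painted-tree figure: lineages colored by supported regime."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    below = tree.below_mask()
    regime_of_tip = np.zeros(tree.n_tips, dtype=int)
    for r, b in enumerate(summary.supported, start=1):
        regime_of_tip[below[b]] = r
    cmap = plt.get_cmap("tab10")
    ys = {}
    for i, t in enumerate(tree.tip_ids):
        ys[int(t)] = i
    for v in range(tree.n_nodes):  # postorder: children first
        if tree.children[v]:
            ys[v] = float(np.mean([ys[c] for c in tree.children[v]]))
    fig, ax = plt.subplots(figsize=(6, max(3, tree.n_tips * 0.12)))
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        p = int(tree.parent[v])
        tips = np.flatnonzero(below[v])
        reg = int(regime_of_tip[tips[0]]) if np.all(
            regime_of_tip[tips] == regime_of_tip[tips[0]]) else 0
        color = "0.4" if reg == 0 else cmap((reg - 1) % 10)
        ax.plot([tree.depths[p], tree.depths[v]], [ys[v], ys[v]], color=color, lw=1.2)
        ax.plot([tree.depths[p], tree.depths[p]], [ys[p], ys[v]], color="0.7", lw=0.6)
    ax.set_yticks([])
    ax.set_xlabel("time from root")
    ax.set_title(f"{len(summary.supported)} supported shifts "
                 f"(pp >= {summary.pp_threshold})")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
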