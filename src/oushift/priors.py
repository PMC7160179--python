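"""Priors for the multi-optima OU allometric model.

Defaults follow the study design this package supports: slope coefficients
are N(0, 0.2); regime optima (intercepts) are N(mean of log frequency,
1.5 x sd of log frequency), resolved from the data at hand; the number of
shifts K is uniform on {0, ..., K_max} with K_max = 200; shift locations are
chosen with probability proportional to branch length, position uniform on
the branch, at most one shift per branch.

The joint prior over a shift *set* of size K is therefore

    p(K) * K! * prod_b (len_b / L)        (distinct branches),

whose marginal over K is p(K) * K! * e_K(len/L) with e_K the K-th elementary
symmetric polynomial of the normalized branch lengths -- slightly
down-weighting large K relative to p(K) because branches cannot be reused.
:func:`k_marginal_exact` computes that marginal exactly; the data-free
sampler run must reproduce it.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np

from .tree import Phylogeny
from .traits import TraitTable


class PriorError(ValueError):
    pass


_LOG2PI = math.log(2.0 * math.pi)


def _norm_logpdf_sum(x, mean, sd):
    c = math.log(sd) + 0.5 * _LOG2PI
    if np.ndim(x) == 0:
        z = (float(x) - mean) / sd
        return -0.5 * z * z - c
    x = np.ravel(x)
    if x.size <= 32:  # python loop beats numpy dispatch on tiny arrays
        tot = 0.0
        for v in x:
            z = (float(v) - mean) / sd
            tot += z * z
        return -0.5 * tot - x.size * c
    z = (x - mean) / sd
    return float(-0.5 * np.dot(z, z) - x.size * c)


def _halfnormal_logpdf(x, scale):
    if x < 0:
        return -np.inf
    return (math.log(2.0) - math.log(scale) - 0.5 * _LOG2PI
            - 0.5 * (x / scale) ** 2)


def _loguniform_logpdf(x, lo, hi):
    if not (lo <= x <= hi):
        return -np.inf
    return -math.log(x) - math.log(math.log(hi / lo))


@dataclasses.dataclass
class Priors:
    """Prior specification; ``intercept_*`` of ``None`` resolve from data."""

    slope_mean: float = 0.0
    slope_sd: float = 0.2
    intercept_mean: float | None = None
    intercept_sd: float | None = None
    site_sd: float = 1.0
    inter_sd: float = 0.2
    k_prior: tuple = ("uniform",)          # or ("poisson", lam), truncated at kmax
    kmax: int = 200
    alpha_prior: tuple = ("halfnormal", 2.0)   # or ("loguniform", lo, hi), ("fixed", v)
    sigma2_prior: tuple = ("loguniform", 1e-3, 10.0)  # or ("halfnormal", s), ("fixed", v)

    def __post_init__(self):
        if self.kmax < 0:
            raise PriorError("kmax must be >= 0")
        if self.slope_sd <= 0 or self.site_sd <= 0 or self.inter_sd <= 0:
            raise PriorError("prior standard deviations must be > 0")

    def resolve(self, table: TraitTable) -> "Priors":
        """Fill intercept hyperparameters from the observed log frequencies."""
        out = dataclasses.replace(self)
        if out.intercept_mean is None:
            out.intercept_mean = float(np.mean(table.log_df))
        if out.intercept_sd is None:
            out.intercept_sd = 1.5 * float(np.std(table.log_df, ddof=1))
        return out

    def _require_resolved(self):
        if self.intercept_mean is None or self.intercept_sd is None:
            raise PriorError("intercept prior unresolved; call .resolve(table) first")

    # ------------------------------------------------------------- densities
    def log_theta(self, theta) -> float:
        self._require_resolved()
        return _norm_logpdf_sum(theta, self.intercept_mean, self.intercept_sd)

    def log_beta(self, beta) -> float:
        return _norm_logpdf_sum(beta, self.slope_mean, self.slope_sd)

    def log_beta_site(self, b) -> float:
        return _norm_logpdf_sum(b, 0.0, self.site_sd)

    def log_beta_inter(self, b) -> float:
        return _norm_logpdf_sum(b, 0.0, self.inter_sd)

    def log_k(self, k: int) -> float:
        if not 0 <= k <= self.kmax:
            return -np.inf
        if self.k_prior[0] == "uniform":
            return -np.log(self.kmax + 1)
        if self.k_prior[0] == "poisson":
            lam = self.k_prior[1]
            ks = np.arange(self.kmax + 1)
            logw = ks * np.log(lam) - lam - np.array([math.lgamma(v + 1) for v in ks])
            return float(logw[k] - np.logaddexp.reduce(logw))
        raise PriorError(f"unknown K prior: {self.k_prior}")

    def log_alpha(self, a: float) -> float:
        kind = self.alpha_prior[0]
        if kind == "halfnormal":
            return float(_halfnormal_logpdf(a, self.alpha_prior[1]))
        if kind == "loguniform":
            return float(_loguniform_logpdf(a, *self.alpha_prior[1:3]))
        if kind == "fixed":
            return 0.0
        raise PriorError(f"unknown alpha prior: {self.alpha_prior}")

    def log_sigma2(self, s: float) -> float:
        kind = self.sigma2_prior[0]
        if kind == "halfnormal":
            return float(_halfnormal_logpdf(s, self.sigma2_prior[1]))
        if kind == "loguniform":
            return float(_loguniform_logpdf(s, *self.sigma2_prior[1:3]))
        if kind == "fixed":
            return 0.0
        raise PriorError(f"unknown sigma2 prior: {self.sigma2_prior}")

    # -------------------------------------------------------------- sampling
    def rvs_theta(self, rng: np.random.Generator, size=None):
        self._require_resolved()
        return rng.normal(self.intercept_mean, self.intercept_sd, size=size)

    def rvs_beta(self, rng: np.random.Generator, size=None):
        return rng.normal(self.slope_mean, self.slope_sd, size=size)

    def rvs_alpha(self, rng: np.random.Generator) -> float:
        kind = self.alpha_prior[0]
        if kind == "halfnormal":
            return abs(rng.normal(0.0, self.alpha_prior[1]))
        if kind == "loguniform":
            lo, hi = self.alpha_prior[1:3]
            return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        if kind == "fixed":
            return float(self.alpha_prior[1])
        raise PriorError(f"unknown alpha prior: {self.alpha_prior}")

    def rvs_sigma2(self, rng: np.random.Generator) -> float:
        kind = self.sigma2_prior[0]
        if kind == "halfnormal":
            return abs(rng.normal(0.0, self.sigma2_prior[1]))
        if kind == "loguniform":
            lo, hi = self.sigma2_prior[1:3]
            return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        if kind == "fixed":
            return float(self.sigma2_prior[1])
        raise PriorError(f"unknown sigma2 prior: {self.sigma2_prior}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_prior"] = list(self.k_prior)
        d["alpha_prior"] = list(self.alpha_prior)
        d["sigma2_prior"] = list(self.sigma2_prior)
        return d


def k_marginal_exact(tree: Phylogeny, priors: Priors) -> np.ndarray:
    """Exact prior marginal P(K = k), k = 0..kmax, under the shift-set prior.

    Uses the recurrence for elementary symmetric polynomials of the
    normalized branch lengths; entries beyond the number of branches are 0.
    """
    lens = tree.lengths[tree.branch_ids()]
    frac = lens / lens.sum()
    kmax = priors.kmax
    # w_k = k! e_k(frac): DP with the factorial folded in to stay in range
    w = np.zeros(kmax + 1)
    w[0] = 1.0
    for f in frac:
        upper = min(kmax, len(frac))
        # iterate downward so each branch is used at most once
        w[1:upper + 1] = w[1:upper + 1] + f * np.arange(1, upper + 1) * w[0:upper]
    logp = np.array([priors.log_k(k) for k in range(kmax + 1)])
    with np.errstate(divide="ignore"):
        logw = np.where(w > 0, np.log(np.maximum(w, 1e-300)), -np.inf) + logp
    logw -= np.logaddexp.reduce(logw[np.isfinite(logw)])
    return np.exp(logw)
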