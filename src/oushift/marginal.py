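"""Marginal-likelihood estimation and Bayes-factor model comparison.

Marginal likelihoods are estimated by stepping-stone sampling over a
power-posterior ladder beta_t = (t / T)^(1/0.3), t = 0..T, which concentrates
rungs near the prior where the integrand changes fastest.  Each rung is
sampled with the same rjMCMC kernel as the posterior (likelihood tempered to
beta_t), warm-started from the previous rung.  The estimator is

    log ML = sum_t log (1/N) sum_i exp[(beta_{t+1} - beta_t) * loglik_i],

with samples drawn at beta_t.  The Monte-Carlo standard error is the
delta-method per-rung variance summed over rungs (treating retained, thinned
samples as independent; thin enough for that to be defensible).

Bayes factors are reported on the natural scale; BF > 10 against a competitor
is flagged as strong support, following the usual Kass-Raftery reading.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .diagnostics import ess_1d
from .priors import Priors
from .sampler import run_chain
from .traits import TraitTable
from .tree import Phylogeny


class MarginalError(ValueError):
    pass


@dataclasses.dataclass
class MarginalLik:
    form: str
    log_ml: float
    se: float
    meta: dict

    def to_dict(self) -> dict:
        return {"form": self.form, "log_ml": self.log_ml, "se": self.se,
                "meta": self.meta}


@dataclasses.dataclass
class BayesFactorTable:
    forms: list
    log_ml: np.ndarray
    log_bf: np.ndarray        # log_bf[i, j] = log ML_i - log ML_j
    strong: np.ndarray        # strong[i, j]: BF(i over j) > threshold
    best: str
    threshold: float

    def bf(self, i: str, j: str) -> float:
        a, b = self.forms.index(i), self.forms.index(j)
        return float(np.exp(self.log_bf[a, b]))

    def to_dict(self) -> dict:
        return {
            "forms": self.forms,
            "log_ml": self.log_ml.tolist(),
            "log_bf": self.log_bf.tolist(),
            "two_ln_bf": (2.0 * self.log_bf).tolist(),
            "strong": self.strong.tolist(),
            "best": self.best,
            "threshold": self.threshold,
        }


def stepping_stone_ladder(rungs: int, exponent: float = 0.3) -> np.ndarray:
    """Power ladder beta_t = (t/T)^(1/exponent), t = 0..T (T = rungs)."""
    if rungs < 2:
        raise MarginalError("need at least 2 rungs")
    t = np.arange(rungs + 1)
    return (t / rungs) ** (1.0 / exponent)


def stepping_stone(tree: Phylogeny, table: TraitTable, form: str,
                   priors: Priors, rungs: int = 20,
                   gens_per_rung: int = 10_000, thinning: int = 20,
                   seed: int = 0, exponent: float = 0.3,
                   burnin_frac: float = 0.25, data_free: bool = False,
                   **chain_kwargs) -> MarginalLik:
    """Stepping-stone estimate of the log marginal likelihood (nats).

    ``data_free=True`` replaces the likelihood with a flat one (every rung
    samples the prior); the estimate is then 0 up to Monte-Carlo error and
    serves as a self-check of the ladder plumbing.
    """
    betas = stepping_stone_ladder(rungs, exponent)
    if data_free:
        betas = np.zeros_like(betas)
    log_ml = 0.0
    var_sum = 0.0
    init = None
    rung_means = []
    for t in range(rungs):
        trace, chain = run_chain(
            tree, table, form, priors, generations=gens_per_rung,
            thinning=thinning, seed=seed + t, power=float(betas[t]),
            burnin_frac=burnin_frac, init=init, return_chain=True,
            spot_check_every=0, **chain_kwargs)
        init = chain.snapshot()
        ll = trace.scalar("loglik")
        d = betas[t + 1] - betas[t]
        w = d * ll
        m = float(np.max(w))
        ratios = np.exp(w - m)
        mean_r = float(np.mean(ratios))
        if not np.isfinite(mean_r) or mean_r <= 0:
            raise MarginalError(
                f"non-finite rung average at rung {t} (beta={betas[t]:.4g}); "
                f"loglik range [{ll.min():.3g}, {ll.max():.3g}]")
        contrib = m + np.log(mean_r)
        log_ml += contrib
        rung_means.append(contrib)
        # delta method with the effective (not nominal) sample size:
        # var(log mean w) ~ var(w) / (ESS * mean(w)^2)
        n_eff = max(ess_1d(ratios), 2.0) if np.var(ratios) > 0 else len(ratios)
        var_sum += float(np.var(ratios, ddof=1) / (n_eff * mean_r ** 2))
    return MarginalLik(
        form=form, log_ml=float(log_ml), se=float(np.sqrt(var_sum)),
        meta={"rungs": rungs, "gens_per_rung": gens_per_rung,
              "thinning": thinning, "seed": seed, "exponent": exponent,
              "rung_contributions": rung_means},
    )


def compare(models: list, threshold: float = 10.0) -> BayesFactorTable:
    """Pairwise Bayes factors among fitted models; best model flagged."""
    if len(models) < 2:
        raise MarginalError("need at least 2 models to compare")
    forms = [m.form for m in models]
    log_ml = np.array([m.log_ml for m in models])
    log_bf = log_ml[:, None] - log_ml[None, :]
    strong = np.exp(log_bf) > threshold
    np.fill_diagonal(strong, False)
    best = forms[int(np.argmax(log_ml))]
    return BayesFactorTable(forms, log_ml, log_bf, strong, best, threshold)
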