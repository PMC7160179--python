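"""Reversible-jump MCMC over shift configurations and OU regression parameters.

The sampler explores the joint posterior of (shift set, per-regime optima and
slopes, global site/interaction coefficients, alpha, sigma2) for one model
form.  Trans-dimensional moves are birth (a new shift on an unoccupied
branch, branch chosen proportional to length, position uniform, new theta and
slope drawn from their priors so the proposal density cancels the parameter
prior), death (its exact reverse) and relocate (move an existing shift,
keeping its regime parameters).  Within-dimension moves are Gaussian random
walks on theta, slopes and site coefficients and log-scale multiplier
proposals for alpha and sigma2.  Random-walk step sizes adapt toward a
0.2-0.5 acceptance rate during burn-in only and are frozen afterwards so the
post-burn-in chain satisfies detailed balance.

The likelihood may be tempered (``power`` in [0, 1]) for power-posterior
ladders; ``power=0`` is the data-free prior run used to validate priors.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import math

import numpy as np
from scipy import linalg

from .likelihood import (ALPHA_BM_THRESHOLD, RegimeParams, fast_hansen_weights,
                         hansen_weights, model_mean, validate_form)
from .priors import Priors
from .regimes import ShiftConfig, ShiftPoint, paint
from .traits import TraitTable
from .tree import Phylogeny

LOG2PI = math.log(2.0 * math.pi)

PARAM_MOVES = ("theta", "beta", "site", "inter", "alpha", "sigma2")
ALL_MOVES = ("birth", "death", "relocate") + PARAM_MOVES

DEFAULT_MOVE_WEIGHTS = {
    "birth": 0.15, "death": 0.15, "relocate": 0.10,
    "theta": 0.15, "beta": 0.15, "site": 0.075, "inter": 0.075,
    "alpha": 0.075, "sigma2": 0.075,
}

DEFAULT_STEPS = {"theta": 0.3, "beta": 0.1, "site": 0.2, "inter": 0.1,
                 "alpha": 0.5, "sigma2": 0.5}


@dataclasses.dataclass
class Sample:
    gen: int
    k: int
    alpha: float
    sigma2: float
    loglik: float
    logprior: float
    shifts: tuple           # ((branch, position), ...) canonical order
    theta: tuple            # root first, then per shift in canonical order
    beta_size: tuple
    beta_site: tuple | None
    beta_inter: tuple | None


@dataclasses.dataclass
class ChainTrace:
    samples: list
    generations: int
    thinning: int
    burnin_frac: float
    seed: int
    form: str
    meta: dict

    def post_burnin(self) -> list:
        cut = int(math.ceil(self.burnin_frac * len(self.samples)))
        return self.samples[cut:]

    def k_values(self, burnin: bool = True) -> np.ndarray:
        src = self.post_burnin() if burnin else self.samples
        return np.array([s.k for s in src])

    def scalar(self, name: str, burnin: bool = True) -> np.ndarray:
        src = self.post_burnin() if burnin else self.samples
        return np.array([getattr(s, name) for s in src], dtype=float)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gen\tk\talpha\tsigma2\tloglik\tlogprior\tshifts\ttheta\t"
                     "beta_size\tbeta_site\tbeta_inter\n")
            for s in self.samples:
                fh.write("\t".join([
                    str(s.gen), str(s.k), repr(s.alpha), repr(s.sigma2),
                    repr(s.loglik), repr(s.logprior),
                    json.dumps([list(x) for x in s.shifts]),
                    json.dumps(list(s.theta)), json.dumps(list(s.beta_size)),
                    json.dumps(None if s.beta_site is None else list(s.beta_site)),
                    json.dumps(None if s.beta_inter is None else list(s.beta_inter)),
                ]) + "\n")
        with open(str(path) + ".meta.json", "w") as fh:
            json.dump({
                "generations": self.generations, "thinning": self.thinning,
                "burnin_frac": self.burnin_frac, "seed": self.seed,
                "form": self.form, "meta": self.meta,
            }, fh, indent=2, default=str)

    @staticmethod
    def read(path) -> "ChainTrace":
        with open(str(path) + ".meta.json") as fh:
            meta = json.load(fh)
        samples = []
        with open(path) as fh:
            next(fh)
            for line in fh:
                (gen, k, alpha, sigma2, ll, lp, shifts, theta, beta,
                 bsite, binter) = line.rstrip("\n").split("\t")
                samples.append(Sample(
                    int(gen), int(k), float(alpha), float(sigma2), float(ll),
                    float(lp),
                    tuple((int(b), float(p)) for b, p in json.loads(shifts)),
                    tuple(json.loads(theta)), tuple(json.loads(beta)),
                    None if json.loads(bsite) is None else tuple(json.loads(bsite)),
                    None if json.loads(binter) is None else tuple(json.loads(binter)),
                ))
        return ChainTrace(samples, meta["generations"], meta["thinning"],
                          meta["burnin_frac"], meta["seed"], meta["form"],
                          meta["meta"])


def tree_hash(tree: Phylogeny) -> str:
    return hashlib.md5(tree.to_newick().encode()).hexdigest()


class _Chain:
    """Mutable sampler state with cached likelihood pieces."""

    def __init__(self, tree, table, form, priors, power, rng,
                 move_weights=None, steps=None):
        self.tree = tree
        self.table = table
        self.form = validate_form(form)
        self.priors = priors
        self.power = float(power)
        self.rng = rng
        self.n = tree.n_tips
        self.T = tree.tip_depths
        self.x = table.log_size
        self.y = table.log_df
        self.dummies = table.site_dummies()
        self.me = table.me_filled()
        self.branches = tree.branch_ids()
        self.branch_lengths = tree.lengths[self.branches]
        self.L = float(self.branch_lengths.sum())
        self._len_of = tree.lengths
        self._pre = tree.preorder
        self._parent = tree.parent
        self._depths = tree.depths
        self.use_lik = self.power > 0.0
        if self.use_lik:
            self._S = tree.shared_depths()
            self._Touter = self.T[:, None] + self.T[None, :]
            self._below = tree.below_mask()
        weights = dict(DEFAULT_MOVE_WEIGHTS if move_weights is None else move_weights)
        if form == "a":
            weights["site"] = weights["inter"] = 0.0
        elif form == "b":
            weights["inter"] = 0.0
        if priors.alpha_prior[0] == "fixed":
            weights["alpha"] = 0.0
        if priors.sigma2_prior[0] == "fixed":
            weights["sigma2"] = 0.0
        tot = sum(weights.values())
        self.move_names = list(ALL_MOVES)
        self.move_probs = np.array([weights[m] / tot for m in self.move_names])
        self._move_cum = np.cumsum(self.move_probs)
        # branch id -> position in self.branches (ids skip the root)
        self._branch_pos = np.full(tree.n_nodes, -1, dtype=np.int64)
        self._branch_pos[self.branches] = np.arange(self.branches.size)
        self.steps = dict(DEFAULT_STEPS if steps is None else steps)
        self.accepts = {m: 0 for m in self.move_names}
        self.proposals = {m: 0 for m in self.move_names}
        self._adapt_acc = {m: 0 for m in PARAM_MOVES}
        self._adapt_n = {m: 0 for m in PARAM_MOVES}

    # ------------------------------------------------------------- state init
    def init_state(self):
        rng = self.rng
        self.shifts = []          # list[(branch, position)] canonical order
        self.theta = np.array([self.priors.rvs_theta(rng)])
        self.beta = np.array([self.priors.rvs_beta(rng)])
        self.bsite = (rng.normal(0.0, self.priors.site_sd, 2)
                      if self.form in ("b", "c") else None)
        self.binter = (rng.normal(0.0, self.priors.inter_sd, 2)
                       if self.form == "c" else None)
        self.alpha = self.priors.rvs_alpha(rng)
        self.sigma2 = self.priors.rvs_sigma2(rng)
        self.occupied = np.zeros(self.branches.size, dtype=bool)
        self._refresh_shift_arrays()
        if self.use_lik:
            self._update_cov()
            self._update_weights()
            self._update_mean()
            self.ll = self._loglik()
        else:
            self.ll = 0.0
        self.lp = self._logprior()

    def snapshot(self) -> dict:
        return {
            "shifts": list(self.shifts), "theta": self.theta.copy(),
            "beta": self.beta.copy(),
            "bsite": None if self.bsite is None else self.bsite.copy(),
            "binter": None if self.binter is None else self.binter.copy(),
            "alpha": self.alpha, "sigma2": self.sigma2,
        }

    def restore(self, snap: dict):
        self.shifts = list(snap["shifts"])
        self.theta = snap["theta"].copy()
        self.beta = snap["beta"].copy()
        self.bsite = None if snap["bsite"] is None else snap["bsite"].copy()
        self.binter = None if snap["binter"] is None else snap["binter"].copy()
        self.alpha = snap["alpha"]
        self.sigma2 = snap["sigma2"]
        self.occupied = np.zeros(self.branches.size, dtype=bool)
        for b, _ in self.shifts:
            self.occupied[self._branch_pos[b]] = True
        self._refresh_shift_arrays()
        if self.use_lik:
            self._update_cov()
            self._update_weights()
            self._update_mean()
            self.ll = self._loglik()
        else:
            self.ll = 0.0
        self.lp = self._logprior()

    # --------------------------------------------------------------- caching
    def _refresh_shift_arrays(self):
        k = len(self.shifts)
        self.times = np.array(
            [self._depths[self._parent[b]] + p * self._len_of[b]
             for b, p in self.shifts]
        ) if k else np.empty(0)
        if self.use_lik:
            self.masks = (self._below[[b for b, _ in self.shifts]]
                          if k else np.empty((0, self.n), dtype=bool))

    def _update_weights(self):
        self.W = fast_hansen_weights(self.T, self.masks, self.times, self.alpha)

    def _update_mean(self):
        params = RegimeParams(self.theta, self.beta, max(self.alpha, 0.0),
                              self.sigma2, self.bsite, self.binter)
        self.mu = model_mean(self.W, params, self.x, self.dummies, self.form)

    def _update_cov(self):
        a, s2 = self.alpha, self.sigma2
        if a < ALPHA_BM_THRESHOLD:
            V = s2 * self._S + np.diag(self.me)
        else:
            V = (s2 / (2.0 * a)
                 * np.exp(-a * (self._Touter - 2.0 * self._S))
                 * (1.0 - np.exp(-2.0 * a * self._S)))
            V = V + np.diag(self.me)
        L = linalg.cholesky(V, lower=True, check_finite=False)
        self.logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        # triangular inverse keeps mean-only moves at one matvec each
        Linv, info = linalg.lapack.dtrtri(L, lower=1)
        if info != 0:
            raise linalg.LinAlgError(f"triangular inversion failed (info={info})")
        self.Linv = Linv

    def _loglik(self) -> float:
        z = self.Linv @ (self.y - self.mu)
        return -0.5 * (self.n * LOG2PI + self.logdet + float(z @ z))

    def _logprior(self) -> float:
        k = len(self.shifts)
        lp = self.priors.log_k(k) + math.lgamma(k + 1)
        for b, _ in self.shifts:
            lp += math.log(self._len_of[b] / self.L)
        lp += self.priors.log_theta(self.theta) + self.priors.log_beta(self.beta)
        if self.bsite is not None:
            lp += self.priors.log_beta_site(self.bsite)
        if self.binter is not None:
            lp += self.priors.log_beta_inter(self.binter)
        lp += self.priors.log_alpha(self.alpha) + self.priors.log_sigma2(self.sigma2)
        return lp

    def _canonical_insert_pos(self, branch: int) -> int:
        rank = self._pre[branch]
        for j, (b, _) in enumerate(self.shifts):
            if self._pre[b] > rank:
                return j
        return len(self.shifts)

    # ----------------------------------------------------------------- moves
    def _accept(self, logr: float) -> bool:
        return math.log(self.rng.random() + 1e-300) < logr

    def _avail(self):
        free = ~self.occupied
        return self.branches[free], self.branch_lengths[free]

    def _choose_weighted(self, ids: np.ndarray, lens: np.ndarray, total: float) -> int:
        cum = np.cumsum(lens)
        j = int(np.searchsorted(cum, self.rng.random() * total))
        return int(ids[min(j, ids.size - 1)])

    def move_birth(self):
        k = len(self.shifts)
        if k >= self.priors.kmax:
            return False
        avail, lens = self._avail()
        if avail.size == 0:
            return False
        L_un = float(lens.sum())
        b = self._choose_weighted(avail, lens, L_un)
        u = float(self.rng.random())
        th = float(self.priors.rvs_theta(self.rng))
        be = float(self.priors.rvs_beta(self.rng))
        pos = self._canonical_insert_pos(b)
        old = (self.shifts, self.theta, self.beta)
        self.shifts = self.shifts[:pos] + [(b, u)] + self.shifts[pos:]
        self.theta = np.insert(self.theta, pos + 1, th)
        self.beta = np.insert(self.beta, pos + 1, be)
        self.occupied[self._branch_pos[b]] = True
        self._refresh_shift_arrays()
        if self.use_lik:
            oldW, oldmu = self.W, self.mu
            self._update_weights()
            self._update_mean()
            ll_new = self._loglik()
        else:
            ll_new = 0.0
        lp_new = self._logprior()
        log_q_fwd = math.log(self._len_of[b] / L_un) \
            + float(self.priors.log_theta(th)) + float(self.priors.log_beta(be))
        log_q_rev = -math.log(k + 1)
        logr = (self.power * (ll_new - self.ll) + (lp_new - self.lp)
                + log_q_rev - log_q_fwd)
        if self._accept(logr):
            self.ll, self.lp = ll_new, lp_new
            return True
        self.shifts, self.theta, self.beta = old
        self.occupied[self._branch_pos[b]] = False
        self._refresh_shift_arrays()
        if self.use_lik:
            self.W, self.mu = oldW, oldmu
        return False

    def move_death(self):
        k = len(self.shifts)
        if k == 0:
            return False
        j = int(self.rng.integers(k))
        b, _ = self.shifts[j]
        th, be = float(self.theta[j + 1]), float(self.beta[j + 1])
        old = (self.shifts, self.theta, self.beta)
        self.shifts = self.shifts[:j] + self.shifts[j + 1:]
        self.theta = np.delete(self.theta, j + 1)
        self.beta = np.delete(self.beta, j + 1)
        self.occupied[self._branch_pos[b]] = False
        self._refresh_shift_arrays()
        if self.use_lik:
            oldW, oldmu = self.W, self.mu
            self._update_weights()
            self._update_mean()
            ll_new = self._loglik()
        else:
            ll_new = 0.0
        lp_new = self._logprior()
        _, lens_after = self._avail()
        L_un_after = float(lens_after.sum())
        log_q_fwd = -math.log(k)
        log_q_rev = math.log(self._len_of[b] / L_un_after) \
            + float(self.priors.log_theta(th)) + float(self.priors.log_beta(be))
        logr = (self.power * (ll_new - self.ll) + (lp_new - self.lp)
                + log_q_rev - log_q_fwd)
        if self._accept(logr):
            self.ll, self.lp = ll_new, lp_new
            return True
        self.shifts, self.theta, self.beta = old
        self.occupied[self._branch_pos[b]] = True
        self._refresh_shift_arrays()
        if self.use_lik:
            self.W, self.mu = oldW, oldmu
        return False

    def move_relocate(self):
        k = len(self.shifts)
        if k == 0:
            return False
        j = int(self.rng.integers(k))
        b_old, _ = self.shifts[j]
        avail, lens = self._avail()
        avail = np.append(avail, b_old)
        lens = np.append(lens, self._len_of[b_old])
        L_av = float(lens.sum())
        b_new = self._choose_weighted(avail, lens, L_av)
        u_new = float(self.rng.random())
        th, be = float(self.theta[j + 1]), float(self.beta[j + 1])
        old = (self.shifts, self.theta, self.beta)
        rest = self.shifts[:j] + self.shifts[j + 1:]
        rest_theta = np.delete(self.theta, j + 1)
        rest_beta = np.delete(self.beta, j + 1)
        # temporary state without shift j, then canonical re-insertion
        self.shifts = rest
        pos = self._canonical_insert_pos(b_new)
        self.shifts = rest[:pos] + [(b_new, u_new)] + rest[pos:]
        self.theta = np.insert(rest_theta, pos + 1, th)
        self.beta = np.insert(rest_beta, pos + 1, be)
        self.occupied[self._branch_pos[b_old]] = False
        self.occupied[self._branch_pos[b_new]] = True
        self._refresh_shift_arrays()
        if self.use_lik:
            oldW, oldmu = self.W, self.mu
            self._update_weights()
            self._update_mean()
            ll_new = self._loglik()
        else:
            ll_new = 0.0
        lp_new = self._logprior()
        # proposal is symmetric in (branch, position) over the same available set
        log_hastings = math.log(self._len_of[b_old] / L_av) \
            - math.log(self._len_of[b_new] / L_av)
        logr = self.power * (ll_new - self.ll) + (lp_new - self.lp) + log_hastings
        if self._accept(logr):
            self.ll, self.lp = ll_new, lp_new
            return True
        self.shifts, self.theta, self.beta = old
        self.occupied[self._branch_pos[b_new]] = False
        self.occupied[self._branch_pos[b_old]] = True
        self._refresh_shift_arrays()
        if self.use_lik:
            self.W, self.mu = oldW, oldmu
        return False

    def _scalar_rw(self, vec: np.ndarray, step_name: str):
        """Random-walk update of one coordinate of ``vec``; returns proposal."""
        j = int(self.rng.integers(vec.shape[0]))
        new = vec.copy()
        new[j] += self.rng.normal(0.0, self.steps[step_name])
        return new

    def move_param(self, which: str):
        oldmu = self.mu if self.use_lik else None
        recompute_cov = False
        recompute_W = False
        log_jac = 0.0
        old_vals = (self.theta, self.beta, self.bsite, self.binter,
                    self.alpha, self.sigma2)
        if which == "theta":
            self.theta = self._scalar_rw(self.theta, "theta")
        elif which == "beta":
            self.beta = self._scalar_rw(self.beta, "beta")
        elif which == "site":
            if self.bsite is None:
                return False
            self.bsite = self._scalar_rw(self.bsite, "site")
        elif which == "inter":
            if self.binter is None:
                return False
            self.binter = self._scalar_rw(self.binter, "inter")
        elif which == "alpha":
            if self.priors.alpha_prior[0] == "fixed":
                return False
            new = self.alpha * math.exp(self.rng.normal(0.0, self.steps["alpha"]))
            log_jac = math.log(new / self.alpha) if self.alpha > 0 else 0.0
            self.alpha = new
            recompute_cov = recompute_W = True
        elif which == "sigma2":
            if self.priors.sigma2_prior[0] == "fixed":
                return False
            new = self.sigma2 * math.exp(self.rng.normal(0.0, self.steps["sigma2"]))
            log_jac = math.log(new / self.sigma2)
            self.sigma2 = new
            recompute_cov = True
        if self.use_lik:
            old_linv, old_logdet, oldW = self.Linv, self.logdet, self.W
            if recompute_cov:
                self._update_cov()
            if recompute_W:
                self._update_weights()
            self._update_mean()
            ll_new = self._loglik()
        else:
            ll_new = 0.0
        lp_new = self._logprior()
        logr = self.power * (ll_new - self.ll) + (lp_new - self.lp) + log_jac
        accepted = np.isfinite(lp_new) and self._accept(logr)
        if accepted:
            self.ll, self.lp = ll_new, lp_new
        else:
            (self.theta, self.beta, self.bsite, self.binter,
             self.alpha, self.sigma2) = old_vals
            if self.use_lik:
                self.Linv, self.logdet, self.W, self.mu = (
                    old_linv, old_logdet, oldW, oldmu)
        return accepted

    # ------------------------------------------------------------- main loop
    def step(self, adapt: bool):
        idx = int(np.searchsorted(self._move_cum, self.rng.random()))
        move = self.move_names[min(idx, len(self.move_names) - 1)]
        self.proposals[move] += 1
        if move == "birth":
            acc = self.move_birth()
        elif move == "death":
            acc = self.move_death()
        elif move == "relocate":
            acc = self.move_relocate()
        else:
            acc = self.move_param(move)
        if acc:
            self.accepts[move] += 1
        if adapt and move in PARAM_MOVES:
            self._adapt_n[move] += 1
            self._adapt_acc[move] += int(acc)
            if self._adapt_n[move] >= 100:
                rate = self._adapt_acc[move] / self._adapt_n[move]
                self.steps[move] = float(np.clip(
                    self.steps[move] * math.exp(rate - 0.3), 1e-4, 1e4))
                self._adapt_n[move] = self._adapt_acc[move] = 0

    def spot_check(self):
        """Verify the cached log-likelihood against the reference path."""
        if not self.use_lik:
            return
        config = ShiftConfig.of([ShiftPoint(b, p) for b, p in self.shifts], self.tree)
        W_ref = hansen_weights(self.tree, paint(self.tree, config), self.alpha)
        params = RegimeParams(self.theta, self.beta, self.alpha, self.sigma2,
                              self.bsite, self.binter)
        mu_ref = model_mean(W_ref, params, self.x, self.dummies, self.form)
        r = self.y - mu_ref
        z = self.Linv @ r
        quad = float(z @ z)
        ll_ref = -0.5 * (self.n * LOG2PI + self.logdet + quad)
        if not math.isclose(ll_ref, self.ll, rel_tol=1e-6, abs_tol=1e-6):
            raise RuntimeError(
                f"cached log-likelihood drifted: cached {self.ll}, reference {ll_ref}")

    def sample(self, gen: int) -> Sample:
        return Sample(
            gen=gen, k=len(self.shifts), alpha=float(self.alpha),
            sigma2=float(self.sigma2), loglik=float(self.ll),
            logprior=float(self.lp),
            shifts=tuple((int(b), float(p)) for b, p in self.shifts),
            theta=tuple(float(v) for v in self.theta),
            beta_size=tuple(float(v) for v in self.beta),
            beta_site=None if self.bsite is None else tuple(map(float, self.bsite)),
            beta_inter=None if self.binter is None else tuple(map(float, self.binter)),
        )


def run_chain(tree: Phylogeny, table: TraitTable, form: str, priors: Priors,
              generations: int = 500_000, thinning: int = 100, seed: int = 0,
              power: float = 1.0, burnin_frac: float = 0.25,
              move_weights: dict | None = None, steps: dict | None = None,
              adapt: bool = True, init: dict | None = None,
              spot_check_every: int = 10_000,
              return_chain: bool = False):
    """Run one rjMCMC chain; bit-reproducible for a fixed seed.

    Returns a :class:`ChainTrace` (and the live chain object if
    ``return_chain``, used for warm-starting power-posterior ladders).
    """
    if generations < thinning:
        raise ValueError("generations must be >= thinning")
    priors = priors.resolve(table)
    rng = np.random.default_rng(seed)
    chain = _Chain(tree, table, form, priors, power, rng, move_weights, steps)
    chain.init_state()
    if init is not None:
        chain.restore(init)
    burnin_gens = int(burnin_frac * generations)
    samples = []
    for gen in range(1, generations + 1):
        chain.step(adapt=adapt and gen <= burnin_gens)
        if gen % thinning == 0:
            samples.append(chain.sample(gen))
        if spot_check_every and gen % spot_check_every == 0:
            chain.spot_check()
    rates = {m: (chain.accepts[m] / chain.proposals[m] if chain.proposals[m] else None)
             for m in chain.move_names}
    trace = ChainTrace(
        samples=samples, generations=generations, thinning=thinning,
        burnin_frac=burnin_frac, seed=seed, form=form,
        meta={
            "power": power, "acceptance_rates": rates,
            "final_steps": dict(chain.steps), "tree_hash": tree_hash(tree),
            "priors": priors.to_dict(),
        },
    )
    if return_chain:
        return trace, chain
    return trace


def chain_seeds(seed: int, n_chains: int) -> list:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n_chains)]


def run_analysis(tree: Phylogeny, table: TraitTable, form: str, priors: Priors,
                 n_chains: int = 4, generations: int = 500_000,
                 thinning: int = 100, seed: int = 0, **kwargs) -> list:
    """Run independent chains with distinct seeds derived from ``seed``."""
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    traces = []
    for s in chain_seeds(seed, n_chains):
        traces.append(run_chain(tree, table, form, priors,
                                generations=generations, thinning=thinning,
                                seed=s, **kwargs))
    return traces
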