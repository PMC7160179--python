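"""End-to-end run orchestration: simulate or fit, with reproducible run dirs.

A run directory contains, per fitted model form: trace files (one per chain,
with JSON metadata sidecars), a convergence report, the shift summary and
regimes table, and optionally marginal likelihoods with the Bayes-factor
decision table; supported shifts are corroborated by phylogenetic ANCOVA.
A ``manifest.json`` (inputs, hashes, seeds, settings, package version) makes
every run reconstructible.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import __version__
from .diagnostics import annotated_newick, gelman_r, summarize_shifts
from .marginal import compare, stepping_stone
from .pancova import PancovaError, pancova
from .priors import Priors
from .sampler import run_analysis, tree_hash
from .simulate import SimConfig, simulate_dataset
from .traits import impute_me, read_traits, reconcile
from .tree import read_tree, write_tree

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    tree_path: str
    traits_path: str
    out_dir: str
    forms: tuple = ("a",)
    tree_format: str = "newick"
    me_policy: str = "zero"
    n_chains: int = 4
    generations: int = 500_000
    thinning: int = 100
    burnin_frac: float = 0.25
    seed: int = 0
    pp_threshold: float = 0.7
    min_clade: int = 4
    bf_threshold: float = 10.0
    r_threshold: float = 1.1
    marginal_likelihood: bool = False
    rungs: int = 20
    gens_per_rung: int = 10_000
    priors: Priors = dataclasses.field(default_factory=Priors)

    @staticmethod
    def from_json(path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        prior_kw = raw.pop("priors", {})
        for key in ("k_prior", "alpha_prior", "sigma2_prior"):
            if key in prior_kw:
                prior_kw[key] = tuple(prior_kw[key])
        if "forms" in raw:
            raw["forms"] = tuple(raw["forms"])
        return RunConfig(priors=Priors(**prior_kw), **raw)


def cmd_simulate(cfg: SimConfig, out_dir) -> Path:
    """Write a simulated dataset (tree, traits, truth) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree, table, truth = simulate_dataset(cfg)
    write_tree(tree, out / "tree.nwk")
    table.write_raw(out / "traits.csv")
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    logger.info("simulated %d tips -> %s", tree.n_tips, out)
    return out


def cmd_fit(cfg: RunConfig) -> dict:
    """Run the full analysis; returns a result dict (also written to disk)."""
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree = read_tree(cfg.tree_path, cfg.tree_format)
    raw = read_traits(cfg.traits_path)
    tree, table = reconcile(tree, raw)
    table = impute_me(table, cfg.me_policy)
    priors = cfg.priors.resolve(table)
    manifest = {
        "version": __version__,
        "tree_path": str(cfg.tree_path), "traits_path": str(cfg.traits_path),
        "tree_hash": tree_hash(tree), "n_species": table.n,
        "seed": cfg.seed, "forms": list(cfg.forms),
        "settings": {
            "n_chains": cfg.n_chains, "generations": cfg.generations,
            "thinning": cfg.thinning, "burnin_frac": cfg.burnin_frac,
            "me_policy": cfg.me_policy, "pp_threshold": cfg.pp_threshold,
            "min_clade": cfg.min_clade, "bf_threshold": cfg.bf_threshold,
            "r_threshold": cfg.r_threshold,
        },
        "priors": priors.to_dict(),
    }
    results = {"manifest": manifest, "models": {}, "converged": True}
    mls = []
    for form in cfg.forms:
        stage0 = time.time()
        logger.info("fitting model %s (%d chains x %d generations)",
                    form, cfg.n_chains, cfg.generations)
        traces = run_analysis(
            tree, table, form, priors, n_chains=cfg.n_chains,
            generations=cfg.generations, thinning=cfg.thinning,
            seed=cfg.seed, burnin_frac=cfg.burnin_frac)
        for i, tr in enumerate(traces):
            tr.write(out / f"trace_{form}_chain{i}.tsv")
        if cfg.n_chains >= 2:
            report = gelman_r(traces, tree, r_threshold=cfg.r_threshold)
        else:
            report = gelman_r(traces, tree, r_threshold=cfg.r_threshold)
        summary = summarize_shifts(traces, tree, cfg.pp_threshold, cfg.min_clade)
        summary.to_frame().to_csv(out / f"regimes_{form}.csv", index=False)
        with open(out / f"summary_{form}.json", "w") as fh:
            json.dump(summary.to_dict(), fh, indent=2)
        with open(out / f"convergence_{form}.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
        with open(out / f"annotated_{form}.nwk", "w") as fh:
            fh.write(annotated_newick(tree, summary) + "\n")
        panc = {}
        below = tree.below_mask()
        for b in summary.supported:
            clade = [tree.tip_labels[i] for i in np.flatnonzero(below[b])]
            try:
                panc[str(b)] = pancova(tree, table, clade).to_dict()
            except PancovaError as exc:
                panc[str(b)] = {"error": str(exc)}
        with open(out / f"pancova_{form}.json", "w") as fh:
            json.dump(panc, fh, indent=2)
        entry = {
            "converged": report.converged,
            "supported_shifts": summary.supported,
            "mean_k": summary.mean_k,
            "pancova": panc,
            "seconds": time.time() - stage0,
        }
        if cfg.marginal_likelihood:
            ml = stepping_stone(tree, table, form, priors, rungs=cfg.rungs,
                                gens_per_rung=cfg.gens_per_rung,
                                seed=cfg.seed + 7919)
            entry["log_ml"] = ml.log_ml
            entry["log_ml_se"] = ml.se
            mls.append(ml)
        results["models"][form] = entry
        results["converged"] = results["converged"] and report.converged
        logger.info("model %s done in %.1f s (converged=%s)",
                    form, entry["seconds"], report.converged)
    if len(mls) >= 2:
        table_bf = compare(mls, threshold=cfg.bf_threshold)
        results["bayes_factors"] = table_bf.to_dict()
        with open(out / "bayes_factors.json", "w") as fh:
            json.dump(table_bf.to_dict(), fh, indent=2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    results["seconds"] = time.time() - t0
    with open(out / "results.json", "w") as fh:
        json.dump(results, fh, indent=2)
    return results
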