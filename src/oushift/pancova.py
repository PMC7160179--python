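"""Phylogenetic ANCOVA under Brownian motion.

For each candidate clade, a full GLS model gives the clade its own intercept
and allometric slope (4 parameters: intercept and slope for the clade,
intercept and slope for everyone else) while the reduced model shares one
intercept and one slope across all species (2 parameters).  Both are fitted
by generalized least squares with the Brownian-motion covariance (shared
root-to-MRCA path lengths), i.e. ordinary least squares after whitening by
an inverse triangular factor of that covariance; residual sums of squares
live in the whitened space.  Nested models are compared with an F-ratio test:

    F = [(RSS_r - RSS_f) / (p_f - p_r)] / [RSS_f / (n - p_f)]

with (p_f - p_r, n - p_f) degrees of freedom.  Any factor C = L L' yields
identical RSS, so the choice of factorization is immaterial.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .traits import TraitTable
from .tree import Phylogeny


class PancovaError(ValueError):
    pass


@dataclasses.dataclass
class PancovaResult:
    n: int
    p_full: int
    p_reduced: int
    rss_full: float
    rss_reduced: float
    mss_full: float           # RSS / (n - p), per model
    mss_reduced: float
    f: float
    df_num: int
    df_den: int
    p_value: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class PglsFit:
    rss_full: float
    rss_reduced: float
    coef_full: np.ndarray     # [intercept_clade, slope_clade, intercept_rest, slope_rest]
    coef_reduced: np.ndarray  # [intercept, slope]
    p_full: int = 4
    p_reduced: int = 2


def _clade_mask(tree: Phylogeny, table: TraitTable, clade) -> np.ndarray:
    if isinstance(clade, np.ndarray) and clade.dtype == bool:
        return clade
    labels = set(clade)
    mask = np.array([s in labels for s in table.species])
    if mask.sum() != len(labels):
        missing = labels - set(table.species)
        raise PancovaError(f"clade species not in table: {sorted(missing)[:5]}")
    return mask


def _check_monophyly(tree: Phylogeny, mask: np.ndarray) -> None:
    node = tree.mrca(np.flatnonzero(mask))
    sub = tree.below_mask()[node]
    if not np.array_equal(sub, mask):
        raise PancovaError("focal clade is not monophyletic on this tree")


def pgls_fit(tree: Phylogeny, table: TraitTable, clade,
             check_monophyly: bool = True) -> PglsFit:
    """GLS fits of the full (clade-specific) and reduced allometric models."""
    mask = _clade_mask(tree, table, clade)
    n = table.n
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise PancovaError("need >= 2 species inside and outside the focal clade")
    if mask.all():
        raise PancovaError("clade cannot contain every tip (singular design)")
    if check_monophyly:
        _check_monophyly(tree, mask)
    C = tree.shared_depths()
    y = table.log_df
    x = table.log_size
    g = mask.astype(float)
    X_full = np.column_stack([g, g * x, 1.0 - g, (1.0 - g) * x])
    X_red = np.column_stack([np.ones(n), x])
    fit_full = sm.GLS(y, X_full, sigma=C).fit()
    fit_red = sm.GLS(y, X_red, sigma=C).fit()
    return PglsFit(
        rss_full=float(fit_full.ssr), rss_reduced=float(fit_red.ssr),
        coef_full=np.asarray(fit_full.params), coef_reduced=np.asarray(fit_red.params),
    )


def f_ratio(rss_full: float, p_full: int, rss_reduced: float, p_reduced: int,
            n: int) -> PancovaResult:
    """F-ratio test between nested GLS models from their residual SS."""
    if p_full <= p_reduced:
        raise PancovaError("full model must have more parameters than reduced")
    if n <= p_full:
        raise PancovaError("need n > p_full")
    if rss_full > rss_reduced * (1 + 1e-12):
        raise PancovaError(
            f"nesting violated: RSS_full ({rss_full}) > RSS_reduced ({rss_reduced})")
    df_num = p_full - p_reduced
    df_den = n - p_full
    f = max(0.0, (rss_reduced - rss_full) / df_num) / (rss_full / df_den)
    p_value = float(stats.f.sf(f, df_num, df_den)) if f > 0 else 1.0
    return PancovaResult(
        n=n, p_full=p_full, p_reduced=p_reduced,
        rss_full=rss_full, rss_reduced=rss_reduced,
        mss_full=rss_full / df_den, mss_reduced=rss_reduced / (n - p_reduced),
        f=float(f), df_num=df_num, df_den=df_den, p_value=p_value,
    )


def pancova(tree: Phylogeny, table: TraitTable, clade,
            check_monophyly: bool = True) -> PancovaResult:
    """Fit and test one candidate clade in a single call."""
    fit = pgls_fit(tree, table, clade, check_monophyly=check_monophyly)
    return f_ratio(fit.rss_full, fit.p_full, fit.rss_reduced, fit.p_reduced,
                   table.n)


def pancova_table(tree: Phylogeny, table: TraitTable, clades: dict,
                  check_monophyly: bool = True) -> pd.DataFrame:
    """Results table for several candidate clades (one row pair per clade)."""
    rows = []
    for name, clade in clades.items():
        r = pancova(tree, table, clade, check_monophyly=check_monophyly)
        rows.append({"clade": name, "model": "full", "df": r.p_full,
                     "sum_squares": r.rss_full, "mean_sum_squares": r.mss_full,
                     "F": r.f, "p_value": r.p_value})
        rows.append({"clade": name, "model": "reduced", "df": r.p_reduced,
                     "sum_squares": r.rss_reduced,
                     "mean_sum_squares": r.mss_reduced,
                     "F": np.nan, "p_value": np.nan})
    return pd.DataFrame(rows)
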