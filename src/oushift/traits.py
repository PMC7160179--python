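"""Species trait tables: dominant call frequency, body size, calling site.

Raw input is a delimited table with header
``species,dominant_frequency_hz,svl_mm,calling_site,me_var`` (``me_var``
optional).  Frequency (Hz) and snout-vent length (mm) are natural-log
transformed on load; ``me_var`` is the observation-error variance of log
frequency (log-Hz^2).  Calling site is one of aquatic / terrestrial /
arboreal, with terrestrial as the dummy-coding reference level.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .tree import Phylogeny, TreeError, _normalize_label

logger = logging.getLogger(__name__)

SITE_LEVELS = ("terrestrial", "aquatic", "arboreal")  # reference level first
NON_REFERENCE_LEVELS = SITE_LEVELS[1:]


class TraitError(ValueError):
    pass


@dataclasses.dataclass
class TraitTable:
    """Per-species traits aligned to a tree's tip order.

    ``log_df`` is ln(dominant frequency in Hz); ``log_size`` is ln(male SVL
    in mm); ``site`` holds category strings; ``me_var`` is NaN where no
    intraspecific variance estimate exists (see :func:`impute_me`).
    """

    species: list
    log_df: np.ndarray
    log_size: np.ndarray
    site: np.ndarray
    me_var: np.ndarray
    me_policy: str | None = None

    def __post_init__(self):
        self.log_df = np.asarray(self.log_df, dtype=float)
        self.log_size = np.asarray(self.log_size, dtype=float)
        self.site = np.asarray(self.site, dtype=object)
        self.me_var = np.asarray(self.me_var, dtype=float)
        if not (np.all(np.isfinite(self.log_df)) and np.all(np.isfinite(self.log_size))):
            raise TraitError("log frequency and log size must be finite")
        bad = [s for s in self.site if s not in SITE_LEVELS]
        if bad:
            raise TraitError(f"unknown calling-site category: {bad[0]!r}")
        with np.errstate(invalid="ignore"):
            if np.any(self.me_var < 0):
                raise TraitError("me_var must be >= 0")

    @property
    def n(self) -> int:
        return len(self.species)

    def site_dummies(self) -> np.ndarray:
        """(n, 2) dummy matrix, columns aquatic & arboreal (terrestrial ref)."""
        d = np.zeros((self.n, len(NON_REFERENCE_LEVELS)))
        for j, lev in enumerate(NON_REFERENCE_LEVELS):
            d[:, j] = self.site == lev
        return d

    def me_filled(self) -> np.ndarray:
        """me_var with NaN treated as zero (for use after imputation)."""
        return np.where(np.isnan(self.me_var), 0.0, self.me_var)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.species,
                "log_df": self.log_df,
                "log_size": self.log_size,
                "calling_site": self.site,
                "me_var": self.me_var,
            }
        )

    def write_raw(self, path) -> None:
        """Write on the raw scale (Hz, mm) in the canonical input format."""
        pd.DataFrame(
            {
                "species": self.species,
                "dominant_frequency_hz": np.exp(self.log_df),
                "svl_mm": np.exp(self.log_size),
                "calling_site": self.site,
                "me_var": self.me_var,
            }
        ).to_csv(path, index=False)


def read_traits(path) -> pd.DataFrame:
    """Read a raw trait table (CSV/TSV autodetected); logs are NOT yet taken."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"species", "dominant_frequency_hz", "svl_mm", "calling_site"}
    missing = required - set(df.columns)
    if missing:
        raise TraitError(f"trait table missing columns: {sorted(missing)}")
    if "me_var" not in df.columns:
        df["me_var"] = np.nan
    return df


def _table_from_raw(df: pd.DataFrame) -> TraitTable:
    if np.any(df["dominant_frequency_hz"] <= 0) or np.any(df["svl_mm"] <= 0):
        raise TraitError("frequency and size must be positive for log transform")
    return TraitTable(
        species=list(df["species"]),
        log_df=np.log(df["dominant_frequency_hz"].to_numpy(float)),
        log_size=np.log(df["svl_mm"].to_numpy(float)),
        site=df["calling_site"].str.strip().str.lower().to_numpy(object),
        me_var=df["me_var"].to_numpy(float),
    )


def reconcile(tree: Phylogeny, raw: pd.DataFrame):
    """Prune tree and trait rows to their common species set.

    Matching is exact after space/underscore normalization and case-folding.
    Returns ``(pruned_tree, trait_table)`` with the table in the pruned
    tree's tip order; dropped names on either side are logged.
    """
    trait_norm = {_normalize_label(s): i for i, s in enumerate(raw["species"])}
    tree_norm = {_normalize_label(l): l for l in tree.tip_labels}
    common = set(trait_norm) & set(tree_norm)
    if not common:
        raise TreeError("no species shared between tree and trait table")
    dropped_tips = [l for l in tree.tip_labels if _normalize_label(l) not in common]
    dropped_rows = [s for s in raw["species"] if _normalize_label(s) not in common]
    if dropped_tips:
        logger.info("reconcile: dropping %d tree tips without traits: %s",
                    len(dropped_tips), ", ".join(dropped_tips[:10]))
    if dropped_rows:
        logger.info("reconcile: dropping %d trait rows not in tree: %s",
                    len(dropped_rows), ", ".join(map(str, dropped_rows[:10])))
    if len(common) < 4:
        raise TreeError(f"only {len(common)} species shared; need at least 4")
    pruned = tree.prune_to([tree_norm[c] for c in common])
    rows = [trait_norm[_normalize_label(l)] for l in pruned.tip_labels]
    table = _table_from_raw(raw.iloc[rows].reset_index(drop=True))
    table.species = list(pruned.tip_labels)  # keep tree spelling
    return pruned, table


def impute_me(table: TraitTable, policy: str = "mean") -> TraitTable:
    """Fill missing measurement-error variances.

    policy: ``"mean"`` (mean of observed me_var), ``"zero"``, or
    ``"fixed:<value>"``.
    """
    me = table.me_var.copy()
    missing = np.isnan(me)
    if policy == "mean":
        if missing.all():
            raise TraitError(
                "policy='mean' needs at least one observed me_var; use 'zero' or 'fixed:<v>'"
            )
        me[missing] = np.nanmean(me)
    elif policy == "zero":
        me[missing] = 0.0
    elif policy.startswith("fixed:"):
        value = float(policy.split(":", 1)[1])
        if value < 0:
            raise TraitError("fixed me_var must be >= 0")
        me[missing] = value
    else:
        raise TraitError(f"unknown ME policy: {policy!r}")
    return TraitTable(
        species=list(table.species),
        log_df=table.log_df.copy(),
        log_size=table.log_size.copy(),
        site=table.site.copy(),
        me_var=me,
        me_policy=policy,
    )
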