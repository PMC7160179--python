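"""Shift configurations and regime paintings.

A shift lives on a branch (identified by the node below it) at a fractional
position measured from the rootward end.  K shifts partition the tree into
K+1 selective regimes: regime 0 is the root/ancestral regime and each shift
starts a new regime inherited tipward until overridden by a more tipward
shift.  At most one shift per branch.  Regime ids are canonical: shifts are
ordered by the pre-order rank of their branch, and shift j (0-based) creates
regime j+1, so summaries are stable under re-orderings of the shift set.
"""
from __future__ import annotations

import dataclasses
import json

import numpy as np

from .tree import Phylogeny


class RegimeError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class ShiftPoint:
    branch: int      # node id below the branch carrying the shift
    position: float  # fraction of the branch from its rootward end, in [0, 1]

    def __post_init__(self):
        if not 0.0 <= self.position <= 1.0:
            raise RegimeError(f"shift position must be in [0,1], got {self.position}")


@dataclasses.dataclass(frozen=True)
class ShiftConfig:
    shifts: tuple  # tuple[ShiftPoint, ...] in canonical order

    @property
    def k(self) -> int:
        return len(self.shifts)

    @staticmethod
    def of(shifts, tree: Phylogeny) -> "ShiftConfig":
        """Build a canonical config, validating the one-shift-per-branch rule."""
        shifts = [s if isinstance(s, ShiftPoint) else ShiftPoint(*s) for s in shifts]
        branches = [s.branch for s in shifts]
        if len(set(branches)) != len(branches):
            raise RegimeError("duplicate branch in shift configuration")
        for s in shifts:
            if s.branch == tree.root or not (0 <= s.branch < tree.n_nodes):
                raise RegimeError(f"shift branch {s.branch} does not exist in tree")
        shifts.sort(key=lambda s: int(tree.preorder[s.branch]))
        return ShiftConfig(tuple(shifts))

    def shift_times(self, tree: Phylogeny) -> np.ndarray:
        """Absolute time (from the root) at which each shift occurs."""
        return np.array(
            [tree.depths[tree.parent[s.branch]] + s.position * tree.lengths[s.branch]
             for s in self.shifts]
        )

    # ------------------------------------------------------------------ JSON
    def to_json(self, tree: Phylogeny) -> str:
        items = []
        for s in self.shifts:
            tips = tree.subtree_tips(s.branch)
            items.append({
                "clade": [tree.tip_labels[i] for i in tips],
                "position": s.position,
            })
        return json.dumps({"shifts": items})

    @staticmethod
    def from_json(data: str, tree: Phylogeny) -> "ShiftConfig":
        obj = json.loads(data)
        shifts = []
        for item in obj["shifts"]:
            branch = tree.clade_branch(item["clade"])
            shifts.append(ShiftPoint(branch, float(item["position"])))
        return ShiftConfig.of(shifts, tree)


EMPTY = ShiftConfig(())


@dataclasses.dataclass
class RegimePainting:
    """Per-tip root-to-tip segment lists ``(regime, t_start, t_end)``."""

    segments: list           # one list per tip, aligned to tree tip order
    tip_regime: np.ndarray   # terminal regime per tip
    n_regimes: int

    def validate(self, tree: Phylogeny) -> None:
        for i, segs in enumerate(self.segments):
            t = 0.0
            for (_, t0, t1) in segs:
                if not np.isclose(t0, t):
                    raise RegimeError(f"non-contiguous segments for tip {i}")
                t = t1
            if not np.isclose(t, tree.tip_depths[i]):
                raise RegimeError(f"segments for tip {i} do not span [0, depth]")


def paint(tree: Phylogeny, config: ShiftConfig) -> RegimePainting:
    """Map a shift configuration to a regime painting of the tree."""
    config = ShiftConfig.of(config.shifts, tree)  # validates + canonicalizes
    times = config.shift_times(tree)
    shift_on = {s.branch: (j + 1, times[j]) for j, s in enumerate(config.shifts)}

    # pre-order walk carrying the chain of (time, regime) events along the path
    events_at = {tree.root: ()}
    regime_at = {tree.root: 0}
    stack = [tree.root]
    while stack:
        v = stack.pop()
        for c in tree.children[v]:
            ev, reg = events_at[v], regime_at[v]
            if c in shift_on:
                r_new, t = shift_on[c]
                ev = ev + ((t, r_new),)
                reg = r_new
            events_at[c] = ev
            regime_at[c] = reg
            stack.append(c)

    segments = []
    tip_regime = np.zeros(tree.n_tips, dtype=np.int64)
    for i, tid in enumerate(tree.tip_ids):
        T = tree.tip_depths[i]
        ev = events_at[int(tid)]
        segs, cur, t_prev = [], 0, 0.0
        for (t, r) in ev:
            if t > t_prev:
                segs.append((cur, t_prev, t))
            cur, t_prev = r, t
        segs.append((cur, t_prev, T))
        segments.append(segs)
        tip_regime[i] = cur
    return RegimePainting(segments, tip_regime, config.k + 1)


def regime_species_count(tree: Phylogeny, config: ShiftConfig) -> dict:
    """Tips whose terminal segment lies in each regime; sums to n_tips."""
    painting = paint(tree, config)
    counts = {r: 0 for r in range(painting.n_regimes)}
    for r in painting.tip_regime:
        counts[int(r)] += 1
    return counts
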