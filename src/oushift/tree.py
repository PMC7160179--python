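"""Indexed phylogeny container and tree I/O.

Nodes are identified by their post-order rank (0-based); the root is always
node ``n_nodes - 1``.  Branch ``b`` refers to the edge subtending node ``b``
(the edge between ``b`` and its parent), so every non-root node names exactly
one branch.  Branch lengths are in time units (e.g. My, or unit tree depth for
simulated trees).
"""
from __future__ import annotations

import dataclasses
import logging

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

ULTRAMETRIC_RTOL = 1e-6


class TreeError(ValueError):
    """Raised when a tree cannot be parsed or violates structural requirements."""


def _normalize_label(label: str) -> str:
    return label.strip().replace(" ", "_").casefold()


@dataclasses.dataclass
class Phylogeny:
    """Rooted tree with post-order integer node ids and branch lengths.

    Attributes
    ----------
    parent : (n_nodes,) int array, parent id per node, -1 at the root.
    lengths : (n_nodes,) float array, length of the branch above each node
        (0.0 at the root).
    children : list of child-id lists per node.
    tip_ids : node ids of the tips in post-order (ascending id) order.
    tip_labels : species names aligned with ``tip_ids``.
    """

    parent: np.ndarray
    lengths: np.ndarray
    children: list
    tip_ids: np.ndarray
    tip_labels: list

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.lengths = np.asarray(self.lengths, dtype=float)
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise TreeError(f"tree must have exactly one root, found {roots.size}")
        self.root = int(roots[0])
        if np.any(self.lengths < 0):
            bad = int(np.flatnonzero(self.lengths < 0)[0])
            raise TreeError(f"negative branch length on branch {bad}")
        if len(set(self.tip_labels)) != len(self.tip_labels):
            seen, dup = set(), None
            for lab in self.tip_labels:
                if lab in seen:
                    dup = lab
                    break
                seen.add(lab)
            raise TreeError(f"duplicate tip label: {dup!r}")
        # depths from the root, filled in pre-order (reverse post-order)
        n = self.n_nodes
        self.depths = np.zeros(n)
        order = np.argsort(-np.arange(n))  # root first
        for v in order:
            p = self.parent[v]
            if p >= 0:
                self.depths[v] = self.depths[p] + self.lengths[v]
        self.tip_depths = self.depths[self.tip_ids]
        span = self.tip_depths.max() - self.tip_depths.min()
        self.is_ultrametric = bool(span <= ULTRAMETRIC_RTOL * max(self.tip_depths.max(), 1e-300))
        # pre-order ranks (root rank 0), used to canonicalize regime ids
        self.preorder = np.empty(n, dtype=np.int64)
        rank = 0
        stack = [self.root]
        order_list = []
        while stack:
            v = stack.pop()
            self.preorder[v] = rank
            rank += 1
            order_list.append(v)
            stack.extend(reversed(self.children[v]))
        self._preorder_nodes = np.array(order_list, dtype=np.int64)
        self._tip_pos = {tid: i for i, tid in enumerate(self.tip_ids)}
        self.label_to_tip = {lab: i for i, lab in enumerate(self.tip_labels)}
        self._norm_label_to_tip = {_normalize_label(l): i for i, l in enumerate(self.tip_labels)}
        self._below = None
        self._shared = None

    # ------------------------------------------------------------------ sizes
    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    @property
    def n_tips(self) -> int:
        return self.tip_ids.shape[0]

    @property
    def depth(self) -> float:
        return float(self.tip_depths.max())

    @property
    def total_branch_length(self) -> float:
        return float(self.lengths.sum())

    # ------------------------------------------------------------ constructors
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        nodes = list(tree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        lengths = np.zeros(n)
        children: list = [[] for _ in range(n)]
        tip_ids, tip_labels = [], []
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                parent[i] = p
                children[p].append(i)
                if nd.edge.length is None:
                    who = nd.taxon.label if nd.taxon else f"internal node {i}"
                    raise TreeError(f"missing branch length above {who}")
                lengths[i] = float(nd.edge.length)
            if nd.is_leaf():
                if nd.taxon is None or nd.taxon.label is None:
                    raise TreeError(f"unlabeled tip (node {i})")
                tip_ids.append(i)
                tip_labels.append(nd.taxon.label)
        # children were appended in postorder discovery order; sort for stability
        children = [sorted(ch) for ch in children]
        return cls(parent, lengths, children, np.array(tip_ids, dtype=np.int64), tip_labels)

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True,
                rooting="default-rooted", suppress_internal_node_taxa=True,
            )
        except TreeError:
            raise
        except Exception as exc:
            raise TreeError(f"could not parse newick: {exc}") from exc
        return cls.from_dendropy(tree)

    # ------------------------------------------------------------------- I/O
    def to_newick(self) -> str:
        parts = [None] * self.n_nodes

        for v in range(self.n_nodes):  # ids are post-order, children precede parents
            if not self.children[v]:
                lab = self.tip_labels[self._tip_pos[v]]
                parts[v] = f"{lab}:{self.lengths[v]:.12g}"
            else:
                inner = ",".join(parts[c] for c in self.children[v])
                if v == self.root:
                    parts[v] = f"({inner});"
                else:
                    parts[v] = f"({inner}):{self.lengths[v]:.12g}"
        return parts[self.root]

    def write(self, path, format: str = "newick") -> None:
        write_tree(self, path, format)

    # ------------------------------------------------------------- structure
    def below_mask(self) -> np.ndarray:
        """(n_nodes, n_tips) boolean: tip j descends from (or is) node i."""
        if self._below is None:
            m = np.zeros((self.n_nodes, self.n_tips), dtype=bool)
            for v in range(self.n_nodes):
                if not self.children[v]:
                    m[v, self._tip_pos[v]] = True
                else:
                    for c in self.children[v]:
                        m[v] |= m[c]
            self._below = m
        return self._below

    def subtree_tips(self, node: int) -> np.ndarray:
        """Positions (0..n_tips-1) of tips descending from ``node``."""
        return np.flatnonzero(self.below_mask()[node])

    def shared_depths(self) -> np.ndarray:
        """(n_tips, n_tips) matrix of MRCA depths; diagonal is tip depth.

        Under Brownian motion with unit rate this is the trait covariance.
        """
        if self._shared is None:
            n = self.n_tips
            S = np.zeros((n, n))
            below = self.below_mask()
            for v in range(self.n_nodes):
                ch = self.children[v]
                if len(ch) < 2:
                    continue
                for a in range(len(ch)):
                    ta = np.flatnonzero(below[ch[a]])
                    for b in range(a + 1, len(ch)):
                        tb = np.flatnonzero(below[ch[b]])
                        S[np.ix_(ta, tb)] = self.depths[v]
                        S[np.ix_(tb, ta)] = self.depths[v]
            np.fill_diagonal(S, self.tip_depths)
            self._shared = S
        return self._shared

    def mrca(self, tip_positions) -> int:
        """Node id of the most recent common ancestor of the given tips."""
        tip_positions = np.atleast_1d(np.asarray(tip_positions, dtype=np.int64))
        cur = int(self.tip_ids[tip_positions[0]])
        for tp in tip_positions[1:]:
            other = int(self.tip_ids[tp])
            while cur != other:
                if self.depths[cur] >= self.depths[other]:
                    cur = int(self.parent[cur])
                else:
                    other = int(self.parent[other])
        return cur

    def clade_branch(self, labels) -> int:
        """Branch id (the MRCA node) subtending the clade named by tip labels."""
        pos = []
        for lab in labels:
            i = self._norm_label_to_tip.get(_normalize_label(lab))
            if i is None:
                raise TreeError(f"tip label not in tree: {lab!r}")
            pos.append(i)
        return self.mrca(np.array(pos))

    def branch_ids(self) -> np.ndarray:
        """All branch ids (every node except the root)."""
        return np.array([v for v in range(self.n_nodes) if v != self.root], dtype=np.int64)

    # --------------------------------------------------------------- pruning
    def prune_to(self, labels) -> "Phylogeny":
        """Return the tree restricted to the given tip labels.

        The original root is kept (even if left with a single child) so that
        the root-to-tip depth of every retained tip is unchanged; unifurcation
        chains below it are merged with summed branch lengths.
        """
        norm = {_normalize_label(l) for l in labels}
        keep_tip = np.array(
            [_normalize_label(l) in norm for l in self.tip_labels], dtype=bool
        )
        if keep_tip.sum() == 0:
            raise TreeError("no tips retained by pruning")
        keep_node = np.zeros(self.n_nodes, dtype=bool)
        for i, tid in enumerate(self.tip_ids):
            keep_node[tid] = keep_tip[i]
        for v in range(self.n_nodes):
            for c in self.children[v]:
                keep_node[v] |= keep_node[c]
        # rebuild, merging unifurcations (root excepted)
        new_parent_of = {}
        new_len_of = {}
        new_children: dict = {}
        alive = []

        def effective_children(v):
            out = []
            for c in self.children[v]:
                if not keep_node[c]:
                    continue
                # walk down through unifurcation chains, summing lengths
                node, acc = c, self.lengths[c]
                while True:
                    kids = [k for k in self.children[node] if keep_node[k]]
                    if len(kids) == 1:
                        node = kids[0]
                        acc += self.lengths[node]
                    else:
                        break
                out.append((node, acc))
            return out

        stack = [(self.root, -1, 0.0)]
        while stack:
            v, par, ln = stack.pop()
            alive.append(v)
            new_parent_of[v] = par
            new_len_of[v] = ln
            new_children[v] = []
            if par >= 0:
                new_children[par].append(v)
            for c, acc in reversed(effective_children(v)):
                stack.append((c, v, acc))

        order = [v for v in alive]
        # reassign ids by post-order of the new structure
        post = []
        stack2 = [(self.root, False)]
        while stack2:
            v, done = stack2.pop()
            if done:
                post.append(v)
            else:
                stack2.append((v, True))
                for c in reversed(new_children[v]):
                    stack2.append((c, False))
        idx = {v: i for i, v in enumerate(post)}
        n = len(post)
        parent = np.full(n, -1, dtype=np.int64)
        lengths = np.zeros(n)
        children: list = [[] for _ in range(n)]
        tip_ids, tip_labels = [], []
        for v in post:
            i = idx[v]
            p = new_parent_of[v]
            if p >= 0:
                parent[i] = idx[p]
                children[idx[p]].append(i)
                lengths[i] = new_len_of[v]
            if not new_children[v]:
                tip_ids.append(i)
                tip_labels.append(self.tip_labels[self._tip_pos[v]])
        children = [sorted(c) for c in children]
        order_tips = np.argsort(np.array(tip_ids))
        tip_ids_arr = np.array(tip_ids, dtype=np.int64)[order_tips]
        tip_labels = [tip_labels[i] for i in order_tips]
        return Phylogeny(parent, lengths, children, tip_ids_arr, tip_labels)


def read_tree(path, format: str = "newick") -> Phylogeny:
    """Read a rooted, branch-length-bearing tree from Newick or Nexus."""
    if format not in ("newick", "nexus"):
        raise TreeError(f"unsupported tree format: {format!r}")
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema=format, preserve_underscores=True,
            rooting="default-rooted", suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted parse errors
        raise TreeError(f"could not parse {path} as {format}: {exc}") from exc
    phy = Phylogeny.from_dendropy(tree)
    logger.info(
        "read %s: %d tips, depth %.6g, ultrametric=%s",
        path, phy.n_tips, phy.depth, phy.is_ultrametric,
    )
    if not phy.is_ultrametric:
        logger.warning("tree %s is not ultrametric; OU likelihood does not require it", path)
    return phy


def write_tree(phy: Phylogeny, path, format: str = "newick") -> None:
    newick = phy.to_newick()
    if format == "newick":
        with open(path, "w") as fh:
            fh.write(newick + "\n")
    elif format == "nexus":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True, rooting="default-rooted")
        tree.write(path=str(path), schema="nexus", unquoted_underscores=True)
    else:
        raise TreeError(f"unsupported tree format: {format!r}")
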