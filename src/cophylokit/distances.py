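"""Host-vs-pathogen tree distance measures.

All measures here compare two rooted trees over the *same* set of tip
labels (enforced; use :func:`cophylokit.treecore.graft_zero_branches` to
one-to-one map real host/pathogen tip sets first).  The battery covers the
classic families:

* clade/bipartition set measures: RF (rooted, normalized), nPH85
  (unrooted, normalized), KF (branch-score, L2 over split lengths),
  Align (optimal one-to-one branch matching), Sim (branch-length-weighted
  shared-clade probability);
* path-length measures: Node (L1 over tip-pair path node counts),
  pathdist / pathdistw (L2 over tip-pair path lengths, in edges or branch
  lengths), KC / KCw (Kendall-Colijn root-to-MRCA vectors, topological or
  length-weighted);
* agreement measures: MAST (maximum agreement subtree), Trip / TripL
  (rooted triplet disagreement, optionally weighted by the triplet's
  internal branch lengths);
* the subset-tree kernels kU, kL, kUn, kLn (delegated to
  :mod:`cophylokit.kernels`, reported as 1 - cosine score).

Set-based measures tolerate polytomies directly; MAST and the kernels
require binary trees, and :func:`compute_all` resolves polytomies with
seeded zero-length branches before calling them.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, sqrt

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import LabelMismatchError, NormalizationError, TreeValidationError, CophyloError
from .kernels import KernelConfig, kernel_distance
from .treecore import TimeTree, resolve_polytomies

__all__ = [
    "MEASURES",
    "TreeProfile",
    "rf_distance",
    "nph85_distance",
    "kf_distance",
    "path_distance",
    "node_distance",
    "align_distance",
    "mast_distance",
    "trip_distance",
    "sim_distance",
    "kc_distance",
    "compute_all",
]

MEASURES = [
    "RF",
    "nPH85",
    "KF",
    "pathdist",
    "pathdistw",
    "Node",
    "Align",
    "MAST",
    "Trip",
    "TripL",
    "Sim",
    "KC",
    "KCw",
    "kU",
    "kL",
    "kUn",
    "kLn",
]


class TreeProfile:
    """Shared precomputations for one tree over an agreed tip ordering.

    Holds clade index sets, unrooted splits with lengths, tip-pair path
    matrices (edge counts and branch lengths) and root-to-MRCA matrices.
    """

    def __init__(self, tree: TimeTree, tip_order: list[str] | None = None):
        tree.validate()
        self.tree = tree
        labels = tree.tip_labels()
        if len(set(labels)) != len(labels):
            raise TreeValidationError("duplicate tip labels")
        self.tip_order = tip_order or sorted(labels)
        if sorted(labels) != sorted(self.tip_order):
            raise LabelMismatchError(
                f"tip sets differ: {sorted(labels)[:5]}... vs {sorted(self.tip_order)[:5]}..."
            )
        self.n = len(labels)
        index = {lab: i for i, lab in enumerate(self.tip_order)}

        # clades as frozensets of tip indices, per node
        self.node_clade = {}
        for node in tree.postorder():
            if node.is_tip:
                self.node_clade[node] = frozenset([index[node.label]])
            else:
                self.node_clade[node] = frozenset().union(
                    *(self.node_clade[c] for c in node.children)
                )
        root = tree.root
        # rooted clades of non-root branches, with subtending branch lengths
        self.branch_clades: list[tuple[frozenset, float]] = [
            (self.node_clade[nd], float(nd.length or 0.0)) for nd in tree.branches()
        ]
        self.rooted_clades = {c for c, _ in self.branch_clades}
        self.nontrivial_clades = {
            self.node_clade[nd]
            for nd in tree.preorder()
            if nd is not root and not nd.is_tip and 1 < len(self.node_clade[nd]) < self.n
        }

        # unrooted splits: canonical side = the side not containing tip 0
        full = frozenset(range(self.n))
        self.split_lengths: dict[frozenset, float] = {}
        for clade, length in self.branch_clades:
            if len(clade) in (0, self.n):
                continue
            side = clade if 0 not in clade else full - clade
            self.split_lengths[side] = self.split_lengths.get(side, 0.0) + length
        self.splits = set(self.split_lengths)
        self.nontrivial_splits = {s for s in self.splits if 1 < len(s) < self.n - 1}

        # depths per tip / node, and MRCA matrices over tip pairs
        depth_len = {root: 0.0}
        depth_top = {root: 0}
        for node in tree.preorder():
            if node is root:
                continue
            depth_len[node] = depth_len[node.parent] + float(node.length or 0.0)
            depth_top[node] = depth_top[node.parent] + 1
        tipnode = {index[t.label]: t for t in tree.tips()}
        self.tip_depth_len = np.array([depth_len[tipnode[i]] for i in range(self.n)])
        self.tip_depth_top = np.array([depth_top[tipnode[i]] for i in range(self.n)], dtype=float)
        self.pendant_lengths = np.array(
            [float(tipnode[i].length or 0.0) for i in range(self.n)]
        )

        self.mrca_len = np.zeros((self.n, self.n))
        self.mrca_top = np.zeros((self.n, self.n))
        np.fill_diagonal(self.mrca_len, self.tip_depth_len)
        np.fill_diagonal(self.mrca_top, self.tip_depth_top)
        for node in tree.preorder():
            if node.is_tip:
                continue
            kids = [sorted(self.node_clade[c]) for c in node.children]
            for a, b in combinations(range(len(kids)), 2):
                for i in kids[a]:
                    for j in kids[b]:
                        self.mrca_len[i, j] = self.mrca_len[j, i] = depth_len[node]
                        self.mrca_top[i, j] = self.mrca_top[j, i] = depth_top[node]

        dl = self.tip_depth_len
        dt = self.tip_depth_top
        self.path_len = dl[:, None] + dl[None, :] - 2 * self.mrca_len
        self.path_top = dt[:, None] + dt[None, :] - 2 * self.mrca_top
        np.fill_diagonal(self.path_len, 0.0)
        np.fill_diagonal(self.path_top, 0.0)

        self.total_length = float(sum(l for _, l in self.branch_clades))


def _profiles(t1, t2) -> tuple[TreeProfile, TreeProfile]:
    p1 = t1 if isinstance(t1, TreeProfile) else TreeProfile(t1)
    p2 = t2 if isinstance(t2, TreeProfile) else TreeProfile(t2, tip_order=p1.tip_order)
    if isinstance(t2, TreeProfile) and p2.tip_order != p1.tip_order:
        raise LabelMismatchError("profiles built over different tip orderings")
    return p1, p2


# ---------------------------------------------------------------------------
# Clade / split measures
# ---------------------------------------------------------------------------


def rf_distance(t1, t2, normalized: bool = True) -> float:
    """Rooted Robinson-Foulds: symmetric difference of nontrivial clades.

    Normalized by the total number of nontrivial clades in the two trees
    (the maximum attainable count for the pair).
    """
    p1, p2 = _profiles(t1, t2)
    sym = len(p1.nontrivial_clades ^ p2.nontrivial_clades)
    if not normalized:
        return float(sym)
    denom = len(p1.nontrivial_clades) + len(p2.nontrivial_clades)
    return sym / denom if denom else 0.0


def nph85_distance(t1, t2) -> float:
    """Normalized Penny-Hendy distance on unrooted nontrivial bipartitions.

    Symmetric difference of splits divided by 2(n-3); invariant to the
    position of the root.
    """
    p1, p2 = _profiles(t1, t2)
    sym = len(p1.nontrivial_splits ^ p2.nontrivial_splits)
    denom = 2 * (p1.n - 3)
    return sym / denom if denom > 0 else 0.0


def kf_distance(t1, t2) -> float:
    """Kuhner-Felsenstein branch-score distance.

    L2 norm over the union of unrooted splits (including pendant edges) of
    the difference in split lengths; a split absent from one tree counts
    with length 0.
    """
    p1, p2 = _profiles(t1, t2)
    total = 0.0
    for split in p1.splits | p2.splits:
        diff = p1.split_lengths.get(split, 0.0) - p2.split_lengths.get(split, 0.0)
        total += diff * diff
    return sqrt(total)


def sim_distance(t1, t2) -> float:
    """Hein's Sim distance: 1 minus the symmetrized probability that a
    uniformly random point of one tree sits on a branch whose subtended
    tip set also exists in the other tree (branch-length weighted)."""
    p1, p2 = _profiles(t1, t2)
    if p1.total_length <= 0 or p2.total_length <= 0:
        raise NormalizationError("Sim requires positive total branch length")

    def shared_fraction(a: TreeProfile, b: TreeProfile) -> float:
        num = sum(l for clade, l in a.branch_clades if clade in b.rooted_clades)
        return num / a.total_length

    return 1.0 - 0.5 * (shared_fraction(p1, p2) + shared_fraction(p2, p1))


def align_distance(t1, t2) -> float:
    """Nye et al. branch alignment distance.

    Every non-root branch defines a bipartition; a pair of branches is
    scored by the best-orientation minimum Jaccard agreement of the two
    sides, and an optimal one-to-one assignment (Hungarian algorithm,
    lowest-index preference on ties) defines the distance as the summed
    disagreement ``1 - score``; unmatched branches count 1.
    """
    p1, p2 = _profiles(t1, t2)
    full = frozenset(range(p1.n))
    sides1 = [(c, full - c) for c, _ in p1.branch_clades]
    sides2 = [(c, full - c) for c, _ in p2.branch_clades]
    n1, n2 = len(sides1), len(sides2)
    m = max(n1, n2)
    cost = np.ones((m, m))

    def jaccard(a, b):
        inter = len(a & b)
        union = len(a | b)
        return inter / union if union else 1.0

    for i, (a1, b1) in enumerate(sides1):
        for j, (a2, b2) in enumerate(sides2):
            score = max(
                min(jaccard(a1, a2), jaccard(b1, b2)),
                min(jaccard(a1, b2), jaccard(b1, a2)),
            )
            cost[i, j] = 1.0 - score
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].sum())


# ---------------------------------------------------------------------------
# Path measures
# ---------------------------------------------------------------------------


def _pair_upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def path_distance(t1, t2, weighted: bool = False) -> float:
    """Steel-Penny path difference: L2 over tip pairs of path lengths
    (edge counts, or summed branch lengths when ``weighted``)."""
    p1, p2 = _profiles(t1, t2)
    m1 = p1.path_len if weighted else p1.path_top
    m2 = p2.path_len if weighted else p2.path_top
    return float(np.linalg.norm(_pair_upper(m1) - _pair_upper(m2)))


def node_distance(t1, t2) -> float:
    """Williams-Clifford Node distance: L1 over tip pairs of node-count
    path lengths."""
    p1, p2 = _profiles(t1, t2)
    return float(np.abs(_pair_upper(p1.path_top) - _pair_upper(p2.path_top)).sum())


def kc_distance(t1, t2, lambda_mix: float = 0.0) -> float:
    """Kendall-Colijn metric.

    Each tree is represented by the vector of root-to-MRCA depths over tip
    pairs plus the per-tip pendant entries; depths are counted in edges
    (weight ``1 - lambda_mix``) and in branch lengths (weight
    ``lambda_mix``).  KC is ``lambda_mix = 0``, KCw is ``lambda_mix = 1``.
    """
    if not 0.0 <= lambda_mix <= 1.0:
        raise ValueError("lambda_mix must be in [0, 1]")
    p1, p2 = _profiles(t1, t2)

    def vector(p: TreeProfile) -> np.ndarray:
        pairs_top = _pair_upper(p.mrca_top)
        pairs_len = _pair_upper(p.mrca_len)
        tips_top = np.ones(p.n)
        tips_len = p.pendant_lengths
        topo = np.concatenate([pairs_top, tips_top])
        lens = np.concatenate([pairs_len, tips_len])
        return (1.0 - lambda_mix) * topo + lambda_mix * lens

    return float(np.linalg.norm(vector(p1) - vector(p2)))


# ---------------------------------------------------------------------------
# Agreement measures
# ---------------------------------------------------------------------------


def mast_distance(t1, t2, normalized: bool = False) -> float:
    """Maximum agreement subtree distance ``n - |MAST|``.

    Dynamic program over node pairs of two rooted binary trees; optionally
    divided by n.
    """
    p1, p2 = _profiles(t1, t2)
    for p in (p1, p2):
        for node in p.tree.preorder():
            if not node.is_tip and len(node.children) != 2:
                raise TreeValidationError("MAST requires binary trees; resolve polytomies")

    memo: dict[tuple[int, int], int] = {}

    def labels_of(profile, node):
        return profile.node_clade[node]

    def m(a, b) -> int:
        key = (id(a), id(b))
        if key in memo:
            return memo[key]
        if a.is_tip and b.is_tip:
            val = 1 if a.label == b.label else 0
        elif a.is_tip:
            val = 1 if labels_of(p1, a) <= labels_of(p2, b) else 0
        elif b.is_tip:
            val = 1 if labels_of(p2, b) <= labels_of(p1, a) else 0
        else:
            a1, a2 = a.children
            b1, b2 = b.children
            val = max(
                m(a1, b1) + m(a2, b2),
                m(a1, b2) + m(a2, b1),
                m(a, b1),
                m(a, b2),
                m(a1, b),
                m(a2, b),
            )
        memo[key] = val
        return val

    size = m(p1.tree.root, p2.tree.root)
    dist = p1.n - size
    return dist / p1.n if normalized else float(dist)


def _triplet_profile(p: TreeProfile, i: int, j: int, k: int):
    """Cherry pair of the rooted triplet {i,j,k} and its internal length.

    Returns (cherry, internal_length) where cherry is the index pair with
    the strictly deepest MRCA, or None for an unresolved triplet; the
    internal length is the path length between the triplet's two internal
    nodes (0 when unresolved).
    """
    pairs = [(i, j), (i, k), (j, k)]
    depths = [p.mrca_top[a, b] for a, b in pairs]
    lens = [p.mrca_len[a, b] for a, b in pairs]
    best = max(depths)
    deepest = [idx for idx, d in enumerate(depths) if d == best]
    if len(deepest) != 1:
        return None, 0.0
    c = deepest[0]
    internal = lens[c] - min(lens)
    return pairs[c], internal


def trip_distance(t1, t2, weighted: bool = False) -> float:
    """Critchlow's triplet distance (fraction of discordant rooted triplets).

    The weighted variant (TripL) replaces the 0/1 topology score with the
    triplets' internal branch lengths: a concordant triplet contributes
    the absolute difference ``|d1 - d2|`` of the internal path lengths
    separating its cherry from the outgroup, a discordant one the total
    ``d1 + d2``; the result is the mean over all C(n,3) triplets (so TripL
    carries branch-length units and is dominated by length discordance,
    like the other length-weighted measures).
    """
    p1, p2 = _profiles(t1, t2)
    n = p1.n
    if n < 3:
        return 0.0
    total = 0.0
    count = comb(n, 3)
    for i, j, k in combinations(range(n), 3):
        c1, d1 = _triplet_profile(p1, i, j, k)
        c2, d2 = _triplet_profile(p2, i, j, k)
        if weighted:
            total += abs(d1 - d2) if c1 == c2 else d1 + d2
        elif c1 != c2:
            total += 1.0
    return total / count


# ---------------------------------------------------------------------------
# One-pass dispatch
# ---------------------------------------------------------------------------


def compute_all(
    t1: TimeTree,
    t2: TimeTree,
    measures: list[str] | None = None,
    options: dict | None = None,
) -> dict[str, float]:
    """Compute a set of measures between two trees in one pass.

    Shares the :class:`TreeProfile` precomputations across measures;
    results are identical to the individual calls.  MAST and the kernels
    see polytomies resolved with zero-length branches (seed from
    ``options['seed']``, default 0).
    """
    measures = measures or list(MEASURES)
    options = options or {}
    unknown = [m for m in measures if m not in MEASURES]
    if unknown:
        raise CophyloError(f"unknown measure(s): {', '.join(unknown)}")

    kernel_only = {"kU", "kL", "kUn", "kLn"}
    p1 = p2 = None
    if any(m not in kernel_only for m in measures):
        # label-matched profiles; kernels alone tolerate disjoint tip sets
        p1 = TreeProfile(t1)
        p2 = TreeProfile(t2, tip_order=p1.tip_order)

    seed = int(options.get("seed", 0))
    binary_needed = kernel_only | {"MAST"}
    b1 = b2 = None
    bp1 = bp2 = None
    if any(m in binary_needed for m in measures):
        b1 = resolve_polytomies(t1, seed=seed)
        b2 = resolve_polytomies(t2, seed=seed + 1)
        if "MAST" in measures:
            bp1 = TreeProfile(b1)
            bp2 = TreeProfile(b2, tip_order=bp1.tip_order)

    out: dict[str, float] = {}
    for m in measures:
        try:
            if m == "RF":
                out[m] = rf_distance(p1, p2, normalized=options.get("rf_normalized", True))
            elif m == "nPH85":
                out[m] = nph85_distance(p1, p2)
            elif m == "KF":
                out[m] = kf_distance(p1, p2)
            elif m == "pathdist":
                out[m] = path_distance(p1, p2, weighted=False)
            elif m == "pathdistw":
                out[m] = path_distance(p1, p2, weighted=True)
            elif m == "Node":
                out[m] = node_distance(p1, p2)
            elif m == "Align":
                out[m] = align_distance(p1, p2)
            elif m == "MAST":
                out[m] = mast_distance(bp1, bp2, normalized=options.get("mast_normalized", False))
            elif m == "Trip":
                out[m] = trip_distance(p1, p2, weighted=False)
            elif m == "TripL":
                out[m] = trip_distance(p1, p2, weighted=True)
            elif m == "Sim":
                out[m] = sim_distance(p1, p2)
            elif m == "KC":
                out[m] = kc_distance(p1, p2, lambda_mix=0.0)
            elif m == "KCw":
                out[m] = kc_distance(p1, p2, lambda_mix=1.0)
            elif m == "kU":
                out[m] = kernel_distance(b1, b2, KernelConfig.unlabeled())
            elif m == "kUn":
                out[m] = kernel_distance(b1, b2, KernelConfig.unlabeled(normalize_lengths=True))
            elif m == "kL":
                out[m] = kernel_distance(b1, b2, KernelConfig.labeled_tips())
            elif m == "kLn":
                out[m] = kernel_distance(b1, b2, KernelConfig.labeled_tips(normalize_lengths=True))
        except CophyloError as exc:
            raise type(exc)(f"[{m}] {exc}") from exc
    return out
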