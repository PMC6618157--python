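"""Synthetic inputs: surrogate host trees and toy tree pairs.

Real analyses start from a time-scaled host phylogeny (e.g. pruned from a
published timetree).  For testing and self-contained experiments this
module generates ultrametric *surrogate* host trees under a pure-birth
(Yule) process, rescaled to a requested root age in Ma, plus a set of
small hard-coded tree pairs with independently derived expected distances.

The Yule construction is the standard forward one: starting from the root
split, with k extant lineages the next split arrives after an
Exp(k * rate) wait on a uniformly random lineage; after the n-th lineage
is born one further Exp(n * rate) interval separates the last split from
the present, so no terminal branch has zero length.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp

import numpy as np

from .errors import TreeValidationError
from .treecore import TimeTree, TreeNode

__all__ = ["HostTreeSpec", "surrogate_host_tree", "toy_tree_pairs"]


@dataclass(frozen=True)
class HostTreeSpec:
    """Specification of a surrogate host tree.

    Defaults (20 tips, root age 500 Ma) approximate the scale of a
    vertebrate host clade.
    """

    n_tips: int = 20
    root_age: float = 500.0
    model: str = "pure_birth"
    seed: int | None = None

    def __post_init__(self):
        if self.n_tips < 2:
            raise TreeValidationError("host tree needs at least 2 tips")
        if self.root_age <= 0:
            raise TreeValidationError("root age must be positive")
        if self.model != "pure_birth":
            raise TreeValidationError(f"unknown model {self.model!r}")


def surrogate_host_tree(spec: HostTreeSpec | None = None, **kwargs) -> TimeTree:
    """Ultrametric rooted binary tree under a pure-birth process.

    Deterministic under ``spec.seed``; tips are labeled ``H01 .. Hnn`` in
    preorder.  Keyword arguments are forwarded to :class:`HostTreeSpec`.
    """
    spec = spec or HostTreeSpec(**kwargs)
    rng = np.random.default_rng(spec.seed)
    root = TreeNode()
    t = 0.0
    active: list[tuple[TreeNode, float]] = [
        (root.add_child(TreeNode()), 0.0),
        (root.add_child(TreeNode()), 0.0),
    ]
    while len(active) < spec.n_tips:
        t += rng.exponential(1.0 / len(active))
        idx = int(rng.integers(len(active)))
        node, _ = active.pop(idx)
        node.length = t - _
        active.append((node.add_child(TreeNode()), t))
        active.append((node.add_child(TreeNode()), t))
    t += rng.exponential(1.0 / len(active))
    for node, born in active:
        node.length = t - born

    tree = TimeTree(root)
    scale = spec.root_age / t
    for node in tree.branches():
        node.length = (node.length or 0.0) * scale
    width = max(2, len(str(spec.n_tips)))
    for i, tip in enumerate(tree.tips(), start=1):
        tip.label = f"H{i:0{width}d}"
    return tree


def toy_tree_pairs() -> dict[str, dict]:
    """Hard-coded small tree pairs with oracle-derived expected distances.

    Each entry maps a name to ``{"t1": newick, "t2": newick,
    "expected": {measure: value}}``.  Expected values were derived by hand
    or by the brute-force oracles in the test suite (clade enumeration,
    exhaustive triplet/assignment search, fragment enumeration for the
    kernel) and are frozen here.
    """
    bal4_a = "((A:1,B:1):1,(C:1,D:1):1);"
    bal4_b = "((A:1,C:1):1,(B:1,D:1):1);"
    relabeled = "((W:1,X:1):1,(Y:1,Z:1):1);"
    five = "((A:1,B:1):1,(C:1,(D:1,E:1):1):2);"
    return {
        "identical_5tip": {
            "t1": five,
            "t2": five,
            "expected": {m: 0.0 for m in [
                "RF", "nPH85", "KF", "pathdist", "pathdistw", "Node", "Align",
                "MAST", "Trip", "TripL", "Sim", "KC", "KCw", "kU", "kL", "kUn", "kLn",
            ]},
        },
        "rf_max_4tip": {
            "t1": bal4_a,
            "t2": bal4_b,
            # hand-derived: clade sets {AB, CD} vs {AC, BD} (symmetric
            # difference 4 of max 4); 2 shared splits of none nontrivial;
            # all 4 triplets discordant; MAST keeps {A, D}
            "expected": {
                "RF": 1.0,
                "nPH85": 1.0,
                "KF": 2.8284271247461903,
                "pathdist": 4.0,
                "pathdistw": 4.0,
                "Node": 8.0,
                "Align": 4.0 / 3.0,
                "MAST": 2.0,
                "Trip": 1.0,
                "TripL": 2.0,
                "Sim": 1.0 / 3.0,
                "KC": 2.0,
                "KCw": 2.0,
            },
        },
        "shape_congruent_label_swap": {
            "t1": bal4_a,
            "t2": relabeled,
            # congruent shapes, disjoint label sets: labeled kernel
            # similarity 0 (distance 1), unlabeled distance 0
            "expected": {"kL": 1.0, "kU": 0.0},
        },
        "cherry_lengths": {
            "t1": "(A:1,B:1);",
            "t2": "(A:1,B:2);",
            # raw unlabeled kernel at defaults (decay 0.2, sigma 2, s 1):
            # 4 tip-pair matches + decay*exp(-1/4)*(1+1)^2 at the roots
            "expected": {"kU_raw_score": 4.0 + 0.8 * exp(-0.25)},
        },
    }
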