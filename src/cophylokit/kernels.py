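"""Subset-tree kernels for phylogenies (unlabeled kU and labeled kL).

A *subset tree* is a fragment rooted at a node of a tree that extends
toward the descendants but need not reach the tips.  The kernel counts
fragments shared by two trees and weights every matched fragment by

* a decay factor per matched internal node (guards against the "large
  diagonal" problem of big fragments dominating the score),
* a Gaussian radial basis penalty on the discordance of the child
  branch-length vectors at every matched internal node, and
* for the labeled kernel, an indicator that matched tips carry the same
  label.

The score is computed by the usual dynamic program over node pairs::

    Delta(tip, tip)  = 1                      (unlabeled)
                     = 1[label1 == label2]    (labeled)
    Delta(n1, n2)    = decay * exp(-||l1 - l2||^2 / (2 sigma))
                       * prod_c (s + Delta(c1, c2))
    K(T1, T2)        = sum over all node pairs of Delta

with children paired after canonical ordering (phylogenies are unordered,
so a deterministic canonical form is required).  The matching parameter
``s`` controls whether fragments may stop short of the tips (s = 1) or
must be complete subtrees (s = 0); the labeled kernel requires s = 0,
otherwise shared shape overwhelms the label signal.

Scores are cosine-normalized, ``k12 / sqrt(k11 * k22)``, to adjust for
tree size, and converted to a distance as ``1 - cosine score``.  Variants
kUn/kLn first divide all branch lengths by the tree's mean branch length
(``normalize_lengths``), which makes the score invariant to the overall
rate of evolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import exp, fsum, sqrt

import numpy as np

from .errors import KernelError
from .treecore import TimeTree, normalize_branch_lengths

__all__ = [
    "KernelConfig",
    "KernelMatrix",
    "kernel_score",
    "cosine_normalize",
    "kernel_distance",
    "kernel_matrix",
    "kernel_pca",
]


@dataclass(frozen=True)
class KernelConfig:
    """Tuning parameters of the subset-tree kernel.

    decay : in (0, 1]; per-internal-node penalty against large fragments.
    sigma : > 0; variance-like scale of the Gaussian branch-length penalty
        ``exp(-||l1 - l2||^2 / (2 sigma))`` (the convention divides by
        ``2*sigma``, not ``2*sigma**2``).
    s : in [0, 1]; fragment matching parameter.  s = 0 restricts matches
        to complete subtrees; required in labeled mode.
    labeled : compare tip labels (kL) instead of ignoring them (kU).
    normalize_lengths : divide branch lengths by each tree's mean branch
        length before scoring (kUn / kLn).
    """

    decay: float = 0.2
    sigma: float = 2.0
    s: float = 1.0
    labeled: bool = False
    normalize_lengths: bool = False

    def __post_init__(self):
        if not 0.0 < self.decay <= 1.0:
            raise KernelError("decay must be in (0, 1]")
        if self.sigma <= 0:
            raise KernelError("sigma must be positive")
        if not 0.0 <= self.s <= 1.0:
            raise KernelError("s must be in [0, 1]")
        if self.labeled and self.s != 0.0:
            raise KernelError("labeled kernel requires s = 0")

    @classmethod
    def unlabeled(cls, normalize_lengths: bool = False) -> "KernelConfig":
        """kU (or kUn) defaults: decay 0.2, sigma 2, s 1."""
        return cls(normalize_lengths=normalize_lengths)

    @classmethod
    def labeled_tips(cls, normalize_lengths: bool = False) -> "KernelConfig":
        """kL (or kLn) defaults: decay 0.2, sigma 2, s 0, labeled."""
        return cls(s=0.0, labeled=True, normalize_lengths=normalize_lengths)

    def metadata(self) -> dict:
        return {
            "decay": self.decay,
            "sigma": self.sigma,
            "s": self.s,
            "labeled": self.labeled,
            "normalize_lengths": self.normalize_lengths,
            "gaussian_denominator": "2*sigma",
            "distance": "1 - cosine-normalized score",
        }


# ---------------------------------------------------------------------------
# Canonical form and the DP
# ---------------------------------------------------------------------------


def _canonical_info(tree: TimeTree):
    """Postorder node list with canonically ordered children.

    Children are sorted by (descendant tip count, total subtree branch
    length, smallest tip label) so that the pairing of children between
    two trees is deterministic and independent of input rotation.
    """
    tip_count: dict[TreeNode, int] = {}
    sub_length: dict[TreeNode, float] = {}
    min_label: dict[TreeNode, str] = {}
    order: dict[TreeNode, list[TreeNode]] = {}
    nodes = list(tree.postorder())
    for node in nodes:
        if node.is_tip:
            tip_count[node] = 1
            sub_length[node] = 0.0
            min_label[node] = node.label or ""
        else:
            if len(node.children) != 2:
                raise KernelError(
                    "kernel requires strictly binary trees; resolve polytomies first"
                )
            tip_count[node] = sum(tip_count[c] for c in node.children)
            sub_length[node] = sum(
                sub_length[c] + (c.length or 0.0) for c in node.children
            )
            min_label[node] = min(min_label[c] for c in node.children)
            order[node] = sorted(
                node.children,
                key=lambda c: (tip_count[c], sub_length[c], min_label[c]),
            )
    return nodes, order


def kernel_score(t1: TimeTree, t2: TimeTree, cfg: KernelConfig | None = None) -> float:
    """Raw (un-normalized) subset-tree kernel score K(T1, T2).

    Symmetric in its arguments; both trees must be strictly binary.
    """
    cfg = cfg or KernelConfig()
    if cfg.normalize_lengths:
        t1 = normalize_branch_lengths(t1)
        t2 = normalize_branch_lengths(t2)
    nodes1, order1 = _canonical_info(t1)
    nodes2, order2 = _canonical_info(t2)

    delta: dict[tuple[int, int], float] = {}
    for n1 in nodes1:  # postorder: children before parents
        for n2 in nodes2:
            if n1.is_tip and n2.is_tip:
                if cfg.labeled:
                    d = 1.0 if n1.label == n2.label else 0.0
                else:
                    d = 1.0
            elif n1.is_tip or n2.is_tip:
                d = 0.0
            else:
                c1 = order1[n1]
                c2 = order2[n2]
                sq = 0.0
                prod = cfg.decay
                for a, b in zip(c1, c2):
                    sq += ((a.length or 0.0) - (b.length or 0.0)) ** 2
                    prod *= cfg.s + delta[(id(a), id(b))]
                d = prod * exp(-sq / (2.0 * cfg.sigma))
            delta[(id(n1), id(n2))] = d
    # fsum: correctly rounded, hence independent of accumulation order,
    # which keeps K(a, b) == K(b, a) exact
    return fsum(delta.values())


def cosine_normalize(k12: float, k11: float, k22: float) -> float:
    """Cosine normalization ``k12 / sqrt(k11 * k22)``; 1 for identical trees."""
    if k11 <= 0 or k22 <= 0:
        raise KernelError("cosine normalization requires positive self-scores")
    return k12 / sqrt(k11 * k22)


def kernel_distance(t1: TimeTree, t2: TimeTree, cfg: KernelConfig | None = None) -> float:
    """``1 - cosine-normalized kernel score``, in [0, 1]."""
    cfg = cfg or KernelConfig()
    k12 = kernel_score(t1, t2, cfg)
    k11 = kernel_score(t1, t1, cfg)
    k22 = kernel_score(t2, t2, cfg)
    d = 1.0 - cosine_normalize(k12, k11, k22)
    return float(min(max(d, 0.0), 1.0))


@dataclass
class KernelMatrix:
    """Pairwise kernel scores for a collection of trees."""

    items: list[str]
    raw: np.ndarray
    normalized: np.ndarray
    config: KernelConfig = field(default_factory=KernelConfig)


def kernel_matrix(
    trees: list[TimeTree],
    cfg: KernelConfig | None = None,
    items: list[str] | None = None,
) -> KernelMatrix:
    """Symmetric raw and cosine-normalized kernel matrices.

    The normalized matrix has unit diagonal and is positive semi-definite
    up to numerical tolerance.
    """
    cfg = cfg or KernelConfig()
    if len(trees) < 2:
        raise KernelError("kernel matrix needs at least 2 trees")
    n = len(trees)
    items = items or [f"tree{i}" for i in range(n)]
    raw = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            raw[i, j] = raw[j, i] = kernel_score(trees[i], trees[j], cfg)
    diag = np.sqrt(np.diag(raw))
    if np.any(diag <= 0):
        raise KernelError("a tree has non-positive self-score; cannot normalize")
    normalized = raw / np.outer(diag, diag)
    np.fill_diagonal(normalized, 1.0)
    return KernelMatrix(items=list(items), raw=raw, normalized=normalized, config=cfg)


def kernel_pca(km: KernelMatrix, n_components: int = 2):
    """Kernel PCA on the cosine-normalized matrix.

    Double-centers the matrix, eigendecomposes it, and returns the
    projection (items x components, each column scaled by the square root
    of its eigenvalue) together with the eigenvalues in decreasing order.
    """
    n = len(km.items)
    if n_components > n:
        raise KernelError("n_components exceeds the number of items")
    K = km.normalized
    H = np.eye(n) - np.ones((n, n)) / n
    Kc = H @ K @ H
    eigval, eigvec = np.linalg.eigh(Kc)
    idx = np.argsort(eigval)[::-1]
    eigval = eigval[idx]
    eigvec = eigvec[:, idx]
    scale = np.sqrt(np.clip(eigval[:n_components], 0.0, None))
    projection = eigvec[:, :n_components] * scale
    return projection, eigval[:n_components]
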