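"""Independent brute-force oracles used to validate the optimized code.

Every function here recomputes a quantity from first principles -- clade
enumeration over label sets, explicit ancestor walks, exhaustive subset /
permutation / fragment enumeration -- avoiding the index-based vectorized
machinery of the package.  They are only feasible on small trees, which is
the point.
"""

from __future__ import annotations

from itertools import combinations, permutations
from math import comb, exp, sqrt

from cophylokit.treecore import TimeTree, TreeNode


# ---------------------------------------------------------------------------
# label-set clade machinery
# ---------------------------------------------------------------------------


def label_clades(tree: TimeTree) -> list[tuple[frozenset, float]]:
    """(label set, branch length) for every non-root branch."""
    out = []

    def walk(node) -> frozenset:
        if node.is_tip:
            mine = frozenset([node.label])
        else:
            mine = frozenset()
            for c in node.children:
                mine |= walk(c)
        if node.parent is not None:
            out.append((mine, float(node.length or 0.0)))
        return mine

    walk(tree.root)
    return out


def nontrivial_clades(tree: TimeTree) -> set[frozenset]:
    n = tree.n_tips
    return {c for c, _ in label_clades(tree) if 1 < len(c) < n}


def split_lengths(tree: TimeTree) -> dict[frozenset, float]:
    """Unrooted splits keyed by the side not containing the smallest label."""
    all_labels = frozenset(tree.tip_labels())
    anchor = min(all_labels)
    out: dict[frozenset, float] = {}
    for clade, length in label_clades(tree):
        if len(clade) in (0, len(all_labels)):
            continue
        side = clade if anchor not in clade else all_labels - clade
        out[side] = out.get(side, 0.0) + length
    return out


def rf_oracle(t1, t2, normalized=True) -> float:
    c1, c2 = nontrivial_clades(t1), nontrivial_clades(t2)
    sym = len(c1 ^ c2)
    if not normalized:
        return float(sym)
    denom = len(c1) + len(c2)
    return sym / denom if denom else 0.0


def nph85_oracle(t1, t2) -> float:
    n = t1.n_tips

    def nts(tree):
        return {s for s in split_lengths(tree) if 1 < len(s) < n - 1}

    denom = 2 * (n - 3)
    sym = len(nts(t1) ^ nts(t2))
    return sym / denom if denom > 0 else 0.0


def kf_oracle(t1, t2) -> float:
    s1, s2 = split_lengths(t1), split_lengths(t2)
    total = 0.0
    for split in set(s1) | set(s2):
        total += (s1.get(split, 0.0) - s2.get(split, 0.0)) ** 2
    return sqrt(total)


def sim_oracle(t1, t2) -> float:
    def frac(a, b):
        bc = {c for c, _ in label_clades(b)}
        tot = sum(l for _, l in label_clades(a))
        num = sum(l for c, l in label_clades(a) if c in bc)
        return num / tot

    return 1.0 - 0.5 * (frac(t1, t2) + frac(t2, t1))


# ---------------------------------------------------------------------------
# explicit path walks
# ---------------------------------------------------------------------------


def _ancestors(node):
    path = [node]
    while path[-1].parent is not None:
        path.append(path[-1].parent)
    return path


def tip_path(tree: TimeTree, a: str, b: str, weighted: bool) -> float:
    """Path length between two tips by explicit ancestor-walk LCA."""
    tips = {t.label: t for t in tree.tips()}
    pa, pb = _ancestors(tips[a]), _ancestors(tips[b])
    seen = {id(n): i for i, n in enumerate(pa)}
    for j, n in enumerate(pb):
        if id(n) in seen:
            i = seen[id(n)]
            if weighted:
                return sum(float(x.length or 0.0) for x in pa[:i]) + sum(
                    float(x.length or 0.0) for x in pb[:j]
                )
            return i + j
    raise AssertionError("no common ancestor")


def mrca_depth(tree: TimeTree, labels, weighted: bool) -> float:
    """Root-to-MRCA depth by the smallest label-clade containing the set."""
    want = frozenset(labels)
    depth = {}

    def walk(node, d_top, d_len):
        depth_key = d_len if weighted else d_top
        mine = frozenset([node.label]) if node.is_tip else frozenset()
        for c in node.children:
            mine |= walk(c, d_top + 1, d_len + float(c.length or 0.0))
        if want <= mine and node not in depth:
            depth[node] = depth_key
        return mine

    walk(tree.root, 0, 0.0)
    # the MRCA is the deepest node whose clade contains the set
    return max(depth.values())


def pathdist_oracle(t1, t2, weighted=False) -> float:
    labels = sorted(t1.tip_labels())
    total = 0.0
    for a, b in combinations(labels, 2):
        total += (tip_path(t1, a, b, weighted) - tip_path(t2, a, b, weighted)) ** 2
    return sqrt(total)


def node_oracle(t1, t2) -> float:
    labels = sorted(t1.tip_labels())
    return float(
        sum(
            abs(tip_path(t1, a, b, False) - tip_path(t2, a, b, False))
            for a, b in combinations(labels, 2)
        )
    )


def kc_oracle(t1, t2, lambda_mix: float) -> float:
    labels = sorted(t1.tip_labels())

    def vec(tree):
        tips = {t.label: t for t in tree.tips()}
        entries = []
        for a, b in combinations(labels, 2):
            topo = mrca_depth(tree, (a, b), weighted=False)
            leng = mrca_depth(tree, (a, b), weighted=True)
            entries.append((1 - lambda_mix) * topo + lambda_mix * leng)
        for a in labels:
            entries.append(
                (1 - lambda_mix) * 1.0 + lambda_mix * float(tips[a].length or 0.0)
            )
        return entries

    v1, v2 = vec(t1), vec(t2)
    return sqrt(sum((x - y) ** 2 for x, y in zip(v1, v2)))


# ---------------------------------------------------------------------------
# agreement measures
# ---------------------------------------------------------------------------


def restricted_clade_set(tree: TimeTree, subset: frozenset) -> frozenset:
    """Clade sets of the tree restricted to a tip subset (topology id)."""
    out = set()
    for clade, _ in label_clades(tree):
        cut = clade & subset
        if cut:
            out.add(cut)
    out.add(subset)
    return frozenset(out)


def mast_oracle(t1, t2, normalized=False) -> float:
    """Exhaustive maximum agreement subtree over all tip subsets."""
    labels = sorted(t1.tip_labels())
    n = len(labels)
    best = 1
    for k in range(n, 1, -1):
        if k <= best:
            break
        for subset in combinations(labels, k):
            s = frozenset(subset)
            if restricted_clade_set(t1, s) == restricted_clade_set(t2, s):
                best = k
                break
    dist = n - best
    return dist / n if normalized else float(dist)


def triplet_topology(tree: TimeTree, a, b, c):
    """Cherry pair of the rooted triplet, via smallest containing clades."""
    for pair, other in (((a, b), c), ((a, c), b), ((b, c), a)):
        # the pair is a cherry iff some clade contains the pair but not the third
        if any(
            set(pair) <= clade and other not in clade for clade, _ in label_clades(tree)
        ):
            return frozenset(pair)
    return None  # unresolved


def triplet_internal_length(tree: TimeTree, a, b, c) -> float:
    cherry = triplet_topology(tree, a, b, c)
    if cherry is None:
        return 0.0
    return mrca_depth(tree, cherry, weighted=True) - mrca_depth(
        tree, (a, b, c), weighted=True
    )


def trip_oracle(t1, t2, weighted=False) -> float:
    labels = sorted(t1.tip_labels())
    n = len(labels)
    total = 0.0
    for a, b, c in combinations(labels, 3):
        top1, top2 = triplet_topology(t1, a, b, c), triplet_topology(t2, a, b, c)
        if weighted:
            d1 = triplet_internal_length(t1, a, b, c)
            d2 = triplet_internal_length(t2, a, b, c)
            total += abs(d1 - d2) if top1 == top2 else d1 + d2
        elif top1 != top2:
            total += 1.0
    return total / comb(n, 3)


def align_oracle(t1, t2) -> float:
    """Exhaustive assignment over all one-to-one branch matchings."""
    full = frozenset(t1.tip_labels())
    e1 = [(c, full - c) for c, _ in label_clades(t1)]
    e2 = [(c, full - c) for c, _ in label_clades(t2)]

    def jac(a, b):
        u = len(a | b)
        return len(a & b) / u if u else 1.0

    def score(x, y):
        (a1, b1), (a2, b2) = x, y
        return max(min(jac(a1, a2), jac(b1, b2)), min(jac(a1, b2), jac(b1, a2)))

    if len(e1) > len(e2):
        e1, e2 = e2, e1
    extra = len(e2) - len(e1)
    best = None
    for perm in permutations(range(len(e2)), len(e1)):
        cost = sum(1.0 - score(e1[i], e2[j]) for i, j in enumerate(perm)) + extra
        if best is None or cost < best:
            best = cost
    return best


# ---------------------------------------------------------------------------
# subset-tree kernel by explicit fragment enumeration
# ---------------------------------------------------------------------------

_STOP = "STOP"


def _canonical_children(node):
    def tip_count(n):
        return 1 if n.is_tip else sum(tip_count(c) for c in n.children)

    def sub_len(n):
        return 0.0 if n.is_tip else sum(
            sub_len(c) + float(c.length or 0.0) for c in n.children
        )

    def min_label(n):
        return (n.label or "") if n.is_tip else min(min_label(c) for c in n.children)

    return sorted(node.children, key=lambda c: (tip_count(c), sub_len(c), min_label(c)))


def enumerate_fragments(node):
    """All subset-tree fragments rooted at ``node`` (canonical child order)."""
    if node.is_tip:
        return [("T", node.label)]
    kids = _canonical_children(node)
    lengths = tuple(float(c.length or 0.0) for c in kids)
    child_options = [[_STOP] + enumerate_fragments(c) for c in kids]
    frags = []
    for left in child_options[0]:
        for right in child_options[1]:
            frags.append(("I", lengths, (left, right)))
    return frags


def fragment_match_weight(f1, f2, cfg) -> float:
    if f1 == _STOP or f2 == _STOP:
        raise AssertionError("stops are handled at the parent")
    if f1[0] == "T" and f2[0] == "T":
        if cfg.labeled:
            return 1.0 if f1[1] == f2[1] else 0.0
        return 1.0
    if f1[0] != f2[0]:
        return 0.0
    (_, l1, subs1), (_, l2, subs2) = f1, f2
    sq = sum((a - b) ** 2 for a, b in zip(l1, l2))
    w = cfg.decay * exp(-sq / (2.0 * cfg.sigma))
    for s1, s2 in zip(subs1, subs2):
        if s1 == _STOP and s2 == _STOP:
            w *= cfg.s
        elif s1 == _STOP or s2 == _STOP:
            return 0.0
        else:
            w *= fragment_match_weight(s1, s2, cfg)
            if w == 0.0:
                return 0.0
    return w


def kernel_oracle(t1: TimeTree, t2: TimeTree, cfg) -> float:
    """K(T1,T2) as a sum over all pairs of explicitly enumerated fragments."""
    from cophylokit.treecore import normalize_branch_lengths

    if cfg.normalize_lengths:
        t1 = normalize_branch_lengths(t1)
        t2 = normalize_branch_lengths(t2)
    nodes1 = list(t1.preorder())
    nodes2 = list(t2.preorder())
    total = 0.0
    for n1 in nodes1:
        f1s = enumerate_fragments(n1)
        for n2 in nodes2:
            for f1 in f1s:
                for f2 in enumerate_fragments(n2):
                    total += fragment_match_weight(f1, f2, cfg)
    return total


# ---------------------------------------------------------------------------
# exhaustive rooted binary topologies
# ---------------------------------------------------------------------------


def enumerate_topologies(labels, lengths=None):
    """All rooted binary labeled topologies on ``labels`` ((2n-3)!! trees).

    Branch lengths default to 1; pass a callable ``lengths(rng_state)`` or
    set them afterwards.
    """
    labels = list(labels)

    def build(labs):
        if len(labs) == 1:
            return [TreeNode(label=labs[0], length=1.0)]
        out = []
        first, rest = labs[0], labs[1:]
        for k in range(1, len(labs)):
            for left_set in combinations(rest, k - 1):
                left = [first, *left_set]
                right = [l for l in labs if l not in left]
                for lt in build(left):
                    for rt in build(right):
                        node = TreeNode(length=1.0)
                        node.add_child(lt)
                        node.add_child(rt)
                        out.append(node)
        return out

    trees = []
    for root in build(labels):
        root.length = None
        trees.append(TimeTree(root))
    return trees
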