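"""Tree data model, Newick I/O and tree surgery.

The central container is :class:`TimeTree`, a rooted tree whose branch
lengths are interpreted as real time (Ma) for host trees and as arbitrary
time/divergence units for pathogen trees.  Node *heights* are measured from
the most recent tip (height 0); tips need not be contemporaneous, so a tip
can itself sit at a positive height (serial sampling).

Two Newick dialects are supported.  The standard dialect contains only
bifurcating (or multifurcating) internal nodes.  The annotated dialect
additionally preserves *unary* nodes -- internal nodes with a single child
-- which the simulator uses to record host-switch events on a branch; unary
nodes are written as ordinary internal nodes with a label (e.g. ``HS``).

Parsing is delegated to dendropy; serialization is a small recursive writer
so that the unary dialect round-trips exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import dendropy
import numpy as np
import pandas as pd

from .errors import (
    AssociationError,
    NewickParseError,
    NormalizationError,
    TreeValidationError,
)

__all__ = [
    "TreeNode",
    "TimeTree",
    "AssociationTable",
    "parse_newick",
    "write_newick",
    "collapse_unary",
    "normalize_branch_lengths",
    "graft_zero_branches",
    "midpoint_root",
    "collapse_tips_by_group",
    "resolve_polytomies",
]


class TreeNode:
    """A node in a rooted tree.

    Attributes
    ----------
    children : list[TreeNode]
    parent : TreeNode or None
    length : float or None
        Length of the branch subtending this node.  ``None`` only on the
        root (a root edge length present in the input is preserved).
    label : str or None
        Tip label, or an optional internal-node label (event annotation).
    event : str or None
        Free-form event tag set by the simulator (``host_switch``,
        ``duplication``, ``cospeciation``); not serialized except through
        the label.
    """

    __slots__ = ("children", "parent", "length", "label", "event")

    def __init__(self, label=None, length=None, event=None):
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self.length = length
        self.label = label
        self.event = event

    @property
    def is_tip(self) -> bool:
        return not self.children

    @property
    def is_unary(self) -> bool:
        return len(self.children) == 1

    def add_child(self, node: "TreeNode") -> "TreeNode":
        node.parent = self
        self.children.append(node)
        return node

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["TreeNode"]:
        out = list(self.preorder())
        return reversed(out)

    def __repr__(self):  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else f"internal({len(self.children)})"
        return f"<TreeNode {self.label!r} {kind} len={self.length}>"


class TimeTree:
    """A rooted phylogeny with branch lengths in units of time."""

    def __init__(self, root: TreeNode):
        self.root = root

    # -- traversal ----------------------------------------------------------

    def preorder(self) -> Iterator[TreeNode]:
        return self.root.preorder()

    def postorder(self) -> Iterator[TreeNode]:
        return self.root.postorder()

    def tips(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_tip]

    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def branches(self) -> list[TreeNode]:
        """All non-root nodes (each node identifies its subtending branch)."""
        return [n for n in self.preorder() if n is not self.root]

    def total_branch_length(self) -> float:
        return float(sum(n.length or 0.0 for n in self.branches()))

    # -- geometry -----------------------------------------------------------

    def depths(self) -> dict[TreeNode, float]:
        """Distance from the root to each node (root edge length ignored)."""
        out = {self.root: 0.0}
        for node in self.preorder():
            if node is self.root:
                continue
            out[node] = out[node.parent] + (node.length or 0.0)
        return out

    def heights(self) -> dict[TreeNode, float]:
        """Distance of each node above the most recent tip (height 0).

        Computed from the maximum root-to-tip depth, so serially sampled
        tips receive positive heights.
        """
        depths = self.depths()
        maxdepth = max(depths[t] for t in self.tips()) if self.tips() else 0.0
        return {n: maxdepth - d for n, d in depths.items()}

    def root_height(self) -> float:
        return self.heights()[self.root]

    # -- utilities ----------------------------------------------------------

    def copy(self) -> "TimeTree":
        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(label=node.label, length=node.length, event=node.event)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return TimeTree(clone(self.root))

    def mrca(self, labels: Iterable[str]) -> TreeNode:
        wanted = set(labels)
        marks: dict[TreeNode, set] = {}
        for node in self.postorder():
            if node.is_tip:
                marks[node] = {node.label} & wanted
            else:
                marks[node] = set().union(*(marks[c] for c in node.children))
            if marks[node] == wanted:
                return node
        raise TreeValidationError(f"tips {sorted(wanted)} not all present")

    def validate(self, require_unique_labels: bool = True) -> None:
        seen = set()
        for node in self.preorder():
            if node is not self.root:
                if node.parent is None:
                    raise TreeValidationError("non-root node without parent")
                if node.length is not None and node.length < 0:
                    raise TreeValidationError(
                        f"negative branch length {node.length} at {node.label!r}"
                    )
            if node.is_tip:
                if not node.label:
                    raise TreeValidationError("tip without label")
                if require_unique_labels:
                    if node.label in seen:
                        raise TreeValidationError(f"duplicate tip label {node.label!r}")
                    seen.add(node.label)

    def __str__(self) -> str:
        return write_newick(self)


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def _from_dendropy(dnode) -> TreeNode:
    label = None
    if dnode.taxon is not None:
        label = dnode.taxon.label
    elif dnode.label is not None:
        label = dnode.label
    node = TreeNode(label=label, length=dnode.edge.length)
    for child in dnode.child_nodes():
        node.add_child(_from_dendropy(child))
    return node


def parse_newick(text: str, allow_unary: bool = False) -> TimeTree:
    """Parse a Newick string into a :class:`TimeTree`.

    Parameters
    ----------
    text : str
        A single rooted Newick tree.
    allow_unary : bool
        Preserve internal nodes with a single child (the annotated
        dialect).  When False, unary nodes are collapsed on read.

    Raises
    ------
    NewickParseError
        On malformed input, with an approximate position when available.
    TreeValidationError
        On negative branch lengths.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several tokenizer error types
        position = getattr(exc, "col_num", None)
        raise NewickParseError(str(exc), position=position) from exc
    tree = TimeTree(_from_dendropy(dtree.seed_node))
    for node in tree.branches():
        if node.length is not None and node.length < 0:
            raise TreeValidationError(f"negative branch length {node.length}")
        if node.length is None:
            node.length = 0.0
    if not allow_unary:
        tree = collapse_unary(tree)
    tree.validate(require_unique_labels=False)
    return tree


def _format_length(x: float) -> str:
    return format(float(x), ".12g")


def write_newick(tree: TimeTree, keep_unary: bool = True) -> str:
    """Serialize a :class:`TimeTree` to Newick.

    With ``keep_unary=False`` unary nodes are collapsed first (their branch
    lengths folded into the child branch), reproducing the plain dialect.
    """
    if not keep_unary:
        tree = collapse_unary(tree)

    def render(node: TreeNode) -> str:
        if node.is_tip:
            body = node.label or ""
        else:
            inner = ",".join(render(c) for c in node.children)
            body = f"({inner})" + (node.label or "")
        if node.length is not None:
            body += ":" + _format_length(node.length)
        return body

    return render(tree.root) + ";"


# ---------------------------------------------------------------------------
# Tree surgery
# ---------------------------------------------------------------------------


def collapse_unary(tree: TimeTree) -> TimeTree:
    """Remove all unary (single-child) nodes, summing branch lengths.

    Tip-to-tip path lengths are preserved exactly: each removed node's
    branch length is added to its child's branch.  A unary root is removed
    by promoting its child to the root.
    """
    out = tree.copy()
    root = out.root
    while root.is_unary:
        child = root.children[0]
        if root.length is not None:
            child.length = (child.length or 0.0) + root.length
        child.parent = None
        root = child
    for node in list(root.preorder()):
        i = 0
        while i < len(node.children):
            child = node.children[i]
            if child.is_unary:
                grand = child.children[0]
                grand.length = (grand.length or 0.0) + (child.length or 0.0)
                grand.parent = node
                node.children[i] = grand
                child.children = []  # detach the spliced-out node
            else:
                i += 1
    return TimeTree(root)


def normalize_branch_lengths(tree: TimeTree) -> TimeTree:
    """Divide every branch length by the tree's mean branch length.

    The mean is taken over all non-root branches; the result has mean
    branch length exactly 1.  Useful when host branches are in Ma while
    pathogen branches are in substitutions/site.
    """
    out = tree.copy()
    lengths = [n.length or 0.0 for n in out.branches()]
    mean = float(np.mean(lengths)) if lengths else 0.0
    if mean <= 0.0:
        raise NormalizationError("cannot normalize: mean branch length is zero")
    for node in out.branches():
        node.length = (node.length or 0.0) / mean
    return out


@dataclass
class AssociationTable:
    """Host-pathogen associations; many-to-many rows of labels."""

    rows: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for host, pathogen in self.rows:
            if not host or not pathogen:
                raise AssociationError("association labels must be non-empty")
            if (host, pathogen) in seen:
                raise AssociationError(f"duplicate association {(host, pathogen)!r}")
            seen.add((host, pathogen))

    @classmethod
    def from_csv(cls, path_or_buffer, sep=None) -> "AssociationTable":
        df = pd.read_csv(path_or_buffer, sep=sep, engine="python")
        cols = {c.lower(): c for c in df.columns}
        if "host" not in cols or "pathogen" not in cols:
            raise AssociationError("association table needs 'host' and 'pathogen' columns")
        rows = [
            (str(h), str(p))
            for h, p in zip(df[cols["host"]], df[cols["pathogen"]])
        ]
        return cls(rows)

    def hosts_of(self, pathogen: str) -> list[str]:
        return sorted(h for h, p in self.rows if p == pathogen)

    def pathogens_of(self, host: str) -> list[str]:
        return sorted(p for h, p in self.rows if h == host)

    def host_labels(self) -> set[str]:
        return {h for h, _ in self.rows}

    def pathogen_labels(self) -> set[str]:
        return {p for _, p in self.rows}


def graft_zero_branches(
    host: TimeTree, pathogen: TimeTree, assoc: AssociationTable
) -> tuple[TimeTree, TimeTree]:
    """Enforce a one-to-one tip map between host and pathogen trees.

    Tips with multiple associations are replaced by polytomies of
    zero-length child tips, one per association row, so that both output
    trees carry one tip per association row with identical label sets.
    Labels are the host label when a host appears in a single row, and
    ``host|pathogen`` otherwise (to keep tip labels unique).  Total branch
    length is unchanged in each tree.
    """
    if not assoc.rows:
        raise AssociationError("empty association table")
    host_tips = {t.label for t in host.tips()}
    path_tips = {t.label for t in pathogen.tips()}
    for h, p in assoc.rows:
        if h not in host_tips:
            raise KeyError(f"association references unknown host tip {h!r}")
        if p not in path_tips:
            raise KeyError(f"association references unknown pathogen tip {p!r}")

    host_count = {h: len(assoc.pathogens_of(h)) for h in assoc.host_labels()}

    def row_label(h: str, p: str) -> str:
        return h if host_count[h] == 1 else f"{h}|{p}"

    def expand(tree: TimeTree, is_host: bool) -> TimeTree:
        out = tree.copy()
        for tip in list(out.tips()):
            if is_host:
                partners = assoc.pathogens_of(tip.label)
                if not partners:
                    raise KeyError(f"host tip {tip.label!r} has no association")
                labels = [row_label(tip.label, p) for p in partners]
            else:
                partners = assoc.hosts_of(tip.label)
                if not partners:
                    raise KeyError(f"pathogen tip {tip.label!r} has no association")
                labels = sorted(row_label(h, tip.label) for h in partners)
            if len(labels) == 1:
                tip.label = labels[0]
            else:
                tip.label = None
                for lab in labels:
                    tip.add_child(TreeNode(label=lab, length=0.0))
        return out

    return expand(host, is_host=True), expand(pathogen, is_host=False)


def midpoint_root(tree: TimeTree) -> TimeTree:
    """Re-root at the midpoint of the longest tip-to-tip path.

    Delegates to dendropy's midpoint rooting; unrooted pairwise path
    lengths are preserved.
    """
    if tree.n_tips < 2:
        raise TreeValidationError("midpoint rooting needs at least 2 tips")
    dtree = dendropy.Tree.get(
        data=write_newick(tree),
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    dtree.reroot_at_midpoint(update_bipartitions=False)
    out = TimeTree(_from_dendropy(dtree.seed_node))
    for node in out.branches():
        if node.length is None:
            node.length = 0.0
    return out


def collapse_tips_by_group(tree: TimeTree, mapping: dict[str, str]) -> TimeTree:
    """Collapse tips mapping to the same group into one terminal branch.

    For each group with more than one tip, the most recent common ancestor
    of those tips is replaced by a single tip labeled by the group (keeping
    the MRCA's subtending branch).  Groups with one tip are relabeled.
    """
    out = tree.copy()
    for tip in out.tips():
        if tip.label not in mapping:
            raise KeyError(f"tip {tip.label!r} not covered by the group mapping")
    groups: dict[str, list[str]] = {}
    for tip in out.tips():
        groups.setdefault(mapping[tip.label], []).append(tip.label)
    for group in sorted(groups):
        labels = [l for l in groups[group] if l in set(out.tip_labels())]
        if not labels:
            continue
        if len(labels) == 1:
            for tip in out.tips():
                if tip.label == labels[0]:
                    tip.label = group
            continue
        node = out.mrca(labels)
        node.children = []
        node.label = group
    return out


def resolve_polytomies(tree: TimeTree, seed: int = 0) -> TimeTree:
    """Arbitrarily resolve polytomies with zero-length internal branches.

    Child order is shuffled with a seeded generator, then siblings are
    joined pairwise left-to-right; deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    out = tree.copy()
    for node in list(out.postorder()):
        while len(node.children) > 2:
            order = rng.permutation(len(node.children))
            a = node.children[order[0]]
            b = node.children[order[1]]
            joint = TreeNode(length=0.0)
            node.children = [c for c in node.children if c is not a and c is not b]
            joint.add_child(a)
            joint.add_child(b)
            node.add_child(joint)
    return out
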