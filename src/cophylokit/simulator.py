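"""Reverse-time Gillespie simulation of a pathogen tree inside a host tree.

The model runs backwards in time from the sampled host tips (t = 0) toward
the host root.  Each sampled host tip starts with exactly one pathogen
lineage.  Three processes shape the pathogen tree:

* **within-host speciation / duplication** (rate ``Lambda`` per lineage
  pair per Ma): two pathogen lineages in the same host coalesce;
* **host switching / migration** (rate ``M`` per lineage per Ma): one
  pathogen lineage is reassigned to a different extant host, recorded as a
  unary node on its branch;
* **cospeciation** (probability ``P`` per host node): when two host
  lineages merge at an internal host node, one pathogen lineage from each
  side coalesces with probability P, exactly at the host node's height.

Host speciation events are deterministic, read off the input host tree.
While more than one host lineage is extant the total stochastic rate is

    lambda = sum_i C(n_pi, 2) * Lambda  +  n_p * M,

and the host-switch rate is zero whenever a single host lineage is extant.
After the host root is reached, remaining lineages coalesce at constant
rate ``C(n_p, 2) * Lambda`` until a single lineage (the pathogen root)
remains.

Two outputs are produced per run: an *annotated* tree whose unary nodes
mark host switches, and a *collapsed* strictly binary tree (unary nodes
removed) whose tips are labeled by host.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np

from .errors import (
    NonTerminatingConfigurationError,
    SimulationError,
    TreeValidationError,
)
from .treecore import TimeTree, TreeNode, collapse_unary

__all__ = [
    "SimParams",
    "SimState",
    "SimResult",
    "Event",
    "total_rate",
    "draw_waiting_time",
    "apply_host_tip",
    "apply_host_node",
    "apply_host_switch",
    "apply_duplication",
    "simulate",
]

_HEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class SimParams:
    """Coevolution parameters.

    Lambda : within-host pathogen speciation (duplication) rate, per
        lineage pair per Ma.
    M : host-switch (migration) rate, per pathogen lineage per Ma.
    P : cospeciation probability per host node, in [0, 1].
    seed : seed for the single generator driving all randomness of a run.
    """

    Lambda: float
    M: float
    P: float
    seed: int | None = None

    def __post_init__(self):
        if self.Lambda < 0:
            raise ValueError("Lambda must be >= 0")
        if self.M < 0:
            raise ValueError("M must be >= 0")
        if not 0.0 <= self.P <= 1.0:
            raise ValueError("P must be in [0, 1]")


@dataclass(frozen=True)
class Event:
    """One entry of the simulation event log."""

    time: float
    type: str  # duplication | host_switch | cospeciation | host_tip | host_node | root_coalescence
    lineages: tuple[int, ...]
    host_from: str | None = None
    host_to: str | None = None


@dataclass
class _Lineage:
    id: int
    host: int  # index into the host-node table
    node: TreeNode  # subtree built so far for this lineage
    node_time: float  # height of `node` (branch grows from here back in time)


class SimState:
    """Mutable bookkeeping of the reverse-time simulation.

    ``extant_hosts`` maps a host-node index to the set of pathogen lineage
    ids it currently carries; ``pending`` holds host tips/internal nodes
    not yet reached, ordered by height.
    """

    def __init__(self, host: TimeTree):
        for node in host.preorder():
            if not node.is_tip and len(node.children) != 2:
                raise TreeValidationError(
                    "simulate requires a strictly binary host tree"
                )
        if host.n_tips < 2:
            raise TreeValidationError("host tree must have at least 2 tips")
        host.validate()

        self.host = host
        self.nodes: list[TreeNode] = list(host.preorder())
        self.index: dict[TreeNode, int] = {n: i for i, n in enumerate(self.nodes)}
        heights = host.heights()
        self.height: list[float] = [heights[n] for n in self.nodes]
        scale = max(heights.values()) or 1.0

        self.t: float = 0.0
        self.extant_hosts: dict[int, set[int]] = {}
        self.lineages: dict[int, _Lineage] = {}
        self.events: list[Event] = []
        self._next_id = 0

        # host events in the order they will be reached going back in time
        entries = []
        for i, node in enumerate(self.nodes):
            if node.is_tip and self.height[i] <= _HEIGHT_TOL * scale:
                continue  # contemporaneous tips initialize the state at t=0
            entries.append((self.height[i], i))
        self.pending: list[tuple[float, int]] = sorted(entries)
        self._pending_pos = 0

        for i, node in enumerate(self.nodes):
            if node.is_tip and self.height[i] <= _HEIGHT_TOL * scale:
                apply_host_tip(self, i)

    # -- derived counts -----------------------------------------------------

    @property
    def nh(self) -> int:
        return len(self.extant_hosts)

    @property
    def np_total(self) -> int:
        return len(self.lineages)

    def npi(self) -> dict[int, int]:
        return {h: len(s) for h, s in self.extant_hosts.items()}

    def next_host_event(self) -> tuple[float, int] | None:
        if self._pending_pos >= len(self.pending):
            return None
        return self.pending[self._pending_pos]

    def host_label(self, i: int) -> str:
        return self.nodes[i].label or f"host_node_{i}"

    # -- internals ----------------------------------------------------------

    def _new_lineage(self, host_idx: int, node: TreeNode, node_time: float) -> _Lineage:
        lin = _Lineage(self._next_id, host_idx, node, node_time)
        self._next_id += 1
        self.lineages[lin.id] = lin
        self.extant_hosts.setdefault(host_idx, set()).add(lin.id)
        return lin

    def _coalesce(self, a: int, b: int, host_idx: int, etype: str) -> _Lineage:
        la, lb = self.lineages.pop(a), self.lineages.pop(b)
        for lin in (la, lb):
            self.extant_hosts[lin.host].discard(lin.id)
        parent = TreeNode(event=etype)
        for lin in (la, lb):
            lin.node.length = self.t - lin.node_time
            parent.add_child(lin.node)
        new = self._new_lineage(host_idx, parent, self.t)
        self.events.append(
            Event(self.t, etype, (a, b), host_from=self.host_label(host_idx))
        )
        return new


# ---------------------------------------------------------------------------
# Elementary transitions
# ---------------------------------------------------------------------------


def total_rate(state: SimState, params: SimParams) -> tuple[float, float, float]:
    """Total stochastic event rate and its components ``(lam, lamP, lamM)``.

    Returns all-zero when a single host lineage is extant; the root-phase
    coalescent (which still runs at rate ``C(n_p,2)*Lambda``) is handled
    separately by :func:`simulate`.
    """
    if state.nh <= 1:
        return 0.0, 0.0, 0.0
    lam_p = params.Lambda * sum(comb(len(s), 2) for s in state.extant_hosts.values())
    lam_m = params.M * state.np_total
    return lam_p + lam_m, lam_p, lam_m


def draw_waiting_time(rate: float, rng: np.random.Generator) -> float:
    """Exponential waiting time with mean ``1/rate``."""
    if rate <= 0:
        raise SimulationError("waiting time requires a positive rate")
    return float(rng.exponential(1.0 / rate))


def apply_host_tip(state: SimState, tip_idx: int) -> SimState:
    """Activate a sampled host tip: one new pathogen lineage, labeled by host."""
    node = state.nodes[tip_idx]
    if not node.is_tip:
        raise SimulationError("apply_host_tip called on an internal host node")
    if tip_idx in state.extant_hosts:
        raise SimulationError(f"host tip {node.label!r} already sampled")
    tip = TreeNode(label=node.label)
    lin = state._new_lineage(tip_idx, tip, state.t)
    state.events.append(
        Event(state.t, "host_tip", (lin.id,), host_from=node.label)
    )
    return state


def apply_host_node(
    state: SimState, node_idx: int, P: float, rng: np.random.Generator
) -> SimState:
    """Merge the two derived host lineages at an internal host node.

    All pathogen lineages are transferred to the ancestral host lineage;
    with probability P -- and only when both derived hosts carry at least
    one lineage -- one uniformly chosen lineage from each side coalesces
    exactly at the host node's height.  A single coalescence attempt is
    made per host node.
    """
    node = state.nodes[node_idx]
    if node.is_tip:
        raise SimulationError("apply_host_node called on a host tip")
    child_idx = [state.index[c] for c in node.children]
    for ci in child_idx:
        if ci not in state.extant_hosts:
            raise SimulationError("derived host lineage not extant (already processed?)")
    if node_idx in state.extant_hosts:
        raise SimulationError("host node already processed")

    left = sorted(state.extant_hosts[child_idx[0]])
    right = sorted(state.extant_hosts[child_idx[1]])
    cospeciate = (rng.random() < P) and left and right
    pair = None
    if cospeciate:
        pair = (
            left[int(rng.integers(len(left)))],
            right[int(rng.integers(len(right)))],
        )

    moved = [state.lineages[i] for ci in child_idx for i in sorted(state.extant_hosts[ci])]
    for ci in child_idx:
        del state.extant_hosts[ci]
    state.extant_hosts[node_idx] = set()
    for lin in moved:
        lin.host = node_idx
        state.extant_hosts[node_idx].add(lin.id)
    state.events.append(Event(state.t, "host_node", (), host_from=node.label))
    if pair is not None:
        state._coalesce(pair[0], pair[1], node_idx, "cospeciation")
    return state


def apply_host_switch(state: SimState, rng: np.random.Generator) -> SimState:
    """Reassign one uniformly chosen lineage to a different extant host.

    Records a unary node at the current time on the lineage's branch in the
    annotated tree; lineage counts are unchanged.
    """
    if state.nh < 2:
        raise SimulationError("host switch requires >= 2 extant host lineages")
    ids = sorted(state.lineages)
    lin = state.lineages[ids[int(rng.integers(len(ids)))]]
    others = sorted(h for h in state.extant_hosts if h != lin.host)
    dest = others[int(rng.integers(len(others)))]

    lin.node.length = state.t - lin.node_time
    marker = TreeNode(label="HS", event="host_switch")
    marker.add_child(lin.node)
    lin.node = marker
    lin.node_time = state.t

    state.extant_hosts[lin.host].discard(lin.id)
    state.extant_hosts[dest].add(lin.id)
    state.events.append(
        Event(
            state.t,
            "host_switch",
            (lin.id,),
            host_from=state.host_label(lin.host),
            host_to=state.host_label(dest),
        )
    )
    lin.host = dest
    return state


def apply_duplication(
    state: SimState, rng: np.random.Generator, etype: str = "duplication"
) -> SimState:
    """Coalesce a uniformly chosen within-host pair of pathogen lineages.

    The host is selected with probability proportional to ``C(n_pi, 2)``,
    i.e. the pair is uniform over all within-host pairs.
    """
    weighted = [
        (h, comb(len(s), 2)) for h, s in sorted(state.extant_hosts.items()) if len(s) >= 2
    ]
    total = sum(w for _, w in weighted)
    if total == 0:
        raise SimulationError("no within-host pair available for duplication")
    pick = int(rng.integers(total))
    for host_idx, w in weighted:
        if pick < w:
            break
        pick -= w
    members = sorted(state.extant_hosts[host_idx])
    i, j = rng.choice(len(members), size=2, replace=False)
    state._coalesce(members[int(i)], members[int(j)], host_idx, etype)
    return state


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


@dataclass
class SimResult:
    """Output of one simulation run."""

    annotated_tree: TimeTree  # unary nodes mark host switches
    collapsed_tree: TimeTree  # strictly binary, tips labeled by host
    events: list[Event] = field(default_factory=list)
    params: SimParams | None = None

    def n_host_switches(self) -> int:
        return sum(1 for e in self.events if e.type == "host_switch")


def simulate(host: TimeTree, params: SimParams) -> SimResult:
    """Simulate one pathogen tree along ``host`` under ``params``.

    Random draws are made in a fixed order (waiting time, event type,
    lineage choice(s), destination host) from a single generator seeded
    with ``params.seed``, so runs are byte-reproducible.

    Raises
    ------
    NonTerminatingConfigurationError
        If the root phase is reached with more than one pathogen lineage
        and ``Lambda == 0`` (the coalescent clock would never ring).
    """
    rng = np.random.default_rng(params.seed)
    state = SimState(host)

    while True:
        nxt = state.next_host_event()
        if nxt is None:
            break
        next_time, next_idx = nxt
        lam, lam_p, lam_m = total_rate(state, params)
        if lam <= 0.0:
            state.t = next_time
            _apply_pending(state, next_idx, params, rng)
            continue
        dt = draw_waiting_time(lam, rng)
        if state.t + dt > next_time:
            # overshoot: discard the draw (memoryless) and take the host event
            state.t = next_time
            _apply_pending(state, next_idx, params, rng)
            continue
        state.t += dt
        if rng.random() < lam_m / lam:
            apply_host_switch(state, rng)
        else:
            apply_duplication(state, rng)

    # root phase: constant-rate coalescent among the surviving lineages
    while state.np_total > 1:
        if params.Lambda <= 0.0:
            raise NonTerminatingConfigurationError(
                f"{state.np_total} lineages at the host root with Lambda = 0"
            )
        rate = params.Lambda * comb(state.np_total, 2)
        state.t += draw_waiting_time(rate, rng)
        apply_duplication(state, rng, etype="root_coalescence")

    (last,) = state.lineages.values()
    root = last.node
    root.length = None
    annotated = TimeTree(root)
    collapsed = collapse_unary(annotated)
    return SimResult(annotated, collapsed, state.events, params)


def _apply_pending(state, idx, params, rng):
    state._pending_pos += 1
    if state.nodes[idx].is_tip:
        apply_host_tip(state, idx)
    else:
        apply_host_node(state, idx, params.P, rng)
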