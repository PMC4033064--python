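"""Tree-structured stick-breaking process (TSSBP).

The TSSBP is a prior over infinite mixtures whose components are the nodes
of an infinitely deep, infinitely branching tree.  Two interleaved
stick-breaking processes define the mixture weight of every node: a depth
stick nu_e (the probability of stopping at node e rather than descending)
and branch sticks psi at each child (partitioning the descending mass among
siblings).  The weight of node e with ancestor chain root = e_0 < ... <
e_k = e is

    pi_e = nu_e * prod_{m=1..k} phi_{e_m} * prod_{m=0..k-1} (1 - nu_{e_m})

with branch weight phi_{e.i} = psi_{e.i} * prod_{j<i} (1 - psi_{e.j}).
Only finitely many nodes are ever instantiated: sticks are drawn lazily
when an assignment draw needs them (retrospective sampling), which avoids
any global truncation of the tree.

The depth sticks follow nu_e ~ Beta(1, alpha0 * lambda**depth(e)), so with
lambda < 1 mass concentrates near the root and small trees are favored;
branch sticks follow psi ~ Beta(1, gamma).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, Set

import numpy as np

from .nodes import ROOT, NodeId, ancestors, depth, parent

# Safety caps for the lazy instantiation; hitting one raises rather than
# silently truncating.
MAX_DEPTH = 25
MAX_CHILDREN = 50

# Sampled sticks are kept away from {0, 1} so that log-weights and the
# stick log-prior stay finite.
_STICK_EPS = 1e-12


def _clip_stick(x: float) -> float:
    return min(max(x, _STICK_EPS), 1.0 - _STICK_EPS)


@dataclass
class TreeHyper:
    """Hyper-parameters of the stick-breaking construction.

    alpha0 : root depth-stick concentration (> 0)
    lam    : per-level decay of the depth concentration, in (0, 1]
    gamma  : branch-stick concentration (> 0)
    """

    alpha0: float = 0.05
    lam: float = 0.2
    gamma: float = 0.05
    max_depth: int = MAX_DEPTH  # soft cap: assignment draws stop here

    def __post_init__(self) -> None:
        if not self.alpha0 > 0:
            raise ValueError("alpha0 must be positive")
        if not 0 < self.lam <= 1:
            raise ValueError("lambda must be in (0, 1]")
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")
        if not 1 <= self.max_depth <= MAX_DEPTH:
            raise ValueError(f"max_depth must be in [1, {MAX_DEPTH}]")

    def alpha(self, d: int) -> float:
        """Depth-stick Beta(1, alpha(d)) concentration at depth d."""
        return self.alpha0 * self.lam**d


class StickState:
    """Lazily instantiated stick variables.

    ``nu`` holds the depth stick of every instantiated node; ``psi`` holds
    branch sticks and may additionally contain lower-index siblings of
    instantiated nodes (their psi is needed to compute branch weights even
    when the sibling itself carries no mass).
    """

    __slots__ = ("nu", "psi")

    def __init__(self) -> None:
        self.nu: Dict[NodeId, float] = {}
        self.psi: Dict[NodeId, float] = {}

    @property
    def instantiated(self) -> Set[NodeId]:
        return set(self.nu)

    def __contains__(self, node: NodeId) -> bool:
        return node in self.nu

    def copy(self) -> "StickState":
        out = StickState()
        out.nu = dict(self.nu)
        out.psi = dict(self.psi)
        return out


@dataclass
class OccupancyCounts:
    """Sufficient statistics for the conjugate stick updates.

    node_count[e]    : number of instances assigned exactly to e
    subtree_count[e] : number assigned to e or any of its descendants
    """

    node_count: Dict[NodeId, int] = field(default_factory=dict)
    subtree_count: Dict[NodeId, int] = field(default_factory=dict)

    @classmethod
    def from_assignments(cls, assignments: Iterable[NodeId]) -> "OccupancyCounts":
        node_count: Counter = Counter()
        subtree_count: Counter = Counter()
        for z in assignments:
            node_count[z] += 1
            for k in range(len(z) + 1):
                subtree_count[z[:k]] += 1
        return cls(dict(node_count), dict(subtree_count))

    def node(self, e: NodeId) -> int:
        return self.node_count.get(e, 0)

    def subtree(self, e: NodeId) -> int:
        return self.subtree_count.get(e, 0)

    def validate(self) -> None:
        for e, n_sub in self.subtree_count.items():
            n_children = sum(
                m for c, m in self.subtree_count.items()
                if len(c) == len(e) + 1 and c[: len(e)] == e
            )
            if n_sub != self.node(e) + n_children:
                raise ValueError(
                    f"inconsistent occupancy counts at node {e}: "
                    f"subtree {n_sub} != node {self.node(e)} + children {n_children}"
                )


def sample_sticks(
    sticks: StickState, hyper: TreeHyper, node: NodeId, rng: np.random.Generator
) -> StickState:
    """Instantiate the sticks of ``node`` from the prior (idempotent).

    Draws nu ~ Beta(1, alpha(depth)) and, for non-root nodes, psi ~
    Beta(1, gamma) for the node and any not-yet-drawn lower-index
    siblings (needed for its branch weight).
    """
    if depth(node) > MAX_DEPTH:
        raise RuntimeError(f"maximum tree depth {MAX_DEPTH} exceeded at {node}")
    if node != ROOT and parent(node) not in sticks.nu:
        raise ValueError(f"parent of {node} is not instantiated")
    if node != ROOT:
        if node[-1] > MAX_CHILDREN:
            raise RuntimeError(f"maximum child count {MAX_CHILDREN} exceeded at {node}")
        for j in range(1, node[-1] + 1):
            sib = node[:-1] + (j,)
            if sib not in sticks.psi:
                sticks.psi[sib] = _clip_stick(rng.beta(1.0, hyper.gamma))
    if node not in sticks.nu:
        sticks.nu[node] = _clip_stick(rng.beta(1.0, hyper.alpha(depth(node))))
    return sticks


def branch_weight(sticks: StickState, node: NodeId) -> float:
    """phi_{e.i} = psi_{e.i} * prod_{j < i} (1 - psi_{e.j})."""
    if node == ROOT:
        raise ValueError("root has no branch weight")
    w = 1.0
    for j in range(1, node[-1]):
        sib = node[:-1] + (j,)
        if sib not in sticks.psi:
            raise ValueError(f"branch stick of sibling {sib} is not instantiated")
        w *= 1.0 - sticks.psi[sib]
    if node not in sticks.psi:
        raise ValueError(f"branch stick of {node} is not instantiated")
    return sticks.psi[node] * w


def node_weight(sticks: StickState, node: NodeId) -> float:
    """Mixture weight pi of ``node`` under the current sticks."""
    for a in ancestors(node):
        if a not in sticks.nu:
            raise ValueError(f"ancestor {a} of {node} is not instantiated")
    if node not in sticks.nu:
        raise ValueError(f"node {node} is not instantiated")
    w = sticks.nu[node]
    for k in range(len(node)):
        w *= 1.0 - sticks.nu[node[:k]]
    for k in range(1, len(node) + 1):
        w *= branch_weight(sticks, node[:k])
    return w


def interval_of(sticks: StickState, node: NodeId) -> tuple[float, float]:
    """Half-open sub-interval of [0, 1) owned by ``node``.

    The stick-breaking construction maps every node to a sub-interval of
    the unit interval whose length is its mixture weight; a uniform draw
    landing in the interval selects the node.
    """
    lo, width = 0.0, 1.0
    for k in range(len(node)):
        prefix = node[:k]
        nu = sticks.nu[prefix]
        lo += nu * width
        width *= 1.0 - nu
        for j in range(1, node[k] + 1):
            sib = prefix + (j,)
            seg = sticks.psi[sib] * width
            if j == node[k]:
                width = seg
            else:
                lo += seg
                width -= seg
    return lo, lo + sticks.nu[node] * width


def assign_via_uniform(
    sticks: StickState, hyper: TreeHyper, u: float, rng: np.random.Generator
) -> NodeId:
    """Return the node whose stick-breaking interval contains ``u``.

    Sticks are instantiated from the prior on demand (retrospective
    sampling), so for u ~ U[0, 1) the returned node is a draw from the
    multinomial with the TSSBP weights pi.
    """
    if not 0.0 <= u < 1.0:
        raise ValueError("u must lie in [0, 1)")
    node: NodeId = ROOT
    lo, width = 0.0, 1.0
    while True:
        sample_sticks(sticks, hyper, node, rng)
        nu = sticks.nu[node]
        if u < lo + nu * width or width <= 0.0:
            return node
        if depth(node) >= hyper.max_depth:
            return node  # soft cap: remaining mass stops here
        if depth(node) >= MAX_DEPTH:
            raise RuntimeError(
                f"maximum tree depth {MAX_DEPTH} exceeded locating u={u!r}"
            )
        lo += nu * width
        width *= 1.0 - nu
        j = 1
        while True:
            if j > MAX_CHILDREN:
                raise RuntimeError(
                    f"maximum child count {MAX_CHILDREN} exceeded locating u={u!r}"
                )
            c = node + (j,)
            if c not in sticks.psi:
                sticks.psi[c] = _clip_stick(rng.beta(1.0, hyper.gamma))
            seg = sticks.psi[c] * width
            if u < lo + seg:
                node = c
                width = seg
                break
            lo += seg
            width -= seg
            j += 1


def resample_sticks(
    sticks: StickState,
    counts: OccupancyCounts,
    hyper: TreeHyper,
    rng: np.random.Generator,
) -> StickState:
    """Conjugate Gibbs update of every stored stick.

    nu_e     ~ Beta(1 + n_e, alpha(depth) + m_e - n_e)
    psi_{e.i}~ Beta(1 + m_{e.i}, gamma + sum_{j>i} m_{e.j})

    with n_e = node_count(e) and m_e = subtree_count(e); with zero counts
    this reduces to the prior.
    """
    counts.validate()
    for node in sorted(sticks.nu):
        n = counts.node(node)
        m = counts.subtree(node)
        if m < n:
            raise ValueError(f"subtree count below node count at {node}")
        sticks.nu[node] = _clip_stick(
            rng.beta(1.0 + n, hyper.alpha(depth(node)) + m - n)
        )
    by_parent: Dict[NodeId, list] = {}
    for node in sticks.psi:
        by_parent.setdefault(node[:-1], []).append(node[-1])
    for par in sorted(by_parent):
        idx = sorted(by_parent[par])
        for i in idx:
            m_i = counts.subtree(par + (i,))
            tail = sum(counts.subtree(par + (j,)) for j in idx if j > i)
            sticks.psi[par + (i,)] = _clip_stick(
                rng.beta(1.0 + m_i, hyper.gamma + tail)
            )
    return sticks


def prune_unoccupied(sticks: StickState, counts: OccupancyCounts) -> StickState:
    """Drop instantiated nodes carrying no data.

    A node is kept iff its subtree holds at least one instance (the root
    is always kept).  Branch sticks of lower-index siblings of kept nodes
    are retained: they enter the kept nodes' branch weights.  Idempotent;
    weights of the kept nodes are unchanged.
    """
    keep = {n for n in sticks.nu if counts.subtree(n) > 0}
    keep.add(ROOT)
    out = StickState()
    out.nu = {n: sticks.nu[n] for n in keep}
    max_sib: Dict[NodeId, int] = {}
    for n in keep:
        if n != ROOT:
            par = n[:-1]
            max_sib[par] = max(max_sib.get(par, 0), n[-1])
    for par, hi in max_sib.items():
        for j in range(1, hi + 1):
            sib = par + (j,)
            out.psi[sib] = sticks.psi[sib]
    return out


def stick_log_prior(sticks: StickState, hyper: TreeHyper) -> float:
    """Log density of all stored sticks under the TSSBP prior.

    Beta(1, b) has log-pdf log(b) + (b - 1) * log(1 - x).
    """
    total = 0.0
    for node, nu in sticks.nu.items():
        b = hyper.alpha(depth(node))
        total += np.log(b) + (b - 1.0) * np.log1p(-nu)
    g = hyper.gamma
    for psi in sticks.psi.values():
        total += np.log(g) + (g - 1.0) * np.log1p(-psi)
    return float(total)
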