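"""MCMC inference for the attribute tree process.

The sampler targets the joint distribution

    p({pi}, {theta}, c, {z}, {x}) =
        p({pi}) p({theta}) prod_i p(z_i | {pi}) p(x_i | theta-chain of z_i)

over the lazily instantiated tree.  One sweep is:

    1. resample_assignments  - per-instance uniform-slice retrospective
       search over the infinite tree (exact; no truncation bias),
    2. resample_sticks       - conjugate Beta updates,
    3. prune_unoccupied      - drop empty nodes (their sticks/parameters
       are re-drawn from the prior if ever revisited),
    4. resample_theta        - per-node, per-dimension Metropolis-Hastings
       with a logit-scale Gaussian random walk,
    5. resample_c            - optional reflected random walk on [l, u].

Everything is a pure function of (data, config, seed).
"""

from __future__ import annotations

import logging
import math
import sys
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.special import expit, logit, logsumexp

from . import tssbp
from .model import (
    THETA_EPS,
    AttributeMatrix,
    NodeParams,
    NoiseModel,
    SparsityHyper,
    beta_logpdf,
    clip_theta,
    flip_prob,
    obs_log_likelihood,
    path_survival,
    sample_child_theta,
    sample_root_theta,
    theta_log_prior,
)
from .nodes import ROOT, NodeId, depth, in_subtree, parent
from .tssbp import (
    OccupancyCounts,
    StickState,
    TreeHyper,
    assign_via_uniform,
    interval_of,
    node_weight,
    prune_unoccupied,
    resample_sticks,
    sample_sticks,
    stick_log_prior,
)

logger = logging.getLogger("attrtree")

_SLICE_MAX_ITER = 10_000


@dataclass
class ModelHyper:
    """Bundle of all fixed hyper-parameters of the model."""

    tree: TreeHyper
    sparsity: SparsityHyper
    noise: NoiseModel

    def copy(self) -> "ModelHyper":
        return ModelHyper(
            tree=TreeHyper(self.tree.alpha0, self.tree.lam, self.tree.gamma),
            sparsity=self.sparsity.copy(),
            noise=NoiseModel(self.noise.omega.copy()),
        )

    @classmethod
    def default(cls, D: int, omega: float = 0.05) -> "ModelHyper":
        return cls(
            tree=TreeHyper(),
            sparsity=SparsityHyper(D=D),
            noise=NoiseModel.constant(D, omega),
        )


@dataclass
class McmcConfig:
    """Sampler settings.

    mh_step is the logit-scale proposal SD for theta updates; c_step the
    random-walk SD for the concentration parameters c^(d).
    """

    n_sweeps: int
    burn_in: int = 0
    thin: int = 1
    seed: int = 0
    mh_step: float = 0.5
    theta_updates: int = 4
    c_step: float = 5.0
    resample_c: bool = True
    fixed_omega: bool = True
    init: str = "root"  # "root" = all instances at the root; "prior" = scatter
    #   each instance over a prior draw of the tree (helps when clusters
    #   must be discovered by merging rather than splitting)
    split_merge: int = 10  # split/merge MH attempts per sweep (0 disables)
    anneal_sweeps: int = 0  # burn-in initialization schedule: hold the
    #   parent-child coupling c at anneal_c0 and ramp it geometrically to
    #   c_lower over this many sweeps before the exact kernel takes over;
    #   lets nested structure crystallize before the tight coupling prior
    #   re-engages.  Must not exceed burn_in (annealed sweeps are never
    #   retained).
    anneal_c0: float = 2.0

    def __post_init__(self) -> None:
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")
        if not 0 <= self.burn_in < self.n_sweeps:
            raise ValueError("require 0 <= burn_in < n_sweeps")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.anneal_sweeps > self.burn_in:
            raise ValueError("anneal_sweeps must not exceed burn_in")


@dataclass
class ModelState:
    """Full latent state of the sampler."""

    sticks: StickState
    params: NodeParams
    counts: OccupancyCounts
    assignments: List[NodeId]
    hyper: ModelHyper

    def copy(self) -> "ModelState":
        return ModelState(
            sticks=self.sticks.copy(),
            params=self.params.copy(),
            counts=OccupancyCounts(
                dict(self.counts.node_count), dict(self.counts.subtree_count)
            ),
            assignments=list(self.assignments),
            hyper=self.hyper.copy(),
        )

    def audit(self) -> None:
        """Raise if counts, assignments, sticks and parameters disagree."""
        recount = OccupancyCounts.from_assignments(self.assignments)
        if recount.node_count != self.counts.node_count:
            raise AssertionError("node counts inconsistent with assignments")
        if recount.subtree_count != self.counts.subtree_count:
            raise AssertionError("subtree counts inconsistent with assignments")
        self.counts.validate()
        for z in set(self.assignments):
            for k in range(len(z) + 1):
                e = z[:k]
                if e not in self.sticks.nu:
                    raise AssertionError(f"assigned node chain missing sticks at {e}")
                if e not in self.params.theta:
                    raise AssertionError(f"assigned node chain missing theta at {e}")


@dataclass
class TraceEntry:
    sweep: int
    log_prob: float
    state: ModelState


@dataclass
class Trace:
    """Retained post-thinning snapshots plus the full log-prob series."""

    samples: List[TraceEntry] = field(default_factory=list)
    log_probs: List[Tuple[int, float]] = field(default_factory=list)


def ensure_theta_chain(state: ModelState, node: NodeId, rng: np.random.Generator) -> None:
    """Draw any missing theta on the root-to-node chain from the prior."""
    sp = state.hyper.sparsity
    for k in range(len(node) + 1):
        e = node[:k]
        if e not in state.params.theta:
            if e == ROOT:
                state.params.theta[e] = sample_root_theta(sp, rng)
            else:
                state.params.theta[e] = sample_child_theta(
                    state.params.theta[e[:-1]], sp.c, rng
                )


def init_state(
    data: AttributeMatrix,
    hyper: ModelHyper,
    rng: np.random.Generator,
    init: str = "root",
) -> ModelState:
    """Initial state: root sticks and theta from the prior.

    ``init="root"`` places every instance at the root (top-down
    refinement); ``init="prior"`` scatters instances over a prior draw of
    the tree, which starts the chain maximally split so structure forms
    by merging.
    """
    hyper = hyper.copy()
    sticks = StickState()
    sample_sticks(sticks, hyper.tree, ROOT, rng)
    params = NodeParams({ROOT: sample_root_theta(hyper.sparsity, rng)})
    state = ModelState(sticks, params, OccupancyCounts(), [], hyper)
    if init == "root":
        state.assignments = [ROOT] * data.n
    elif init == "prior":
        for _ in range(data.n):
            z = tssbp.assign_via_uniform(sticks, hyper.tree, rng.random(), rng)
            ensure_theta_chain(state, z, rng)
            state.assignments.append(z)
    else:
        raise ValueError(f"unknown init {init!r}")
    state.counts = OccupancyCounts.from_assignments(state.assignments)
    return state


def _node_ll_terms(
    state: ModelState, node: NodeId
) -> Tuple[float, np.ndarray]:
    """(base, w) with loglik(x) = base + x . w for observations at node."""
    p = 1.0 - path_survival(state.params, node)
    pt = flip_prob(p, state.hyper.noise)
    pt = np.clip(pt, 1e-300, 1.0 - 1e-16)
    log_p = np.log(pt)
    log_q = np.log1p(-pt)
    return float(log_q.sum()), log_p - log_q


def joint_log_prob(state: ModelState, data: AttributeMatrix) -> float:
    """Log of the (unnormalized) joint over instantiated nodes."""
    state.counts.validate()
    total = stick_log_prior(state.sticks, state.hyper.tree)
    total += theta_log_prior(state.params, state.hyper.sparsity)
    cache: Dict[NodeId, Tuple[float, np.ndarray, float]] = {}
    for i, z in enumerate(state.assignments):
        if z not in cache:
            base, w = _node_ll_terms(state, z)
            cache[z] = (base, w, math.log(node_weight(state.sticks, z)))
        base, w, log_pi = cache[z]
        total += log_pi + base + float(data.X[i] @ w)
    return float(total)


def resample_assignments(
    state: ModelState, data: AttributeMatrix, rng: np.random.Generator
) -> ModelState:
    """Redraw every z_i from its full conditional over the infinite tree.

    Uses a uniform-slice retrospective search on the stick-breaking
    interval representation: a slice threshold is drawn under the current
    node's likelihood, then the bracket [0, 1) is shrunk around the
    current node's interval coordinate until a node above the slice is
    found.  Node likelihoods are cached; nodes are instantiated lazily.
    """
    terms: Dict[NodeId, Tuple[float, np.ndarray]] = {}
    X = data.X.astype(float)

    def ll(i: int, node: NodeId) -> float:
        t = terms.get(node)
        if t is None:
            t = _node_ll_terms(state, node)
            terms[node] = t
        base, w = t
        return base + float(X[i] @ w)

    for i in range(data.n):
        z = state.assignments[i]
        ll_z = ll(i, z)
        log_t = ll_z + math.log(rng.random())
        lo_z, hi_z = interval_of(state.sticks, z)
        u_z = lo_z + rng.random() * (hi_z - lo_z)
        lo, hi = 0.0, 1.0
        for _ in range(_SLICE_MAX_ITER):
            v = lo + rng.random() * (hi - lo)
            node = assign_via_uniform(state.sticks, state.hyper.tree, v, rng)
            ensure_theta_chain(state, node, rng)
            if ll(i, node) > log_t:
                state.assignments[i] = node
                break
            if v < u_z:
                lo = v
            else:
                hi = v
        else:
            raise RuntimeError(
                f"slice search failed to move instance {i} "
                f"(current node {z}, log-threshold {log_t:.3f})"
            )
    state.counts = OccupancyCounts.from_assignments(state.assignments)
    return state


def _subtree_stats(
    state: ModelState, data: AttributeMatrix
) -> Dict[NodeId, Tuple[np.ndarray, np.ndarray]]:
    """Per occupied node: (count of ones per dim, count of zeros per dim)."""
    groups: Dict[NodeId, List[int]] = {}
    for i, z in enumerate(state.assignments):
        groups.setdefault(z, []).append(i)
    out = {}
    for z, idx in groups.items():
        n1 = data.X[idx].sum(axis=0).astype(float)
        out[z] = (n1, float(len(idx)) - n1)
    return out


def resample_theta(
    state: ModelState,
    data: AttributeMatrix,
    rng: np.random.Generator,
    mh_step: float = 0.5,
) -> ModelState:
    """Metropolis-Hastings update of every stored theta vector.

    The proposal is an independent Gaussian random walk on the logit
    scale per dimension; acceptance is decided per dimension (the full
    conditional factorizes over attributes).  The conditional of theta_e
    combines its own prior, the child priors of its instantiated
    children, and the likelihood of every instance assigned in e's
    subtree, where theta_e enters through the path product.
    """
    return _resample_theta(state, data, rng, mh_step)


def _resample_theta(
    state: ModelState,
    data: AttributeMatrix,
    rng: np.random.Generator,
    mh_step: Optional[float],
    n_updates: int = 1,
) -> ModelState:
    step = 0.5 if mh_step is None else mh_step
    if step == 0.0:
        return state
    sp = state.hyper.sparsity
    stats = _subtree_stats(state, data)
    nodes = sorted(state.params.theta)
    children: Dict[NodeId, List[NodeId]] = {n: [] for n in nodes}
    for n in nodes:
        if n != ROOT and n[:-1] in children:
            children[n[:-1]].append(n)

    for node in nodes:
        theta = state.params.theta[node]
        if node == ROOT:
            pa_a = np.full(sp.D, sp.root_alpha)
            pa_b = np.full(sp.D, sp.root_beta)
        else:
            pt = state.params.theta[node[:-1]]
            pa_a = sp.c * pt
            pa_b = sp.c * (1.0 - pt)
        # Data terms: for each occupied node in the subtree, the path
        # survival excluding this node's own factor.
        sub = [
            (z, stats[z][0], stats[z][1]) for z in stats if in_subtree(node, z)
        ]
        q_excl = []
        for z, _, _ in sub:
            q = np.ones(sp.D)
            for k in range(len(z) + 1):
                e = z[:k]
                if e != node:
                    q *= 1.0 - state.params.theta[e]
            q_excl.append(q)

        def cond_logpdf(t: np.ndarray) -> np.ndarray:
            lp = beta_logpdf(t, pa_a, pa_b)
            for ch in children[node]:
                lp = lp + beta_logpdf(state.params.theta[ch], sp.c * t, sp.c * (1.0 - t))
            for (z, n1, n0), q in zip(sub, q_excl):
                p = 1.0 - q * (1.0 - t)
                ptil = np.clip(flip_prob(p, state.hyper.noise), 1e-300, 1 - 1e-16)
                lp = lp + n1 * np.log(ptil) + n0 * np.log1p(-ptil)
            return lp

        # Alternate small and large proposal scales: small steps refine,
        # large ones let a probability jump between the sparse-off and
        # confident-on regimes in one move.
        for it in range(n_updates):
            s = step if it % 2 == 0 else 5.0 * step
            prop = clip_theta(expit(logit(theta) + s * rng.standard_normal(sp.D)))
            log_acc = (
                cond_logpdf(prop)
                - cond_logpdf(theta)
                + np.log(prop * (1.0 - prop))
                - np.log(theta * (1.0 - theta))
            )
            accept = np.log(rng.random(sp.D)) < log_acc
            theta[accept] = prop[accept]
    return state


def resample_c(state: ModelState, rng: np.random.Generator, c_step: float = 5.0) -> ModelState:
    """Reflected random-walk MH for c^(d) on [c_lower, c_upper].

    The target is the product over instantiated parent-child edges of the
    child prior density; with no edges it reduces to the uniform prior.
    """
    sp = state.hyper.sparsity
    edges = [
        (state.params.theta[n[:-1]], state.params.theta[n])
        for n in sorted(state.params.theta)
        if n != ROOT
    ]

    def target(c: np.ndarray) -> np.ndarray:
        lp = np.zeros(sp.D)
        for pa, ch in edges:
            lp = lp + beta_logpdf(ch, c * pa, c * (1.0 - pa))
        return lp

    prop = sp.c + c_step * rng.standard_normal(sp.D)
    prop = _reflect(prop, sp.c_lower, sp.c_upper)
    log_acc = target(prop) - target(sp.c)
    accept = np.log(rng.random(sp.D)) < log_acc
    sp.c[accept] = prop[accept]
    return state


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if hi == lo:
        return np.full_like(x, lo)
    width = hi - lo
    y = np.mod(x - lo, 2.0 * width)
    y = np.where(y > width, 2.0 * width - y, y)
    return lo + y


def _beta_lpdf(x: float, a: float, b: float) -> float:
    return float(beta_logpdf(np.asarray(x), np.asarray(a), np.asarray(b)))


def _fresh_child_index(sticks: StickState, u: NodeId) -> int:
    idx = [n[-1] for n in sticks.psi if n[:-1] == u]
    return (max(idx) + 1) if idx else 1


def _splittable(state: ModelState) -> List[NodeId]:
    out = []
    cap = min(tssbp.MAX_DEPTH, state.hyper.tree.max_depth)
    for u in sorted(set(state.assignments)):
        if (
            state.counts.node(u) >= 1
            and depth(u) < cap
            and _fresh_child_index(state.sticks, u) <= tssbp.MAX_CHILDREN
        ):
            out.append(u)
    return out


def _mergeable(state: ModelState) -> List[NodeId]:
    occupied = set(state.assignments)
    out = []
    for v in sorted(occupied):
        if v == ROOT:
            continue
        u = v[:-1]
        # the parent may be empty: merging into an empty connector is the
        # reverse of a split that moved every instance into the child
        if v[-1] != _fresh_child_index(state.sticks, u) - 1:
            continue  # only the highest-index child is mergeable (reversibility)
        if any(k != v and k[: len(v)] == v for k in state.sticks.nu):
            continue
        if any(k[: len(v)] == v and len(k) > len(v) for k in state.sticks.psi):
            continue
        out.append(v)
    return out


def _sm_core(
    state: ModelState,
    u: NodeId,
    n_u: int,
    n_v: int,
    m_u: int,
    nu_u_split: float,
    nu_v: float,
    psi_v: float,
    phi_lower_log: float,
    nu_u_merged: float,
) -> Tuple[float, float, float]:
    """Shared split/merge terms.

    Returns (log target ratio split/merged excluding likelihood and
    move-choice terms, log proposal density of the split-direction stick
    draws, log proposal density of the merge-direction stick draw).
    """
    hy = state.hyper.tree
    a_u = hy.alpha(depth(u))
    a_v = hy.alpha(depth(u) + 1)
    n_m = n_u + n_v
    lp = (
        n_u * math.log(nu_u_split)
        + n_v * (math.log1p(-nu_u_split) + math.log(psi_v) + phi_lower_log + math.log(nu_v))
        - n_m * math.log(nu_u_merged)
        + (m_u - n_m) * (math.log1p(-nu_u_split) - math.log1p(-nu_u_merged))
    )
    lp += (
        _beta_lpdf(nu_u_split, 1.0, a_u)
        - _beta_lpdf(nu_u_merged, 1.0, a_u)
        + _beta_lpdf(nu_v, 1.0, a_v)
        + _beta_lpdf(psi_v, 1.0, hy.gamma)
    )
    q_split = (
        _beta_lpdf(nu_u_split, 1.0 + n_u, a_u + m_u - n_u)
        + _beta_lpdf(nu_v, 1.0 + n_v, a_v)
        + _beta_lpdf(psi_v, 1.0 + n_v, hy.gamma)
    )
    q_merge = _beta_lpdf(nu_u_merged, 1.0 + n_m, a_u + m_u - n_m)
    return lp, q_split, q_merge


def _phi_lower_log(state: ModelState, v: NodeId) -> float:
    u = v[:-1]
    return sum(
        math.log1p(-state.sticks.psi[u + (k,)]) for k in range(1, v[-1])
    )


# Proposal constants for the theta_v draw in split moves.  The proposal is
# a mixture: with probability _SM_CLONE_PROB theta_v is drawn tightly
# around the parent theta (a "connector" child), otherwise around a blend
# of the parent and one uniformly chosen seed instance's observation (a
# "cluster" child).  The mixture density enters the Hastings ratio, so
# both split directions and the reverse merges stay exact.
_SM_SEED_WEIGHT = 0.85
_SM_KAPPA = 20.0
_SM_CLONE_PROB = 0.5


def _seed_means(theta_u: np.ndarray, X_u: np.ndarray) -> np.ndarray:
    """Proposal means: row 0 is the parent clone, then one row per seed."""
    m = (1.0 - _SM_SEED_WEIGHT) * theta_u[None, :] + _SM_SEED_WEIGHT * X_u
    return np.clip(np.vstack([theta_u[None, :], m]), 0.02, 0.98)


def _seeded_theta_logq(theta_v: np.ndarray, means: np.ndarray) -> float:
    """Log density of theta_v under the clone/seed mixture."""
    lp = beta_logpdf(
        theta_v[None, :], _SM_KAPPA * means, _SM_KAPPA * (1.0 - means)
    ).sum(axis=1)
    n_seeds = len(means) - 1
    log_w = np.concatenate(
        [
            [math.log(_SM_CLONE_PROB)],
            np.full(n_seeds, math.log((1.0 - _SM_CLONE_PROB) / n_seeds)),
        ]
    )
    return float(logsumexp(lp + log_w))


def _draw_seeded_theta(
    means: np.ndarray, rng: np.random.Generator
) -> Optional[np.ndarray]:
    """Unclipped draw so the proposal density is exact; None if the draw
    falls into the clipped boundary region (its reverse probability is
    zero on the interior state space, so the attempt is abandoned)."""
    if rng.random() < _SM_CLONE_PROB:
        k = 0
    else:
        k = 1 + int(rng.integers(len(means) - 1))
    draw = rng.beta(_SM_KAPPA * means[k], _SM_KAPPA * (1.0 - means[k]))
    if np.any(draw <= THETA_EPS) or np.any(draw >= 1.0 - THETA_EPS):
        return None
    return draw


def split_merge_move(
    state: ModelState, data: AttributeMatrix, rng: np.random.Generator
) -> bool:
    """One Metropolis-Hastings split or merge attempt.

    A split proposes a fresh highest-index child v of an occupied node u,
    draws theta_v from its prior (which cancels in the ratio), allocates
    u's instances between u and v by sequential restricted Gibbs on the
    likelihood, and draws the affected sticks from their conjugate
    posteriors under the proposed counts (their proposal densities enter
    the Hastings ratio).  A merge is the exact reverse.  These moves let
    the chain cross between merged and split explanations that
    single-instance reassignment essentially never crosses.
    """
    if rng.random() < 0.5:
        return _attempt_split(state, data, rng)
    return _attempt_merge(state, data, rng)


def _attempt_split(
    state: ModelState, data: AttributeMatrix, rng: np.random.Generator
) -> bool:
    cand = _splittable(state)
    if not cand:
        return False
    u = cand[int(rng.integers(len(cand)))]
    s_size = len(cand)
    j = _fresh_child_index(state.sticks, u)
    v = u + (j,)
    sp = state.hyper.sparsity
    theta_u = state.params.theta[u]
    idx = np.asarray([i for i, z in enumerate(state.assignments) if z == u])
    Xu = data.X[idx].astype(float)
    # Seeded proposal: centre theta_v on a blend of theta_u and one seed
    # instance, so proposed partitions align with actual sub-structure.
    means = _seed_means(theta_u, Xu)
    theta_v = _draw_seeded_theta(means, rng)
    if theta_v is None:
        return False
    q_theta = _seeded_theta_logq(theta_v, means)
    lp_theta = float(
        beta_logpdf(theta_v, sp.c * theta_u, sp.c * (1.0 - theta_u)).sum()
    )
    state.params.theta[v] = theta_v  # temporary; removed on rejection
    base_u, w_u = _node_ll_terms(state, u)
    base_v, w_v = _node_ll_terms(state, v)
    L_u = base_u + Xu @ w_u
    L_v = base_v + Xu @ w_v
    with np.errstate(over="ignore"):
        p_v = 1.0 / (1.0 + np.exp(L_u - L_v))
    go_v = rng.random(len(idx)) < p_v
    n_v = int(go_v.sum())
    n_u = len(idx) - n_v
    if n_v == 0:  # no new node created; n_u = 0 (a connector split) is valid
        del state.params.theta[v]
        return False
    with np.errstate(divide="ignore"):
        q_alloc = float(
            np.log(np.where(go_v, p_v, 1.0 - p_v)).sum()
        )
    m_u = state.counts.subtree(u)
    hy = state.hyper.tree
    a_u = hy.alpha(depth(u))
    a_v = hy.alpha(depth(u) + 1)
    nu_u_merged = state.sticks.nu[u]
    nu_u_split = tssbp._clip_stick(rng.beta(1.0 + n_u, a_u + m_u - n_u))
    nu_v = tssbp._clip_stick(rng.beta(1.0 + n_v, a_v))
    psi_v = tssbp._clip_stick(rng.beta(1.0 + n_v, hy.gamma))
    # apply tentatively (counts change only at u and the fresh v)
    state.sticks.nu[u] = nu_u_split
    state.sticks.nu[v] = nu_v
    state.sticks.psi[v] = psi_v
    moved = idx[go_v]
    for i in moved:
        state.assignments[i] = v
    if n_u:
        state.counts.node_count[u] = n_u
    else:
        state.counts.node_count.pop(u, None)
    state.counts.node_count[v] = n_v
    state.counts.subtree_count[v] = n_v
    m_size = len(_mergeable(state))
    lp, q_split, q_merge = _sm_core(
        state, u, n_u, n_v, m_u, nu_u_split, nu_v, psi_v,
        _phi_lower_log(state, v), nu_u_merged,
    )
    lik = float(L_v[go_v].sum() - L_u[go_v].sum())
    log_acc = (
        lp + lik + lp_theta
        + (-math.log(m_size) + q_merge)
        - (-math.log(s_size) + q_theta + q_alloc + q_split)
    )
    if math.log(rng.random()) < log_acc:
        return True
    # revert
    for i in moved:
        state.assignments[i] = u
    state.sticks.nu[u] = nu_u_merged
    del state.sticks.nu[v], state.sticks.psi[v], state.params.theta[v]
    state.counts.node_count[u] = n_u + n_v
    del state.counts.node_count[v], state.counts.subtree_count[v]
    return False


def _attempt_merge(
    state: ModelState, data: AttributeMatrix, rng: np.random.Generator
) -> bool:
    cand = _mergeable(state)
    if not cand:
        return False
    v = cand[int(rng.integers(len(cand)))]
    m_size = len(cand)
    u = v[:-1]
    sp = state.hyper.sparsity
    theta_u = state.params.theta[u]
    base_u, w_u = _node_ll_terms(state, u)
    base_v, w_v = _node_ll_terms(state, v)
    idx = np.asarray(
        [i for i, z in enumerate(state.assignments) if z == u or z == v]
    )
    at_v = np.asarray([state.assignments[i] == v for i in idx])
    Xm = data.X[idx].astype(float)
    L_u = base_u + Xm @ w_u
    L_v = base_v + Xm @ w_v
    with np.errstate(over="ignore"):
        p_v = 1.0 / (1.0 + np.exp(L_u - L_v))
    with np.errstate(divide="ignore"):
        q_alloc = float(np.log(np.where(at_v, p_v, 1.0 - p_v)).sum())
    if not np.isfinite(q_alloc):
        return False  # current partition unreachable by the reverse split
    n_v = int(at_v.sum())
    n_u = len(idx) - n_v
    n_m = len(idx)
    m_u = state.counts.subtree(u)
    hy = state.hyper.tree
    a_u = hy.alpha(depth(u))
    nu_u_split = state.sticks.nu[u]
    nu_v = state.sticks.nu[v]
    psi_v = state.sticks.psi[v]
    theta_v = state.params.theta[v]
    if np.any(theta_v <= THETA_EPS) or np.any(theta_v >= 1.0 - THETA_EPS):
        return False  # boundary-clipped theta: the reverse split cannot
        # produce it, so the merge has zero acceptance
    phi_lower = _phi_lower_log(state, v)
    q_theta = _seeded_theta_logq(theta_v, _seed_means(theta_u, Xm))
    lp_theta = float(
        beta_logpdf(theta_v, sp.c * theta_u, sp.c * (1.0 - theta_u)).sum()
    )
    nu_u_merged = tssbp._clip_stick(rng.beta(1.0 + n_m, a_u + m_u - n_m))
    lp, q_split, q_merge = _sm_core(
        state, u, n_u, n_v, m_u, nu_u_split, nu_v, psi_v, phi_lower, nu_u_merged
    )
    lik = float(L_v[at_v].sum() - L_u[at_v].sum())
    # apply tentatively (counts change only at u and v)
    moved = idx[at_v]
    for i in moved:
        state.assignments[i] = u
    old_nu_u = nu_u_split
    state.sticks.nu[u] = nu_u_merged
    del state.sticks.nu[v], state.sticks.psi[v], state.params.theta[v]
    state.counts.node_count[u] = n_m
    del state.counts.node_count[v], state.counts.subtree_count[v]
    s_size = len(_splittable(state))
    log_acc = -(
        lp + lik + lp_theta
        + (-math.log(m_size) + q_merge)
        - (-math.log(s_size) + q_theta + q_alloc + q_split)
    )
    if math.log(rng.random()) < log_acc:
        return True
    # revert
    for i in moved:
        state.assignments[i] = v
    state.sticks.nu[u] = old_nu_u
    state.sticks.nu[v] = nu_v
    state.sticks.psi[v] = psi_v
    state.params.theta[v] = theta_v
    if n_u:
        state.counts.node_count[u] = n_u
    else:
        state.counts.node_count.pop(u, None)
    state.counts.node_count[v] = n_v
    state.counts.subtree_count[v] = n_v
    return False


def prune_state(state: ModelState) -> ModelState:
    """Remove unoccupied nodes from sticks and parameters."""
    state.sticks = prune_unoccupied(state.sticks, state.counts)
    keep = set(state.sticks.nu)
    state.params.theta = {
        n: t for n, t in state.params.theta.items() if n in keep
    }
    return state


def mcmc_sweep(
    state: ModelState,
    data: AttributeMatrix,
    config: McmcConfig,
    rng: np.random.Generator,
) -> ModelState:
    """One full transition of the sampler (leaves the joint invariant)."""
    resample_assignments(state, data, rng)
    resample_sticks(state.sticks, state.counts, state.hyper.tree, rng)
    prune_state(state)
    for _ in range(config.split_merge):
        split_merge_move(state, data, rng)
    _resample_theta(state, data, rng, config.mh_step, config.theta_updates)
    if config.resample_c:
        resample_c(state, rng, config.c_step)
    return state


def run_mcmc(
    data: AttributeMatrix,
    config: McmcConfig,
    hyper: Optional[ModelHyper] = None,
    audit: bool = False,
) -> Trace:
    """Run the full sampler and return the trace.

    Initialization places every instance at the root with theta drawn
    from the prior and c drawn uniformly on [c_lower, c_upper].  The
    log joint is recorded every sweep; snapshots are retained after
    burn-in at the configured thinning.
    """
    if hyper is None:
        hyper = ModelHyper.default(data.D)
    if hyper.sparsity.D != data.D:
        raise ValueError("hyper-parameter dimension does not match the data")
    rng = np.random.default_rng(config.seed)
    state = init_state(data, hyper, rng, config.init)
    if config.resample_c:
        state.hyper.sparsity.c = np.asarray(
            rng.uniform(state.hyper.sparsity.c_lower, state.hyper.sparsity.c_upper, data.D)
        )
    trace = Trace()
    sp = state.hyper.sparsity
    anneal_cfg = None
    if config.anneal_sweeps:
        anneal_cfg = McmcConfig(
            **{**config.__dict__, "resample_c": False, "anneal_sweeps": 0}
        )
    full_depth = state.hyper.tree.max_depth
    for sweep in range(1, config.n_sweeps + 1):
        if anneal_cfg is not None and sweep <= config.anneal_sweeps:
            # Initialization schedule: ramp the parent-child coupling
            # geometrically from anneal_c0 to c_lower while growing the
            # allowed tree depth one level at a time (clusters separate
            # laterally first, then nest), then hand back to the exact
            # kernel.
            frac = sweep / config.anneal_sweeps
            sp.c[:] = config.anneal_c0 * (sp.c_lower / config.anneal_c0) ** frac
            state.hyper.tree.max_depth = min(full_depth, 1 + int(4 * frac))
            mcmc_sweep(state, data, anneal_cfg, rng)
            if sweep == config.anneal_sweeps:
                state.hyper.tree.max_depth = full_depth
                if config.resample_c:
                    sp.c[:] = rng.uniform(sp.c_lower, sp.c_upper, sp.D)
                else:
                    sp.c[:] = 0.5 * (sp.c_lower + sp.c_upper)
        else:
            mcmc_sweep(state, data, config, rng)
        if audit:
            state.audit()
        lp = joint_log_prob(state, data)
        if not np.isfinite(lp):
            raise RuntimeError(
                f"non-finite joint log-probability at sweep {sweep} "
                f"({len(state.sticks.nu)} nodes instantiated)"
            )
        trace.log_probs.append((sweep, lp))
        if sweep % max(1, config.n_sweeps // 20) == 0 or sweep == 1:
            logger.info(
                "sweep %d/%d log_prob=%.3f nodes=%d",
                sweep, config.n_sweeps, lp, len(state.sticks.nu),
            )
        if sweep > config.burn_in and (sweep - config.burn_in) % config.thin == 0:
            trace.samples.append(TraceEntry(sweep, lp, state.copy()))
    return trace


def select_map_sample(trace: Trace) -> ModelState:
    """Retained snapshot with maximal log joint; ties go to the later sweep."""
    if not trace.samples:
        raise ValueError("trace contains no retained samples")
    best = trace.samples[0]
    for entry in trace.samples[1:]:
        if entry.log_prob >= best.log_prob:
            best = entry
    return best.state
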