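"""Hierarchical Beta-Bernoulli attribute model with a path-OR likelihood.

Each node e of the tree carries a vector theta_e of D attribute
probabilities.  The root prior is sparse,

    theta_root^(d) ~ Beta(a/D, b(D-1)/D),

pushing most root probabilities toward zero, while every other node is
tied to its parent,

    theta_e^(d) ~ Beta(c^(d) theta_pa^(d), c^(d) (1 - theta_pa^(d))),

whose mean is exactly the parent value, so sparsity pressure applies only
to attributes not already explained by an ancestor.

An observation assigned to node e is generated by drawing a Bernoulli
vector at every node on the root-to-e path, OR-ing them per dimension,
and finally flipping each bit independently with probability omega^(d).
Marginalizing the per-node activations gives the closed-form likelihood
used everywhere: the activation probability is

    p_e^(d) = 1 - prod_{e' on path} (1 - theta_{e'}^(d)),

and after noise the probability of observing a 1 is

    ptilde = p_e^(d) (1 - omega^(d)) + (1 - p_e^(d)) omega^(d).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.special import gammaln

from .nodes import ROOT, NodeId, path

# Node probabilities are clipped to this open interval after every update
# so the child prior Beta(c*theta, c*(1-theta)) stays proper.
THETA_EPS = 1e-6


def clip_theta(theta: np.ndarray) -> np.ndarray:
    return np.clip(theta, THETA_EPS, 1.0 - THETA_EPS)


def beta_logpdf(x: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Elementwise log Beta(a, b) density; -inf on the closed boundary."""
    x = np.asarray(x, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    out = np.full(np.broadcast(x, a, b).shape, -np.inf)
    ok = (x > 0.0) & (x < 1.0) & (a > 0.0) & (b > 0.0)
    xo = np.broadcast_to(x, out.shape)[ok]
    ao = np.broadcast_to(a, out.shape)[ok]
    bo = np.broadcast_to(b, out.shape)[ok]
    out[ok] = (
        gammaln(ao + bo)
        - gammaln(ao)
        - gammaln(bo)
        + (ao - 1.0) * np.log(xo)
        + (bo - 1.0) * np.log1p(-xo)
    )
    return out


@dataclass
class SparsityHyper:
    """Hyper-parameters of the hierarchical Beta prior on node parameters.

    a, b    : root sparsity; the root prior mean is a / (a + b(D-1))
    c       : per-attribute concentration tying children to their parent
    c_lower, c_upper : support of the uniform prior on each c^(d)
    D       : number of attributes
    """

    D: int
    a: float = 10.0
    b: float = 5.0
    c: np.ndarray = None  # type: ignore[assignment]
    c_lower: float = 20.0
    c_upper: float = 100.0

    def __post_init__(self) -> None:
        if self.D < 1:
            raise ValueError("D must be >= 1")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("a and b must be positive")
        if not 0 < self.c_lower <= self.c_upper:
            raise ValueError("require 0 < c_lower <= c_upper")
        if self.c is None:
            self.c = np.full(self.D, 0.5 * (self.c_lower + self.c_upper))
        self.c = np.asarray(self.c, dtype=float)
        if self.c.shape != (self.D,):
            raise ValueError("c must have one entry per attribute")
        if np.any(self.c < self.c_lower) or np.any(self.c > self.c_upper):
            raise ValueError("c entries must lie in [c_lower, c_upper]")

    @property
    def root_alpha(self) -> float:
        return self.a / self.D

    @property
    def root_beta(self) -> float:
        return self.b * (self.D - 1) / self.D

    def copy(self) -> "SparsityHyper":
        return SparsityHyper(
            D=self.D, a=self.a, b=self.b, c=self.c.copy(),
            c_lower=self.c_lower, c_upper=self.c_upper,
        )


@dataclass
class NoiseModel:
    """Attribute-dependent bit-flip probabilities omega^(d) in [0, 0.5)."""

    omega: np.ndarray

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        if np.any(self.omega < 0) or np.any(self.omega >= 0.5):
            raise ValueError("flip probabilities must lie in [0, 0.5)")

    @classmethod
    def constant(cls, D: int, omega: float = 0.05) -> "NoiseModel":
        return cls(np.full(D, float(omega)))


class NodeParams:
    """Per-node attribute probability vectors theta_e."""

    __slots__ = ("theta",)

    def __init__(self, theta: Optional[Dict[NodeId, np.ndarray]] = None) -> None:
        self.theta: Dict[NodeId, np.ndarray] = theta if theta is not None else {}

    def __contains__(self, node: NodeId) -> bool:
        return node in self.theta

    def copy(self) -> "NodeParams":
        return NodeParams({n: t.copy() for n, t in self.theta.items()})


@dataclass
class AttributeMatrix:
    """N x D binary observation table with names and optional categories."""

    X: np.ndarray
    instance_ids: List[str]
    attribute_names: List[str]
    categories: Optional[List[str]] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D array")
        if not np.isin(self.X, (0, 1)).all():
            raise ValueError("observations must be binary")
        self.X = self.X.astype(np.int8)
        n, d = self.X.shape
        if len(self.instance_ids) != n:
            raise ValueError("instance_ids length does not match X")
        if len(set(self.instance_ids)) != n:
            raise ValueError("duplicate instance ids")
        if len(self.attribute_names) != d:
            raise ValueError("attribute_names length does not match X")
        if self.categories is not None and len(self.categories) != n:
            raise ValueError("categories length does not match X")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def D(self) -> int:
        return self.X.shape[1]


def sample_root_theta(hyper: SparsityHyper, rng: np.random.Generator) -> np.ndarray:
    """Draw theta_root^(d) ~ Beta(a/D, b(D-1)/D) independently per d."""
    if hyper.root_beta <= 0:
        raise ValueError("root prior is degenerate for D = 1")
    return clip_theta(rng.beta(hyper.root_alpha, hyper.root_beta, size=hyper.D))


def sample_child_theta(
    parent_theta: np.ndarray, c: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw theta^(d) ~ Beta(c^(d) mu, c^(d)(1 - mu)) around the parent mu."""
    parent_theta = np.asarray(parent_theta, dtype=float)
    if np.any(parent_theta <= 0.0) or np.any(parent_theta >= 1.0):
        raise ValueError("parent theta must lie strictly inside (0, 1)")
    c = np.asarray(c, dtype=float)
    return clip_theta(rng.beta(c * parent_theta, c * (1.0 - parent_theta)))


def theta_log_prior(params: NodeParams, hyper: SparsityHyper) -> float:
    """Sum of log Beta densities of all stored node parameter vectors.

    Returns -inf if any theta sits on the boundary of [0, 1].
    """
    total = 0.0
    for node, theta in params.theta.items():
        if node == ROOT:
            lp = beta_logpdf(theta, hyper.root_alpha, hyper.root_beta)
        else:
            pa = params.theta[node[:-1]]
            lp = beta_logpdf(theta, hyper.c * pa, hyper.c * (1.0 - pa))
        s = lp.sum()
        if not np.isfinite(s):
            return -np.inf
        total += s
    return float(total)


def path_survival(params: NodeParams, node: NodeId) -> np.ndarray:
    """prod over the root-to-node path of (1 - theta); vector of length D."""
    q = None
    for e in path(node):
        if e not in params.theta:
            raise ValueError(f"node {e} has no parameters")
        t = params.theta[e]
        q = (1.0 - t) if q is None else q * (1.0 - t)
    return q


def path_activation_prob(params: NodeParams, node: NodeId) -> np.ndarray:
    """Marginal activation probability p_e^(d) = 1 - prod(1 - theta)."""
    return 1.0 - path_survival(params, node)


def flip_prob(p: np.ndarray, noise: NoiseModel) -> np.ndarray:
    """Observation probability after the bit-flip channel."""
    w = noise.omega
    return p * (1.0 - w) + (1.0 - p) * w


def obs_log_likelihood(
    x: np.ndarray, node: NodeId, params: NodeParams, noise: NoiseModel
) -> float:
    """Exact marginal log-likelihood of a binary vector at ``node``.

    Equals the sum over all latent per-node activation configurations of
    the path-OR generative process, marginalized in closed form.
    """
    x = np.asarray(x)
    p = path_activation_prob(params, node)
    if x.shape != p.shape:
        raise ValueError("observation dimension does not match the model")
    pt = flip_prob(p, noise)
    with np.errstate(divide="ignore"):
        ll = np.where(x == 1, np.log(pt), np.log1p(-pt))
    return float(ll.sum())


def generate_observation(
    node: NodeId, params: NodeParams, noise: NoiseModel, rng: np.random.Generator
) -> np.ndarray:
    """Sample one binary vector by the path-OR-then-flip process."""
    active = None
    for e in path(node):
        draw = rng.random(params.theta[e].shape) < params.theta[e]
        active = draw if active is None else (active | draw)
    flips = rng.random(active.shape) < noise.omega
    return (active ^ flips).astype(np.int8)
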