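"""Planted-hierarchy generators for end-to-end testing without real data.

The generator emulates the regime the model is meant for: instances are
binary attribute vectors drawn from a known (planted) tree whose nodes
carry sparse attribute-probability vectors.  Each node owns a small set
of "novel" attributes with high probability; everything else sits at a
low background probability, and ancestor attributes propagate to
descendants through the path-OR of the generative process, not by
duplicating them in the child's theta.  Observed bits are flipped with
probability omega, mimicking unreliable attribute detectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .evaluation import LearnedHierarchy, Taxonomy, average_edge_error
from .model import (
    AttributeMatrix,
    NodeParams,
    NoiseModel,
    clip_theta,
    generate_observation,
)
from .nodes import ROOT, NodeId, path_str
from .tssbp import StickState


@dataclass
class PlantedSpec:
    """Layout of the planted tree and its attribute regime.

    children_per_level: fan-out at each depth, e.g. [3, 2] = a root with
    3 children, each with 2 grandchildren.  Every non-root node (and
    optionally the root) owns ``novel_per_node`` attributes, disjoint
    across nodes, with probability ``high_prob``; all other entries are
    ``low_prob``.  Instances are placed on the tree by ``mixing``
    ("nonroot" = uniform over all non-root nodes, "leaves" = uniform over
    the deepest level, or an explicit node -> probability map).
    """

    children_per_level: Sequence[int] = (3, 2)
    D: int = 20
    novel_per_node: int = 2
    root_novel: int = 0
    high_prob: float = 0.95
    low_prob: float = 0.01
    omega: float = 0.02
    N: int = 300
    mixing: object = "nonroot"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.high_prob > 0.5 > self.low_prob >= 0):
            raise ValueError("require high_prob > 0.5 > low_prob >= 0")
        if not 0 <= self.omega < 0.5:
            raise ValueError("omega must lie in [0, 0.5)")

    def nodes_by_level(self) -> List[List[NodeId]]:
        levels: List[List[NodeId]] = [[ROOT]]
        for fanout in self.children_per_level:
            levels.append(
                [p + (j,) for p in levels[-1] for j in range(1, fanout + 1)]
            )
        return levels


@dataclass
class PlantedModel:
    """A planted tree: parameters, taxonomy, and the novel-support map."""

    sticks: StickState
    params: NodeParams
    taxonomy: Taxonomy
    noise: NoiseModel
    novel_support: Dict[NodeId, List[int]]
    spec: PlantedSpec

    @property
    def nodes(self) -> List[NodeId]:
        return sorted(self.params.theta)

    def category_of_node(self, node: NodeId) -> str:
        return "cat_" + (path_str(node) or "root")


def make_planted_model(spec: PlantedSpec) -> PlantedModel:
    """Build the explicit planted tree from the layout specification.

    theta of each node is high_prob on its own novel attributes and
    low_prob elsewhere; the taxonomy is the planted tree itself with a
    category attached to every node.
    """
    levels = spec.nodes_by_level()
    all_nodes = [n for level in levels for n in level]
    budget = spec.root_novel + spec.novel_per_node * (len(all_nodes) - 1)
    if budget > spec.D:
        raise ValueError(
            f"attribute budget exceeded: {budget} novel attributes > D = {spec.D}"
        )
    novel: Dict[NodeId, List[int]] = {}
    cursor = 0
    for node in all_nodes:
        k = spec.root_novel if node == ROOT else spec.novel_per_node
        novel[node] = list(range(cursor, cursor + k))
        cursor += k
    params = NodeParams()
    sticks = StickState()
    for node in all_nodes:
        theta = np.full(spec.D, spec.low_prob, dtype=float)
        theta[novel[node]] = spec.high_prob
        params.theta[node] = clip_theta(theta)
        sticks.nu[node] = 0.5
        if node != ROOT:
            sticks.psi[node] = 0.5
    parent_map = {n: (None if n == ROOT else n[:-1]) for n in all_nodes}
    category_node = {
        "cat_" + (path_str(n) or "root"): n for n in all_nodes
    }
    taxonomy = Taxonomy(parent_map, category_node)
    noise = NoiseModel.constant(spec.D, spec.omega)
    return PlantedModel(sticks, params, taxonomy, noise, novel, spec)


def _mixing_nodes_probs(model: PlantedModel) -> Tuple[List[NodeId], np.ndarray]:
    spec = model.spec
    if isinstance(spec.mixing, dict):
        nodes = sorted(spec.mixing)
        probs = np.array([spec.mixing[n] for n in nodes], dtype=float)
    elif spec.mixing == "nonroot":
        nodes = [n for n in model.nodes if n != ROOT]
        probs = np.ones(len(nodes))
    elif spec.mixing == "leaves":
        nodes = model.spec.nodes_by_level()[-1]
        probs = np.ones(len(nodes))
    else:
        raise ValueError(f"unknown mixing {spec.mixing!r}")
    return nodes, probs / probs.sum()


def simulate_dataset(
    model: PlantedModel,
    N: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[AttributeMatrix, List[NodeId], List[str]]:
    """Draw instances from the planted model.

    Each instance's node comes from the mixing distribution; its vector
    from the path-OR-then-flip process.  Returns the data together with
    the true assignments and category labels for recovery scoring.
    """
    spec = model.spec
    if N is None:
        N = spec.N
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    nodes, probs = _mixing_nodes_probs(model)
    idx = rng.choice(len(nodes), size=N, p=probs)
    assignments = [nodes[i] for i in idx]
    X = np.empty((N, spec.D), dtype=np.int8)
    for i, z in enumerate(assignments):
        X[i] = generate_observation(z, model.params, model.noise, rng)
    categories = [model.category_of_node(z) for z in assignments]
    ids = [f"i{i:05d}" for i in range(N)]
    names = [f"attr{d:03d}" for d in range(spec.D)]
    data = AttributeMatrix(X, ids, names, categories)
    return data, assignments, categories


def binarize_scores(
    scores: np.ndarray,
    instance_ids: List[str],
    attribute_names: List[str],
    threshold: float = 0.0,
    categories: Optional[List[str]] = None,
) -> AttributeMatrix:
    """Threshold real-valued detector scores into a binary matrix.

    An entry is 1 iff its score exceeds the threshold (default 0, the
    margin sign of a linear classifier).
    """
    scores = np.asarray(scores, dtype=float)
    if np.isnan(scores).any():
        raise ValueError("scores contain NaN")
    X = (scores > threshold).astype(np.int8)
    return AttributeMatrix(X, instance_ids, attribute_names, categories)


def random_assignment_baseline(
    learned: LearnedHierarchy,
    taxonomy: Taxonomy,
    rng: np.random.Generator,
    repeats: int = 100,
) -> np.ndarray:
    """Calibration floor: scores of uniformly scrambled assignments.

    Keeps the learned tree but assigns every instance to one of its
    occupied nodes uniformly at random; returns the average edge error
    of each repeat.
    """
    occupied = sorted(set(learned.node_of.values()))
    instances = list(learned.node_of)
    out = np.empty(repeats)
    for r in range(repeats):
        scrambled = {
            i: occupied[k]
            for i, k in zip(instances, rng.integers(0, len(occupied), len(instances)))
        }
        out[r] = average_edge_error(
            LearnedHierarchy(dict(learned.parent), scrambled), taxonomy
        )
    return out
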