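"""Hierarchy evaluation: edge distances, the average edge error, and
per-node attribute labeling.

The average edge error compares a learned hierarchical clustering with a
ground-truth category taxonomy:

    (2 / (N(N-1))) * sum_{i<j} | d_H(i, j) - d_GT(c(i), c(j)) |

where d_H counts tree edges between the nodes holding instances i and j
in the learned hierarchy, and d_GT counts edges between their categories'
nodes in the taxonomy.  Two instances at the same node are at distance 0,
and identical categories are at distance 0.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Hashable, List, Optional

import numpy as np

from .inference import ModelState
from .model import path_activation_prob
from .nodes import ROOT, NodeId, path_str


def edge_distance(parent_map: Dict[Hashable, Optional[Hashable]], a: Hashable, b: Hashable) -> int:
    """Number of edges on the unique path between two tree nodes.

    ``parent_map`` maps every node to its parent (None for the root).
    Computed via the lowest common ancestor; symmetric, and 0 iff a = b.
    """
    if a not in parent_map:
        raise ValueError(f"node {a!r} is not in the tree")
    if b not in parent_map:
        raise ValueError(f"node {b!r} is not in the tree")

    def chain(n: Hashable) -> List[Hashable]:
        out = [n]
        while parent_map[n] is not None:
            n = parent_map[n]
            out.append(n)
        return out

    ca, cb = chain(a), chain(b)
    anc_a = {n: i for i, n in enumerate(ca)}
    for j, n in enumerate(cb):
        if n in anc_a:
            return anc_a[n] + j
    raise ValueError(f"nodes {a!r} and {b!r} are not in the same tree")


@dataclass
class Taxonomy:
    """Ground-truth category tree plus instance category labels.

    Categories are attached to labeled nodes of the tree (usually leaves;
    internal labels are allowed, as in planted synthetic taxonomies).
    """

    parent: Dict[Hashable, Optional[Hashable]]
    category_node: Dict[str, Hashable]
    category_of: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        roots = [n for n, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError("taxonomy must have exactly one root")
        for cat, node in self.category_node.items():
            if node not in self.parent:
                raise ValueError(f"category {cat!r} points outside the tree")

    def distance(self, c1: str, c2: str) -> int:
        if c1 not in self.category_node:
            raise ValueError(f"unknown category {c1!r}")
        if c2 not in self.category_node:
            raise ValueError(f"unknown category {c2!r}")
        return edge_distance(self.parent, self.category_node[c1], self.category_node[c2])

    def with_categories(self, category_of: Dict[str, str]) -> "Taxonomy":
        return Taxonomy(self.parent, self.category_node, dict(category_of))


@dataclass
class LearnedHierarchy:
    """A learned tree plus the node each instance is assigned to."""

    parent: Dict[Hashable, Optional[Hashable]]
    node_of: Dict[str, Hashable]

    def __post_init__(self) -> None:
        for i, n in self.node_of.items():
            if n not in self.parent:
                raise ValueError(f"instance {i!r} assigned outside the tree")

    @classmethod
    def from_state(cls, state: ModelState, instance_ids: List[str]) -> "LearnedHierarchy":
        """Tree of occupied nodes and their ancestors, instances attached."""
        nodes = set()
        for z in state.assignments:
            for k in range(len(z) + 1):
                nodes.add(z[:k])
        parent_map: Dict[Hashable, Optional[Hashable]] = {}
        for n in nodes:
            parent_map[n] = None if n == ROOT else n[:-1]
        node_of = dict(zip(instance_ids, state.assignments))
        return cls(parent_map, node_of)


def average_edge_error(learned: LearnedHierarchy, taxonomy: Taxonomy) -> float:
    """Mean absolute edge-distance discrepancy over all instance pairs."""
    instances = list(learned.node_of)
    n = len(instances)
    if n < 2:
        raise ValueError("average edge error needs at least two instances")
    for i in instances:
        if i not in taxonomy.category_of:
            raise ValueError(f"instance {i!r} has no category")
    # Group instances by (node, category): the pair term only depends on
    # the group, so the O(N^2) sum collapses to a sum over group pairs.
    combos = Counter(
        (learned.node_of[i], taxonomy.category_of[i]) for i in instances
    )
    keys = list(combos)
    total = 0.0
    for a in range(len(keys)):
        node_a, cat_a = keys[a]
        m_a = combos[keys[a]]
        for b in range(a + 1, len(keys)):
            node_b, cat_b = keys[b]
            d_h = edge_distance(learned.parent, node_a, node_b)
            d_gt = taxonomy.distance(cat_a, cat_b)
            total += abs(d_h - d_gt) * m_a * combos[keys[b]]
        # same node, same category pairs contribute |0 - 0| = 0
    return 2.0 * total / (n * (n - 1))


def extract_node_attributes(
    state: ModelState,
    node: NodeId,
    threshold: float = 0.7,
    attribute_names: Optional[List[str]] = None,
) -> List[str]:
    """Attributes newly displayed at ``node``.

    An attribute is shown iff its path-activation probability exceeds the
    threshold at the node but not at the parent (activation is monotone
    along the path, so the parent check covers all ancestors).  Ordered
    by decreasing probability.
    """
    p = path_activation_prob(state.params, node)
    shown = p > threshold
    if node != ROOT:
        p_parent = path_activation_prob(state.params, node[:-1])
        shown &= ~(p_parent > threshold)
    idx = np.nonzero(shown)[0]
    idx = idx[np.argsort(-p[idx], kind="stable")]
    if attribute_names is None:
        return [str(d) for d in idx]
    return [attribute_names[d] for d in idx]


def render_hierarchy(
    state: ModelState,
    threshold: float = 0.7,
    attribute_names: Optional[List[str]] = None,
) -> str:
    """Indented text rendering of the occupied tree.

    Each line shows the node path, its instance count, and the attributes
    newly displayed there; "(-)" marks nodes contributing no new
    attributes (internal/connector nodes).
    """
    nodes = set()
    for z in state.assignments:
        for k in range(len(z) + 1):
            nodes.add(z[:k])
    nodes.add(ROOT)
    lines = []
    for node in sorted(nodes):
        attrs = extract_node_attributes(state, node, threshold, attribute_names)
        label = ", ".join(attrs) if attrs else "(-)"
        count = state.counts.node(node)
        name = path_str(node) or "root"
        lines.append(f"{'  ' * len(node)}{name} [n={count}] {label}")
    return "\n".join(lines)
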