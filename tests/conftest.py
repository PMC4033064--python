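"""Shared fixtures and independent oracle implementations.

Oracles here deliberately avoid the package's own code paths: the
likelihood oracle enumerates latent activations, the linkage oracle
recomputes average distances from raw points at every step, and tree
distances come from networkx shortest paths.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def enumerate_loglik(
    x: Sequence[int], thetas: Sequence[Sequence[float]], omega: Sequence[float]
) -> float:
    """Brute-force log-likelihood of the path-OR-then-flip process.

    Sums over every combination of per-node Bernoulli activations for
    every dimension independently.
    """
    total = 0.0
    k = len(thetas)
    for d in range(len(x)):
        p_obs = 0.0
        for bits in itertools.product((0, 1), repeat=k):
            p_bits = 1.0
            for j, b in enumerate(bits):
                t = thetas[j][d]
                p_bits *= t if b else (1.0 - t)
            active = 1 if any(bits) else 0
            p_one = (1.0 - omega[d]) if active else omega[d]
            p_obs += p_bits * (p_one if x[d] == 1 else 1.0 - p_one)
        total += math.log(p_obs)
    return total


def brute_force_average_edge_error(
    node_of: Dict[str, object],
    learned_parent: Dict[object, object],
    category_of: Dict[str, str],
    category_node: Dict[str, object],
    taxonomy_parent: Dict[object, object],
) -> float:
    """O(N^2) double loop over instance pairs with networkx distances."""
    import networkx as nx

    def graph(parent):
        g = nx.Graph()
        for n, p in parent.items():
            g.add_node(n)
            if p is not None:
                g.add_edge(n, p)
        return g

    gl = graph(learned_parent)
    gt = graph(taxonomy_parent)
    ids = sorted(node_of)
    n = len(ids)
    total = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dh = nx.shortest_path_length(gl, node_of[ids[i]], node_of[ids[j]])
            dgt = nx.shortest_path_length(
                gt, category_node[category_of[ids[i]]], category_node[category_of[ids[j]]]
            )
            total += abs(dh - dgt)
    return 2.0 * total / (n * (n - 1))


def brute_force_upgma(points: np.ndarray) -> List[Tuple[frozenset, frozenset, float]]:
    """From-scratch average linkage: recompute every cluster-pair mean
    pairwise Euclidean distance from raw points at every step.

    Ties break toward the pair with the smallest (min index, min index)
    labels.  Returns merges as (members_a, members_b, height).
    """
    clusters: List[frozenset] = [frozenset([i]) for i in range(len(points))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            ca, cb = clusters[a], clusters[b]
            dist = np.mean(
                [
                    np.linalg.norm(points[i] - points[j])
                    for i in ca
                    for j in cb
                ]
            )
            lo, hi = sorted((min(ca), min(cb)))
            key = (dist, lo, hi)
            if best is None or key < best[0]:
                best = (key, a, b)
        (_, lo, hi), a, b = best[0], best[1], best[2]
        ca, cb = clusters[a], clusters[b]
        first, second = (ca, cb) if min(ca) <= min(cb) else (cb, ca)
        merges.append((first, second, float(best[0][0])))
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(ca | cb)
    return merges


def random_parent_map(rng: np.random.Generator, n_nodes: int) -> Dict[int, object]:
    """A uniform-ish random rooted tree on integer nodes 0..n-1."""
    parent: Dict[int, object] = {0: None}
    for v in range(1, n_nodes):
        parent[v] = int(rng.integers(0, v))
    return parent
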