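"""Agglomerative hierarchical clustering baseline (UPGMA).

UPGMA (Unweighted Pair Group Method with Arithmetic Mean) iteratively
merges the two clusters with the smallest average pairwise Euclidean
distance.  A distance threshold cuts the dendrogram into clusters (the
maximal merged groups whose internal merge heights stay at or below the
threshold); the merge structure above the cut is kept as the hierarchy,
so the result can be scored with the same average-edge-error metric as
the generative model.

The linkage is implemented here rather than delegated so that ties in
merge distance - which binary data produces constantly - follow a fixed
deterministic rule: among equally close pairs, the pair whose clusters
contain the smallest original instance indices merges first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Hashable, List, Optional, Sequence, Tuple

import numpy as np

from .evaluation import LearnedHierarchy, Taxonomy, average_edge_error
from .model import AttributeMatrix


@dataclass
class Dendrogram:
    """Merge history: (cluster_a, cluster_b, height), scipy-style ids.

    Leaves are 0..N-1; the k-th merge creates cluster N+k.  Heights are
    non-decreasing (average linkage is monotone).
    """

    merges: List[Tuple[int, int, float]]
    leaves: List[str]

    def n_leaves(self) -> int:
        return len(self.leaves)


def upgma_linkage(data) -> Dendrogram:
    """Average-linkage clustering of the rows of ``data``.

    ``data`` is an AttributeMatrix or any numeric 2-D array.
    Cluster-to-cluster distance is the arithmetic mean of pairwise
    Euclidean distances, maintained with the Lance-Williams update.
    Ties are broken toward the pair with lexicographically smallest
    (min original index of a, min original index of b).
    """
    if isinstance(data, AttributeMatrix):
        X = data.X.astype(float)
        ids = list(data.instance_ids)
    else:
        X = np.asarray(data, dtype=float)
        ids = [f"r{k}" for k in range(len(X))]
    n = len(X)
    if n < 2:
        raise ValueError("clustering needs at least two instances")
    diff = X[:, None, :] - X[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))

    # active cluster id -> (size, min original index)
    active: Dict[int, Tuple[int, int]] = {i: (1, i) for i in range(n)}
    d: Dict[Tuple[int, int], float] = {
        (i, j): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    merges: List[Tuple[int, int, float]] = []
    next_id = n
    for _ in range(n - 1):
        best = None
        for (i, j), v in d.items():
            key = (v, min(active[i][1], active[j][1]), max(active[i][1], active[j][1]))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        h = d[(i, j)]
        si, mi = active[i]
        sj, mj = active[j]
        a, b = (i, j) if mi <= mj else (j, i)
        merges.append((a, b, h))
        new = next_id
        next_id += 1
        del d[(i, j)]
        for k in list(active):
            if k in (i, j):
                continue
            dik = d.pop((min(i, k), max(i, k)))
            djk = d.pop((min(j, k), max(j, k)))
            d[(min(new, k), max(new, k))] = (si * dik + sj * djk) / (si + sj)
        del active[i], active[j]
        active[new] = (si + sj, min(mi, mj))
    return Dendrogram(merges, ids)


def cut_by_threshold(dend: Dendrogram, t: float) -> LearnedHierarchy:
    """Cut the dendrogram at height ``t`` and keep the structure above.

    Merges at height <= t form the clusters; each cluster becomes one
    node holding its instances.  Merges above the threshold become
    internal nodes joining the cluster nodes below them.
    """
    if t < 0:
        raise ValueError("threshold must be nonnegative")
    n = dend.n_leaves()
    # Heights are non-decreasing, so every below-threshold merge precedes
    # every above-threshold merge: first collapse clusters, then build the
    # retained structure on top.
    rep: Dict[int, Hashable] = {i: ("c", i) for i in range(n)}
    members: Dict[int, List[int]] = {i: [i] for i in range(n)}
    parent: Dict[Hashable, Optional[Hashable]] = {("c", i): None for i in range(n)}
    cluster_of: Dict[int, Hashable] = {i: ("c", i) for i in range(n)}
    for k, (a, b, h) in enumerate(dend.merges):
        new = n + k
        members[new] = members[a] + members[b]
        if h <= t:
            node = ("c", min(members[new]))
            for old in (rep[a], rep[b]):
                if old != node:
                    del parent[old]
            parent[node] = None
            rep[new] = node
            for leaf in members[new]:
                cluster_of[leaf] = node
        else:
            node = ("m", new)
            parent[node] = None
            parent[rep[a]] = node
            parent[rep[b]] = node
            rep[new] = node
    node_of = {dend.leaves[i]: cluster_of[i] for i in range(n)}
    return LearnedHierarchy(parent, node_of)


def threshold_sweep(
    data: AttributeMatrix,
    taxonomy: Taxonomy,
    thresholds: Sequence[float],
) -> List[Tuple[float, float]]:
    """Average edge error of the AHC baseline over a threshold grid."""
    if len(thresholds) == 0:
        raise ValueError("threshold list must be nonempty")
    if data.categories is None:
        raise ValueError("data must carry category labels")
    tax = taxonomy.with_categories(dict(zip(data.instance_ids, data.categories)))
    dend = upgma_linkage(data)
    out = []
    for t in thresholds:
        learned = cut_by_threshold(dend, t)
        out.append((float(t), average_edge_error(learned, tax)))
    return out
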