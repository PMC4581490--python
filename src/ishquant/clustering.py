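"""Stage-wise hierarchical clustering of standardized expression profiles.

Profiles within one developmental stage are compared with the Pearson
correlation distance 1 - r (a "similarity" in the 0-2 range: 0 identical
shape, 1 uncorrelated, 2 anti-correlated) and merged by unweighted average
linkage (UPGMA), where the distance between two clusters is the arithmetic
mean of all inter-member leaf distances.  Dendrograms are cut either at a
stage-specific threshold or by the main-cluster rule: split into two main
clusters, or three if the second-highest merge subdivides the larger root
branch.

UPGMA is implemented directly (rather than delegated) so that tie-breaking
is part of the contract: when several cluster pairs are equally close, the
lexicographically smallest pair of node indices merges first, making merge
sequences bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .profile_extraction import StandardizedProfile

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "ClusterAssignment",
    "pearson_distance_matrix",
    "upgma_linkage",
    "cut_dendrogram",
    "main_cluster_split",
    "order_correlation_matrix",
    "STAGE_CUTOFFS",
]

# Stage-specific dendrogram cut thresholds on the 1 - r scale, blastula
# through late planula.  Values above 1 are meaningful (anti-correlation);
# distances are deliberately not clamped to [0, 1].
STAGE_CUTOFFS = (0.7, 1.3, 1.1, 0.6, 0.9, 0.9, 0.9)


@dataclass(frozen=True)
class DistanceMatrix:
    """Square symmetric 1 - Pearson distance matrix with sample labels."""

    values: np.ndarray
    labels: tuple

    def __init__(self, values: np.ndarray, labels: Sequence[str]) -> None:
        values = np.asarray(values, dtype=float)
        labels = tuple(labels)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(labels) != values.shape[0]:
            raise ValueError("label count does not match matrix size")
        if not np.allclose(values, values.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=1e-9):
            raise ValueError("distance matrix diagonal must be zero")
        if values.min() < -1e-9 or values.max() > 2.0 + 1e-9:
            raise ValueError("1 - r distances must lie in [0, 2]")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class Dendrogram:
    """UPGMA merge tree: leaves 0..n-1, merge m creates node n+m.

    ``merges`` rows are (node_a, node_b, height, size) with node_a < node_b;
    heights are on the 1 - r scale and non-decreasing.
    """

    merges: tuple
    labels: tuple

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def to_linkage(self) -> np.ndarray:
        """SciPy-style linkage matrix (for plotting / Newick export)."""
        return np.array([[a, b, h, s] for a, b, h, s in self.merges], dtype=float)

    def children(self) -> dict:
        """node id -> (child_a, child_b, height) for internal nodes."""
        n = self.n_leaves
        return {n + m: (a, b, h) for m, (a, b, h, _) in enumerate(self.merges)}

    def leaves_under(self, node: int) -> list:
        n = self.n_leaves
        kids = self.children()
        stack, out = [node], []
        while stack:
            v = stack.pop()
            if v < n:
                out.append(v)
            else:
                a, b, _ = kids[v]
                stack.extend((b, a))
        return out

    def leaf_order(self) -> list:
        """Display order: at each merge the branch whose subtree contains the
        smallest leaf index goes left."""
        n = self.n_leaves
        if n == 1:
            return [0]
        kids = self.children()
        min_leaf: dict = {i: i for i in range(n)}
        for node in sorted(kids):
            a, b, _ = kids[node]
            min_leaf[node] = min(min_leaf[a], min_leaf[b])

        def order(node: int) -> list:
            if node < n:
                return [node]
            a, b, _ = kids[node]
            if min_leaf[b] < min_leaf[a]:
                a, b = b, a
            return order(a) + order(b)

        return order(2 * n - 2)


@dataclass(frozen=True)
class ClusterAssignment:
    """Partition of the leaves into clusters with contiguous ids from 1."""

    labels: tuple
    cluster_ids: tuple
    threshold: Optional[float] = None
    n_main: Optional[int] = None

    @property
    def n_clusters(self) -> int:
        return max(self.cluster_ids)

    def as_dict(self) -> dict:
        return dict(zip(self.labels, self.cluster_ids))

    def members(self, cluster: int) -> list:
        return [l for l, c in zip(self.labels, self.cluster_ids) if c == cluster]

    def sizes(self) -> list:
        return [self.cluster_ids.count(c) for c in range(1, self.n_clusters + 1)]


def pearson_distance_matrix(
    profiles: "Sequence[StandardizedProfile] | np.ndarray",
    labels: Optional[Sequence[str]] = None,
) -> DistanceMatrix:
    """1 - Pearson correlation between profile value vectors.

    Accepts a list of :class:`StandardizedProfile` (labels taken from
    ``sample_id``) or a 2D array of row vectors plus explicit labels.
    A constant (zero-variance) profile has no defined correlation and raises
    an error naming the sample.
    """
    if len(profiles) and isinstance(profiles[0], StandardizedProfile):
        data = np.vstack([p.values for p in profiles])
        if labels is None:
            labels = [p.sample_id or f"sample{i}" for i, p in enumerate(profiles)]
    else:
        data = np.asarray(profiles, dtype=float)
        if labels is None:
            labels = [f"sample{i}" for i in range(data.shape[0])]
    if data.shape[0] < 2:
        raise ValueError("need at least two profiles")
    sd = data.std(axis=1)
    for i, s in enumerate(sd):
        if s <= 0:
            raise ValueError(f"profile {labels[i]!r} is constant (zero variance)")
    dist = 1.0 - np.corrcoef(data)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(0.5 * (dist + dist.T), 0.0, 2.0)
    return DistanceMatrix(dist, labels)


def upgma_linkage(dist: DistanceMatrix) -> Dendrogram:
    """Unweighted pair-group average linkage.

    The distance between clusters is the arithmetic mean over all inter-leaf
    distances, maintained with Lance-Williams size-weighted updates.  Equal
    minimal distances are resolved toward the lexicographically smallest
    (node_a, node_b) pair, where node ids are creation-ordered.
    """
    n = dist.n
    size_total = 2 * n - 1
    d = np.full((size_total, size_total), np.inf)
    d[:n, :n] = dist.values
    np.fill_diagonal(d, np.inf)
    sizes = np.zeros(size_total, dtype=int)
    sizes[:n] = 1
    active = list(range(n))
    merges = []
    for m in range(n - 1):
        best = None
        for ii, a in enumerate(active):
            for b in active[ii + 1 :]:
                key = (d[a, b], a, b)
                if best is None or key < best:
                    best = key
        h, a, b = best
        new = n + m
        sizes[new] = sizes[a] + sizes[b]
        for k in active:
            if k in (a, b):
                continue
            d[new, k] = d[k, new] = (sizes[a] * d[a, k] + sizes[b] * d[b, k]) / sizes[new]
        active.remove(a)
        active.remove(b)
        active.append(new)
        merges.append((a, b, float(h), int(sizes[new])))
    return Dendrogram(tuple(merges), tuple(dist.labels))


def _assignment_from_components(
    dend: Dendrogram, components: list, threshold=None, n_main=None
) -> ClusterAssignment:
    # contiguous ids from 1, ordered by each cluster's smallest leaf index
    components = sorted(components, key=min)
    ids = np.zeros(dend.n_leaves, dtype=int)
    for cid, leaves in enumerate(components, start=1):
        for leaf in leaves:
            ids[leaf] = cid
    return ClusterAssignment(
        tuple(dend.labels), tuple(int(i) for i in ids), threshold, n_main
    )


def cut_dendrogram(dend: Dendrogram, threshold: float) -> ClusterAssignment:
    """Clusters = connected components after removing merges above ``threshold``."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    n = dend.n_leaves
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m, (a, b, h, _) in enumerate(dend.merges):
        if h <= threshold:
            node = n + m
            parent[find(a)] = node
            parent[find(b)] = node
    groups: dict = {}
    for leaf in range(n):
        groups.setdefault(find(leaf), []).append(leaf)
    return _assignment_from_components(dend, list(groups.values()), threshold=threshold)


def main_cluster_split(dend: Dendrogram) -> ClusterAssignment:
    """Two main clusters, or three if the second-highest merge subdivides the
    larger root branch.

    The root split always yields two branches.  Because UPGMA heights are
    monotone, the second-highest merge is the top merge of one of those
    branches; if that branch is the strictly larger one (by leaf count), it is
    split as well.
    """
    n = dend.n_leaves
    if n < 3:
        raise ValueError("need at least 3 leaves for a main-cluster split")
    kids = dend.children()
    root = 2 * n - 2
    a, b, _ = kids[root]

    def top_height(node: int) -> float:
        return kids[node][2] if node in kids else -np.inf

    def size(node: int) -> int:
        return len(dend.leaves_under(node))

    higher = a if top_height(a) >= top_height(b) else b
    other = b if higher == a else a
    if higher in kids and size(higher) > size(other):
        ha, hb, _ = kids[higher]
        components = [
            dend.leaves_under(other),
            dend.leaves_under(ha),
            dend.leaves_under(hb),
        ]
        n_main = 3
    else:
        components = [dend.leaves_under(a), dend.leaves_under(b)]
        n_main = 2
    return _assignment_from_components(dend, components, n_main=n_main)


def order_correlation_matrix(
    dist: DistanceMatrix, dend: Dendrogram
) -> tuple:
    """Correlation matrix (r = 1 - distance) permuted to dendrogram leaf order.

    Returns ``(corr, order, labels)`` where ``order`` indexes into the
    original sample order.
    """
    if tuple(dist.labels) != tuple(dend.labels):
        raise ValueError("distance matrix and dendrogram label sets differ")
    order = dend.leaf_order()
    corr = 1.0 - dist.values[np.ix_(order, order)]
    labels = [dist.labels[i] for i in order]
    return corr, order, labels
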