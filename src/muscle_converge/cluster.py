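"""Clustering of expression profiles: hierarchical merges, cutree, k-means.

Hierarchical clustering is a plain agglomerative procedure (Euclidean
distance; complete, single, or average linkage) with an explicit, documented
tie-break: when two candidate merges are at exactly equal height, the pair
whose first cluster was created earliest (and then whose second cluster was
created earliest) merges first. This makes dendrograms deterministic in the
input order, which matters because the pipeline reads the *first* merge of
the four group columns as the "which groups are most alike" call. The
procedure is quadratic per merge and is intended for the small item counts
it is used on (group columns, samples, DEG panels), not for genome-scale
gene trees — gene clusters come from k-means.

K-means delegates to scikit-learn (k-means++ seeding, best of n_init runs by
within-cluster sum of squares, deterministic given the seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io import GROUPS
from .normalize import ExpressionMatrix


def group_mean_z(z: ExpressionMatrix, samples: pd.DataFrame) -> pd.DataFrame:
    """Gene x group matrix of mean z-scores over each group's samples."""
    if z.transform != "zscore":
        raise ValueError(f"group_mean_z expects zscore, got {z.transform!r}")
    cols = {}
    for group in GROUPS:
        members = [s for s in samples.index[samples["group"] == group] if s in z.values.columns]
        if not members:
            raise ValueError(f"group {group!r} has no samples in the z-score matrix")
        cols[group] = z.values[members].mean(axis=1)
    return pd.DataFrame(cols)[list(GROUPS)]


@dataclass
class Dendrogram:
    """Binary merge tree: leaves 0..n-1, merge i creates node n+i.

    ``merges`` holds (left_node, right_node, height, size) in merge order;
    heights are non-decreasing for the monotone linkages used here.
    """

    labels: list[str]
    merges: list[tuple[int, int, float, int]]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> list[float]:
        return [m[2] for m in self.merges]

    def _children(self, node: int) -> tuple[int, int] | None:
        if node < self.n_leaves:
            return None
        left, right, _, _ = self.merges[node - self.n_leaves]
        return left, right

    def leaves_of(self, node: int) -> list[int]:
        kids = self._children(node)
        if kids is None:
            return [node]
        return self.leaves_of(kids[0]) + self.leaves_of(kids[1])

    def leaf_order(self) -> list[int]:
        """Left-to-right traversal of the full tree."""
        root = self.n_leaves + len(self.merges) - 1
        return self.leaves_of(root)

    def cut(self, k: int) -> pd.Series:
        """Cluster labels (1..k, numbered by first appearance in leaf order)."""
        n = self.n_leaves
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}], got {k}")
        parent = list(range(n + len(self.merges)))

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i, (left, right, _, _) in enumerate(self.merges[: n - k]):
            node = n + i
            parent[find(left)] = node
            parent[find(right)] = node
        roots: dict[int, int] = {}
        raw = {}
        for leaf in range(n):
            raw[leaf] = find(leaf)
        labels = {}
        next_id = 1
        for leaf in self.leaf_order():
            r = raw[leaf]
            if r not in roots:
                roots[r] = next_id
                next_id += 1
            labels[self.labels[leaf]] = roots[r]
        return pd.Series(labels, name="cluster").loc[self.labels]

    def first_merge_pair(self) -> tuple[str, str]:
        """Labels of the two leaves joined at the lowest height."""
        left, right, _, _ = self.merges[0]
        return (self.labels[left], self.labels[right])

    def to_newick(self) -> str:
        def render(node: int) -> tuple[str, float]:
            kids = self._children(node)
            if kids is None:
                return self.labels[node], 0.0
            height = self.merges[node - self.n_leaves][2]
            parts = []
            for kid in kids:
                text, kid_height = render(kid)
                parts.append(f"{text}:{(height - kid_height) / 2:.6g}")
            return "(" + ",".join(parts) + ")", height

        text, _ = render(self.n_leaves + len(self.merges) - 1)
        return text + ";"


def hclust(
    matrix: pd.DataFrame,
    axis: str = "rows",
    metric: str = "euclidean",
    linkage: str = "complete",
) -> Dendrogram:
    """Agglomerative clustering of the rows (or columns) of a matrix."""
    if axis not in ("rows", "columns"):
        raise ValueError(f"axis must be 'rows' or 'columns', got {axis!r}")
    if metric != "euclidean":
        raise ValueError(f"unsupported metric {metric!r}")
    if linkage not in ("complete", "single", "average"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    data = matrix.T if axis == "columns" else matrix
    labels = [str(x) for x in data.index]
    X = data.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("hclust needs at least 2 items")
    if not np.isfinite(X).all():
        raise ValueError("hclust input contains NaN or infinite values")

    diff = X[:, None, :] - X[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))

    # active clusters keyed by node id, with member leaf lists and sizes
    active: list[int] = list(range(n))
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    d: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = float(dist[i, j])

    merges: list[tuple[int, int, float, int]] = []
    for step in range(n - 1):
        # argmin with tie-break on creation order of (first, then second) cluster
        best = None
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                a, b = active[ii], active[jj]
                key = (a, b) if a < b else (b, a)
                h = d[key]
                if best is None or h < best[0]:
                    best = (h, a, b)
        h, a, b = best
        new = n + step
        merges.append((a, b, h, len(members[a]) + len(members[b])))
        merged_members = members[a] + members[b]
        for other in active:
            if other in (a, b):
                continue
            da = d[(min(a, other), max(a, other))]
            db = d[(min(b, other), max(b, other))]
            if linkage == "complete":
                dn = max(da, db)
            elif linkage == "single":
                dn = min(da, db)
            else:
                wa, wb = len(members[a]), len(members[b])
                dn = (wa * da + wb * db) / (wa + wb)
            d[(other, new)] = dn
        active = [c for c in active if c not in (a, b)] + [new]
        members.pop(a), members.pop(b)
        members[new] = merged_members
    return Dendrogram(labels=labels, merges=merges)


@dataclass
class ClusterAssignment:
    """Gene -> cluster id (1..k), with the method and seed that produced it."""

    labels: pd.Series
    method: str
    k: int
    seed: int | None = None

    def __post_init__(self) -> None:
        ids = set(self.labels.unique())
        if ids != set(range(1, self.k + 1)):
            raise ValueError(f"cluster ids must be contiguous 1..{self.k}, got {sorted(ids)}")

    def genes_in(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])


def cutree(d: Dendrogram, k: int) -> ClusterAssignment:
    """Cut a dendrogram into exactly k clusters."""
    labels = d.cut(k)
    return ClusterAssignment(labels=labels, method="cutree", k=k)


def kmeans(matrix: pd.DataFrame, k: int, seed: int = 0, n_init: int = 10) -> ClusterAssignment:
    """K-means on the rows; best of n_init k-means++ starts, seeded."""
    n = matrix.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    X = matrix.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("kmeans input contains NaN or infinite values")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    raw = km.labels_
    # renumber contiguously by first appearance so output ignores sklearn's labeling
    mapping: dict[int, int] = {}
    for lab in raw:
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
    labels = pd.Series([mapping[lab] for lab in raw], index=matrix.index, name="cluster")
    return ClusterAssignment(labels=labels, method="kmeans", k=len(mapping), seed=seed)


def column_adjacency(d: Dendrogram) -> tuple[str, str]:
    """The pair of group columns merged at the lowest height.

    The dendrogram must be over exactly the four group columns; the first
    merge identifies the two most alike groups (the diet-linked pair
    (SDGF, SDGM) under convergence).
    """
    if d.n_leaves != 4:
        raise ValueError(f"column_adjacency expects a 4-leaf dendrogram, got {d.n_leaves}")
    left, right, _, _ = d.merges[0]
    if left >= 4 or right >= 4:
        raise ValueError("first merge is not between two leaves")
    return (d.labels[left], d.labels[right])
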