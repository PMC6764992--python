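"""Mapper topological summarisation of an embedded point cloud.

The classic three-step construction: bin a scalar filter function into
``n_f`` overlapping intervals, single-linkage-cluster the points of each
slice at threshold ``t``, and take the nerve of the resulting cluster cover
(nodes = slice clusters, edges = overlapping clusters from distinct bins).

Two filter functions are built in: closeness centrality on a symmetrized
k-nearest-neighbour graph of the point cloud (the general-purpose default),
and Mahalanobis distance from a control point set (a deviation-from-normal
filter for progression-style analyses).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator
from sklearn.neighbors import kneighbors_graph

from .errors import ValidationError


@dataclass(frozen=True)
class FilterValues:
    """Finite scalar filter values, one per sample."""

    values: np.ndarray
    provenance: str = "user"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValidationError("filter values must be a 1-D array")
        if not np.all(np.isfinite(v)):
            raise ValidationError("filter values must be finite")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class MapperCover:
    """``n_f`` overlapping closed intervals covering [min f, max f]."""

    intervals: tuple[tuple[float, float], ...]
    n_intervals: int
    overlap: float

    def membership(self, f: np.ndarray) -> list[np.ndarray]:
        """Indices of points falling in each interval (closed on both ends)."""
        f = np.asarray(f, dtype=float)
        return [
            np.flatnonzero((f >= lo) & (f <= hi)) for lo, hi in self.intervals
        ]


@dataclass(frozen=True)
class MapperNode:
    """One slice cluster: bin index, member sample positions, mean filter."""

    bin_index: int
    members: tuple[int, ...]
    mean_filter: float


@dataclass(frozen=True)
class MapperComplex:
    """Nerve of the slice-cluster cover (nodes, weighted edges, 2-simplices)."""

    nodes: tuple[MapperNode, ...]
    edges: dict = field(default_factory=dict)  # (i, j) -> overlap count
    triangles: tuple[tuple[int, int, int], ...] = ()

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_json(self) -> str:
        payload = {
            "nodes": [
                {
                    "id": i,
                    "bin": n.bin_index,
                    "members": list(n.members),
                    "mean_filter": n.mean_filter,
                }
                for i, n in enumerate(self.nodes)
            ],
            "edges": [
                {"source": i, "target": j, "overlap": o}
                for (i, j), o in sorted(self.edges.items())
            ],
            "triangles": [list(t) for t in self.triangles],
        }
        return json.dumps(payload, indent=1)


def centrality_filter(points: np.ndarray, k: int) -> FilterValues:
    """Closeness centrality on the symmetrized k-nearest-neighbour graph.

    Edges carry Euclidean lengths; ``f(i) = (N - 1) / Σ_j d_graph(i, j)``.
    Raises if the kNN graph is disconnected (increase ``k``) or if all
    points coincide.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = points.shape[0]
    if not 1 <= k < n:
        raise ValidationError(f"need 1 <= k < n_samples; got k={k}, n={n}")
    if np.allclose(pdist(points), 0):
        raise ValidationError("degenerate metric: all points coincide")
    knn = kneighbors_graph(points, k, mode="distance")
    sym = knn.maximum(knn.T)
    d = shortest_path(sym, directed=False)
    if not np.all(np.isfinite(d)):
        raise ValidationError(
            "k-nearest-neighbour graph is disconnected; increase k"
        )
    f = (n - 1) / d.sum(axis=1)
    return FilterValues(f, provenance="centrality")


def mahalanobis_filter(
    points: np.ndarray, control: np.ndarray, ridge: float = 0.0
) -> FilterValues:
    """Mahalanobis distance of each point from a control cohort.

    Uses the control's mean and population covariance; requires more control
    points than dimensions.  ``ridge`` adds a multiple of the identity to a
    singular covariance.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    control = np.atleast_2d(np.asarray(control, dtype=float))
    m = points.shape[1]
    if control.shape[1] != m:
        raise ValidationError("control and points dimension mismatch")
    if control.shape[0] <= m + 1:
        raise ValidationError(
            f"control size {control.shape[0]} too small for dimension {m}"
        )
    mu = control.mean(axis=0)
    xc = control - mu
    cov = xc.T @ xc / control.shape[0]
    if ridge:
        cov = cov + ridge * np.eye(m)
    try:
        inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        raise ValidationError(
            "singular control covariance; pass a positive ridge"
        ) from None
    diff = points - mu
    f = np.sqrt(np.einsum("ij,jk,ik->i", diff, inv, diff))
    return FilterValues(f, provenance="mahalanobis")


def build_cover(f, n_f: int, g: float = 0.5) -> MapperCover:
    """Overlapping interval cover of the filter range.

    Base width ``l = (max f - min f) / n_f``; interval ``i`` is
    ``[min + i*l - g*l/2, min + (i+1)*l + g*l/2]`` clipped to the range.
    """
    values = f.values if isinstance(f, FilterValues) else np.asarray(f, dtype=float)
    if n_f < 1:
        raise ValidationError("n_f must be >= 1")
    if not 0 <= g < 1:
        raise ValidationError("overlap fraction must lie in [0, 1)")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi and n_f > 1:
        raise ValidationError("filter has no range")
    width = (hi - lo) / n_f
    pad = g * width / 2.0
    intervals = []
    for i in range(n_f):
        a = max(lo, lo + i * width - pad)
        b = min(hi, lo + (i + 1) * width + pad)
        intervals.append((a, b))
    return MapperCover(tuple(intervals), n_f, g)


def slice_cluster(points, t: float, metric: str = "euclidean") -> list[np.ndarray]:
    """Single-linkage clusters of one slice, cut at height ``t``.

    Equivalent to connected components of the graph with an edge wherever
    the pairwise distance is ≤ t.  ``metric="precomputed"`` interprets
    ``points`` as a square distance matrix.
    """
    if t <= 0:
        raise ValidationError("linkage threshold t must be positive")
    if metric == "precomputed":
        D = np.asarray(points, dtype=float)
        n = D.shape[0]
        condensed = squareform(D, checks=False) if n > 1 else None
    else:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        n = pts.shape[0]
        condensed = pdist(pts) if n > 1 else None
    if n == 0:
        return []
    if n == 1:
        return [np.array([0])]
    labels = fcluster(linkage(condensed, method="single"), t, criterion="distance")
    return [np.flatnonzero(labels == lab) for lab in np.unique(labels)]


def nerve(
    partitions: list[list[np.ndarray]],
    filter_values: FilterValues | np.ndarray,
    min_overlap: int = 1,
    triangles: bool = False,
) -> MapperComplex:
    """Nerve of the cover: one node per slice cluster, edges for overlaps.

    ``partitions[b]`` lists the clusters of bin ``b`` as arrays of global
    sample positions.  Edges join clusters from distinct bins sharing at
    least ``min_overlap`` samples; with ``triangles`` set, 2-simplices are
    recorded for triples with a common sample.
    """
    f = filter_values.values if isinstance(filter_values, FilterValues) else np.asarray(filter_values)
    nodes: list[MapperNode] = []
    member_sets: list[frozenset[int]] = []
    for b, clusters in enumerate(partitions):
        for cluster in clusters:
            members = tuple(int(i) for i in np.sort(cluster))
            nodes.append(MapperNode(b, members, float(np.mean(f[list(members)]))))
            member_sets.append(frozenset(members))
    edges: dict[tuple[int, int], int] = {}
    for i, j in combinations(range(len(nodes)), 2):
        if nodes[i].bin_index == nodes[j].bin_index:
            continue
        shared = len(member_sets[i] & member_sets[j])
        if shared >= min_overlap:
            edges[(i, j)] = shared
    tris: list[tuple[int, int, int]] = []
    if triangles:
        for i, j, k in combinations(range(len(nodes)), 3):
            if (i, j) in edges and (j, k) in edges and (i, k) in edges:
                if member_sets[i] & member_sets[j] & member_sets[k]:
                    tris.append((i, j, k))
    return MapperComplex(tuple(nodes), edges, tuple(tris))


class Mapper(BaseEstimator):
    """Mapper state-graph estimator over an embedded point cloud.

    ``fit(X)`` computes the filter, cover, per-slice clustering and nerve,
    then extracts the state graph (linear-path decomposition) and a
    per-maximal-path sample grouping exposed as ``labels_``.

    Parameters
    ----------
    filter:
        ``"centrality"`` (default), ``"mahalanobis"``, or ``"user"`` (pass
        ``filter_values`` to ``fit``).
    n_neighbors:
        k for the centrality filter's kNN graph.
    control:
        Control coordinates for the Mahalanobis filter.
    n_intervals, overlap:
        Cover resolution ``n_f`` and overlap fraction ``g``.
    threshold:
        Single-linkage cut height ``t`` within each slice.
    min_overlap:
        Minimum shared samples for a nerve edge.
    cluster_distances:
        Optional precomputed full pairwise distance matrix; slices are then
        clustered on its restriction instead of embedding Euclidean
        distances.
    """

    def __init__(self, *, filter: str = "centrality", n_neighbors: int = 5,
                 control=None, ridge: float = 0.0, n_intervals: int = 6,
                 overlap: float = 0.5, threshold: float = 1.0,
                 min_overlap: int = 1, triangles: bool = False,
                 cluster_distances=None):
        self.filter = filter
        self.n_neighbors = n_neighbors
        self.control = control
        self.ridge = ridge
        self.n_intervals = n_intervals
        self.overlap = overlap
        self.threshold = threshold
        self.min_overlap = min_overlap
        self.triangles = triangles
        self.cluster_distances = cluster_distances

    def _filter(self, X, filter_values) -> FilterValues:
        if filter_values is not None:
            if isinstance(filter_values, FilterValues):
                return filter_values
            return FilterValues(np.asarray(filter_values, dtype=float))
        if self.filter == "centrality":
            return centrality_filter(X, self.n_neighbors)
        if self.filter == "mahalanobis":
            if self.control is None:
                raise ValidationError("mahalanobis filter requires control points")
            return mahalanobis_filter(X, self.control, self.ridge)
        raise ValidationError(
            f"filter {self.filter!r} requires explicit filter_values"
        )

    def fit(self, X, y=None, filter_values=None):
        from .stategraph import decompose_paths, group_labels, order_samples

        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = X.shape[0]
        fv = self._filter(X, filter_values)
        if len(fv.values) != n:
            raise ValidationError("filter values do not match sample count")
        cover = build_cover(fv, self.n_intervals, self.overlap)
        partitions = []
        for idx in cover.membership(fv.values):
            if self.cluster_distances is not None:
                D = np.asarray(self.cluster_distances)[np.ix_(idx, idx)]
                local = slice_cluster(D, self.threshold, metric="precomputed")
            else:
                local = slice_cluster(X[idx], self.threshold)
            partitions.append([idx[c] for c in local])
        complex_ = nerve(partitions, fv, self.min_overlap, self.triangles)
        self.filter_values_ = fv
        self.cover_ = cover
        self.partitions_ = partitions
        self.complex_ = complex_
        self.state_graph_ = decompose_paths(complex_)
        self.sample_order_ = order_samples(self.state_graph_, fv)
        self.labels_ = group_labels(self.state_graph_, n)
        return self

    def fit_predict(self, X, y=None, filter_values=None) -> np.ndarray:
        return self.fit(X, filter_values=filter_values).labels_
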