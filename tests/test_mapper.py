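import numpy as np
import pytest

from wassermap.errors import ValidationError
from wassermap.mapper import (
    FilterValues,
    Mapper,
    build_cover,
    centrality_filter,
    mahalanobis_filter,
    nerve,
    slice_cluster,
)
from wassermap.pipeline import pick_stable, scan_parameters


def threshold_graph_components(points, t):
    """Brute-force oracle: connected components of the <=t graph."""
    n = len(points)
    D = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if D[i, j] <= t:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(sorted(g) for g in groups.values())


class TestCentralityFilter:
    def test_three_collinear_points(self):
        pts = np.array([[0.0], [1.0], [2.0]])
        f = centrality_filter(pts, k=1)
        np.testing.assert_allclose(f.values, [2 / 3, 1.0, 2 / 3])

    def test_coincident_points_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            centrality_filter(np.zeros((4, 2)), k=1)

    def test_symmetric_configuration_gives_equal_values(self):
        pts = np.array([[-1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        f = centrality_filter(pts, k=3)
        assert f.values[0] == pytest.approx(f.values[1])
        assert f.values[2] == pytest.approx(f.values[3])

    def test_disconnected_knn_graph_instructs_larger_k(self):
        pts = np.vstack(
            [np.random.default_rng(0).normal(0, 0.01, (5, 2)),
             np.random.default_rng(1).normal(100, 0.01, (5, 2))]
        )
        with pytest.raises(ValidationError, match="increase k"):
            centrality_filter(pts, k=2)


class TestMahalanobisFilter:
    def test_identity_covariance_equals_euclidean(self, rng):
        control = rng.normal(size=(500, 2))
        control = (control - control.mean(0)) / control.std(0)
        f = mahalanobis_filter(np.array([[3.0, 4.0]]), control)
        mu = control.mean(0)
        expected = np.linalg.norm(np.array([3.0, 4.0]) - mu)
        assert f.values[0] == pytest.approx(expected, rel=0.05)

    def test_control_mean_maps_to_zero(self, rng):
        control = rng.normal(size=(50, 3))
        f = mahalanobis_filter(control.mean(0, keepdims=True), control)
        assert f.values[0] == pytest.approx(0.0, abs=1e-10)

    def test_one_dimensional_hand_case(self):
        control = np.array([[-1.0], [1.0], [-1.0], [1.0]])  # population var 1
        f = mahalanobis_filter(np.array([[3.0]]), control)
        assert f.values[0] == pytest.approx(3.0)

    def test_small_control_rejected(self):
        with pytest.raises(ValidationError, match="too small"):
            mahalanobis_filter(np.zeros((1, 2)), np.zeros((3, 2)))

    def test_singular_covariance_needs_ridge(self):
        control = np.tile([[1.0, 2.0]], (10, 1))
        with pytest.raises(ValidationError, match="ridge"):
            mahalanobis_filter(np.array([[0.0, 0.0]]), control)
        f = mahalanobis_filter(np.array([[1.0, 2.0]]), control, ridge=1e-3)
        assert f.values[0] == pytest.approx(0.0)


class TestBuildCover:
    def test_disjoint_halves(self):
        cover = build_cover(np.array([0.0, 1.0]), 2, 0.0)
        assert cover.intervals == ((0.0, 0.5), (0.5, 1.0))

    def test_half_overlap(self):
        cover = build_cover(np.array([0.0, 1.0]), 2, 0.5)
        np.testing.assert_allclose(cover.intervals, [(0.0, 0.625), (0.375, 1.0)])

    def test_single_interval_any_overlap(self):
        cover = build_cover(np.array([2.0, 5.0]), 1, 0.7)
        assert cover.intervals == ((2.0, 5.0),)

    def test_constant_filter_rejected(self):
        with pytest.raises(ValidationError, match="no range"):
            build_cover(np.array([1.0, 1.0]), 2)

    def test_every_point_in_one_or_two_bins(self, rng):
        f = rng.uniform(size=40)
        cover = build_cover(f, 5, 0.5)
        counts = np.zeros(40, dtype=int)
        for idx in cover.membership(f):
            counts[idx] += 1
        assert np.all(counts >= 1) and np.all(counts <= 2)

    def test_boundary_membership_closed(self):
        f = np.array([0.0, 0.5, 1.0])
        cover = build_cover(f, 2, 0.0)
        member = cover.membership(f)
        assert 1 in member[0] and 1 in member[1]


class TestSliceCluster:
    def test_two_near_one_far(self):
        parts = slice_cluster(np.array([[0.0], [0.1], [5.0]]), t=1.0)
        assert sorted(tuple(p) for p in parts) == [(0, 1), (2,)]

    def test_all_far_apart_all_singletons(self):
        parts = slice_cluster(np.array([[0.0], [10.0], [20.0]]), t=1.0)
        assert all(len(p) == 1 for p in parts)

    def test_empty_and_singleton_slices(self):
        assert slice_cluster(np.empty((0, 2)), 1.0) == []
        (only,) = slice_cluster(np.array([[1.0, 2.0]]), 1.0)
        assert list(only) == [0]

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_threshold_graph_components(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(size=(int(rng.integers(2, 11)), 2))
        t = float(rng.uniform(0.05, 0.8))
        parts = slice_cluster(pts, t)
        ours = sorted(sorted(int(i) for i in p) for p in parts)
        assert ours == threshold_graph_components(pts, t)

    def test_increasing_t_only_merges(self, rng):
        pts = rng.uniform(size=(12, 2))
        small = slice_cluster(pts, 0.1)
        large = slice_cluster(pts, 0.4)
        for cluster in small:
            holders = [
                big for big in large if set(cluster) <= set(big)
            ]
            assert len(holders) == 1


class TestNerve:
    def test_single_shared_sample_links(self):
        parts = [[np.array([0, 1])], [np.array([1, 2])]]
        complex_ = nerve(parts, np.zeros(3))
        assert complex_.n_nodes == 2
        assert complex_.edges == {(0, 1): 1}

    def test_disjoint_clusters_unlinked(self):
        parts = [[np.array([0])], [np.array([1])]]
        complex_ = nerve(parts, np.zeros(2))
        assert complex_.n_edges == 0

    def test_min_overlap_threshold(self):
        parts = [[np.array([0, 1, 2])], [np.array([1, 2, 3])]]
        assert nerve(parts, np.zeros(4), min_overlap=3).n_edges == 0
        assert nerve(parts, np.zeros(4), min_overlap=2).n_edges == 1

    def test_triangles_recorded_when_requested(self):
        parts = [[np.array([0, 1])], [np.array([0, 2])], [np.array([0, 3])]]
        complex_ = nerve(parts, np.zeros(4), triangles=True)
        assert complex_.triangles == ((0, 1, 2),)


class TestMapperEstimator:
    def circle_points(self, n=100, seed=5):
        rng = np.random.default_rng(seed)
        theta = rng.uniform(0, 2 * np.pi, n)
        return np.c_[np.cos(theta), np.sin(theta)]

    def test_circle_recovers_one_cycle(self):
        """The classic Mapper sanity check: points on a circle with the
        first-coordinate filter produce a nerve with exactly one
        independent cycle."""
        pts = self.circle_points()
        f = FilterValues(pts[:, 0])
        table = scan_parameters(pts, f, [4], np.linspace(0.05, 1.2, 24), 0.5)
        _, t = pick_stable(table)
        est = Mapper(filter="user", n_intervals=4, overlap=0.5, threshold=t)
        est.fit(pts, filter_values=f)
        complex_ = est.complex_
        n_components = len(
            set(
                frozenset(c)
                for c in _components(complex_.n_nodes, complex_.edges)
            )
        )
        cycles = complex_.n_edges - complex_.n_nodes + n_components
        assert cycles == 1

    def test_every_sample_covered(self, rng):
        pts = rng.normal(size=(40, 2))
        est = Mapper(filter="user", n_intervals=5, overlap=0.5, threshold=10.0)
        est.fit(pts, filter_values=pts[:, 0])
        covered = set()
        for node in est.complex_.nodes:
            covered.update(node.members)
        assert covered == set(range(40))

    def test_single_blob_gives_short_path(self, rng):
        """A single dense blob yields one cluster per bin, hence a path
        graph of at most n_f nodes and no branch points."""
        pts = rng.normal(size=(60, 2))
        est = Mapper(filter="user", n_intervals=4, overlap=0.5, threshold=50.0)
        est.fit(pts, filter_values=pts[:, 0])
        assert est.complex_.n_nodes <= 4
        assert est.state_graph_.branch_nodes == ()
        assert est.state_graph_.n_paths == 1

    def test_labels_partition_samples(self, rng):
        pts = np.vstack([rng.normal(0, 0.1, (20, 2)), rng.normal(5, 0.1, (20, 2))])
        est = Mapper(filter="user", n_intervals=3, overlap=0.5, threshold=1.0)
        est.fit(pts, filter_values=pts[:, 1])
        assert est.labels_.shape == (40,)
        assert np.all(est.labels_ >= 0)


def _components(n_nodes, edges):
    adj = {i: set() for i in range(n_nodes)}
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    seen, comps = set(), []
    for i in range(n_nodes):
        if i in seen:
            continue
        comp, stack = {i}, [i]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in comp:
                    comp.add(v)
                    stack.append(v)
        seen |= comp
        comps.append(comp)
    return comps
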