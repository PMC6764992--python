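import itertools

import numpy as np
import pytest

from wassermap.errors import ValidationError
from wassermap.network import from_edges, ground_metric
from wassermap.transport import (
    NodeDistribution,
    WassersteinNetworkMetric,
    distance_matrix,
    emd_component,
    emd_component_hungarian,
    sample_distance,
    to_distribution,
)

from .conftest import make_matrix, random_connected_network
from .oracles import emd_network_simplex_oracle, path_cdf_closed_form


class TestToDistribution:
    def test_uniform_density(self):
        g = from_edges([("A", "B")])
        d = to_distribution(np.array([2.0, 2.0]), g)
        np.testing.assert_allclose(d.masses[0], [0.5, 0.5])

    def test_per_component_normalization(self):
        g = from_edges([("A", "B")], nodes=["A", "B", "C"])
        d = to_distribution(np.array([1.0, 0.0, 3.0]), g)
        np.testing.assert_allclose(d.masses[0], [1.0, 0.0])
        np.testing.assert_allclose(d.masses[1], [1.0])

    def test_zero_component_rejected_without_pseudocount(self):
        g = from_edges([("A", "B")], nodes=["A", "B", "C"])
        with pytest.raises(ValidationError, match="empty component"):
            to_distribution(np.array([1.0, 1.0, 0.0]), g)
        d = to_distribution(np.array([1.0, 1.0, 0.0]), g, pseudocount=0.1)
        np.testing.assert_allclose(d.masses[1], [1.0])

    def test_invariant_measure_matches_power_iteration(self, triangle):
        x = np.array([1.0, 1.0, 2.0])
        d = to_distribution(x, triangle, mode="invariant_measure")
        # oracle: power-iterate the literal lazy transition matrix
        P = np.array(
            [[0, 1 / 3, 2 / 3], [1 / 3, 0, 2 / 3], [1 / 2, 1 / 2, 0]]
        )
        P = 0.5 * np.eye(3) + 0.5 * P
        pi = np.full(3, 1 / 3)
        for _ in range(20000):
            pi = pi @ P
        np.testing.assert_allclose(d.masses[0], pi, atol=1e-10)

    def test_invariant_measure_is_stationary_and_positive(self, rng):
        g = random_connected_network(rng, 6, edge_prob=0.4)
        x = rng.uniform(0.1, 5.0, size=6)
        d = to_distribution(x, g, mode="invariant_measure", pseudocount=0.5)
        pi = d.masses[0]
        assert np.all(pi > 0)
        # rebuild the lazy walk and check pi P = pi
        comp = g.components[0]
        local = {n: i for i, n in enumerate(comp)}
        order = {n: i for i, n in enumerate(g.nodes)}
        xv = np.array([x[order[n]] for n in comp]) + 0.5
        P = np.zeros((6, 6))
        for u in comp:
            nbrs = [local[v] for v in g.graph.neighbors(u)]
            P[local[u], nbrs] = xv[nbrs] / xv[nbrs].sum()
        P = 0.5 * np.eye(6) + 0.5 * P
        np.testing.assert_allclose(pi @ P, pi, atol=1e-8)

    def test_negative_values_rejected(self, path3):
        with pytest.raises(ValidationError):
            to_distribution(np.array([1.0, -0.5, 1.0]), path3)


class TestEmdComponent:
    def test_identity_of_indiscernibles(self, rng):
        g = random_connected_network(rng, 5)
        G = ground_metric(g).matrices[0]
        p = rng.dirichlet(np.ones(5))
        assert emd_component(p, p, G) == pytest.approx(0.0, abs=1e-9)

    def test_all_mass_across_unit_path(self, path3):
        G = ground_metric(path3).matrices[0]
        assert emd_component([1, 0, 0], [0, 0, 1], G) == pytest.approx(2.0)

    def test_half_mass_shift_on_path(self, path3):
        G = ground_metric(path3).matrices[0]
        d = emd_component([0.5, 0.5, 0], [0, 0.5, 0.5], G)
        assert d == pytest.approx(1.0, abs=1e-8)

    def test_star_leaves_to_center(self, star4):
        gm = ground_metric(star4)
        order = gm.component_nodes[0]
        p = np.array([1 / 3 if n.startswith("L") else 0.0 for n in order])
        q = np.array([1.0 if n == "H" else 0.0 for n in order])
        assert emd_component(p, q, gm.matrices[0]) == pytest.approx(1.0, abs=1e-8)

    def test_mass_mismatch_rejected(self, path3):
        G = ground_metric(path3).matrices[0]
        with pytest.raises(ValidationError, match="mismatch"):
            emd_component([1, 0, 0], [0, 0, 0.5], G)

    def test_negative_mass_rejected(self, path3):
        G = ground_metric(path3).matrices[0]
        with pytest.raises(ValidationError):
            emd_component([1.5, -0.5, 0], [0, 0, 1], G)

    @pytest.mark.parametrize("seed", range(30))
    def test_agrees_with_network_simplex_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        g = random_connected_network(rng, n, edge_prob=0.4, weighted=bool(seed % 2))
        G = ground_metric(g).matrices[0]
        p = rng.dirichlet(np.ones(n))
        q = rng.dirichlet(np.ones(n))
        ours = emd_component(p, q, G)
        oracle = emd_network_simplex_oracle(p, q, G)
        assert ours == pytest.approx(oracle, abs=1e-6)

    @pytest.mark.parametrize("seed", range(20))
    def test_path_graph_cdf_closed_form(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(2, 9))
        names = [f"n{i}" for i in range(n)]
        g = from_edges([(names[i], names[i + 1]) for i in range(n - 1)])
        G = ground_metric(g).matrices[0]
        p = rng.dirichlet(np.ones(n))
        q = rng.dirichlet(np.ones(n))
        assert emd_component(p, q, G) == pytest.approx(
            path_cdf_closed_form(p, q), abs=1e-9
        )

    def test_bounded_by_component_diameter(self, rng):
        for _ in range(10):
            n = int(rng.integers(2, 7))
            g = random_connected_network(rng, n, weighted=True)
            G = ground_metric(g).matrices[0]
            p = rng.dirichlet(np.ones(n))
            q = rng.dirichlet(np.ones(n))
            assert emd_component(p, q, G) <= G.max() + 1e-9

    def test_hungarian_quantization_converges_to_lp(self, rng):
        n = 5
        g = random_connected_network(rng, n, edge_prob=0.5)
        G = ground_metric(g).matrices[0]
        p = rng.dirichlet(np.ones(n))
        q = rng.dirichlet(np.ones(n))
        exact = emd_component(p, q, G)
        coarse = emd_component_hungarian(p, q, G, resolution=50)
        fine = emd_component_hungarian(p, q, G, resolution=2000)
        assert abs(fine - exact) <= abs(coarse - exact) + 1e-9
        assert fine == pytest.approx(exact, abs=5e-3)


class TestSampleDistance:
    def test_single_component_equals_emd(self, path3, rng):
        gm = ground_metric(path3)
        p = rng.dirichlet(np.ones(3))
        q = rng.dirichlet(np.ones(3))
        a = NodeDistribution((p,), (False,))
        b = NodeDistribution((q,), (False,))
        assert sample_distance(a, b, gm) == pytest.approx(
            emd_component(p, q, gm.matrices[0])
        )

    def test_direct_sum_is_pythagorean(self):
        # components: two unit-edge paths scaled so EMDs are 3 and 4
        g = from_edges([("A", "B", 1 / 3), ("C", "D", 0.25)])
        gm = ground_metric(g)
        a = NodeDistribution((np.array([1.0, 0]), np.array([1.0, 0])), (False, False))
        b = NodeDistribution((np.array([0, 1.0]), np.array([0, 1.0])), (False, False))
        assert sample_distance(a, b, gm) == pytest.approx(5.0)

    def test_empty_in_exactly_one_rejected(self):
        g = from_edges([("A", "B")], nodes=["A", "B", "C"])
        gm = ground_metric(g)
        a = NodeDistribution((np.array([0.5, 0.5]), np.array([1.0])), (False, False))
        b = NodeDistribution((np.array([0.5, 0.5]), np.array([0.0])), (False, True))
        with pytest.raises(ValidationError, match="incomparable"):
            sample_distance(a, b, gm)

    def test_empty_in_both_contributes_zero(self):
        g = from_edges([("A", "B")], nodes=["A", "B", "C"])
        gm = ground_metric(g)
        a = NodeDistribution((np.array([1.0, 0.0]), np.array([0.0])), (False, True))
        b = NodeDistribution((np.array([0.0, 1.0]), np.array([0.0])), (False, True))
        assert sample_distance(a, b, gm) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_metric_axioms_on_random_triples(self, seed):
        rng = np.random.default_rng(200 + seed)
        n = int(rng.integers(3, 7))
        g = random_connected_network(rng, n, edge_prob=0.4)
        gm = ground_metric(g)
        dists = [
            NodeDistribution((rng.dirichlet(np.ones(n)),), (False,))
            for _ in range(3)
        ]
        d = {
            (i, j): sample_distance(dists[i], dists[j], gm)
            for i, j in itertools.combinations(range(3), 2)
        }
        for (i, j), val in d.items():
            assert val == pytest.approx(
                sample_distance(dists[j], dists[i], gm), abs=1e-10
            )
            assert val >= 0
        assert d[(0, 2)] <= d[(0, 1)] + d[(1, 2)] + 1e-8
        assert d[(0, 1)] <= d[(0, 2)] + d[(1, 2)] + 1e-8
        assert d[(1, 2)] <= d[(0, 1)] + d[(0, 2)] + 1e-8


class TestDistanceMatrix:
    def test_single_sample(self, path3):
        m = make_matrix([[1.0], [2.0], [3.0]], genes=["A", "B", "C"])
        D = distance_matrix(m, path3)
        assert D.D.shape == (1, 1) and D.D[0, 0] == 0

    def test_identical_samples_are_at_distance_zero(self, path3):
        m = make_matrix([[1, 1], [2, 2], [3, 3]], genes=["A", "B", "C"])
        D = distance_matrix(m, path3)
        assert D.D[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_network_location_beats_euclidean_ambiguity(self, path6):
        """Samples active on overlapping node sets are Wasserstein-close;
        samples active far apart on the path are Wasserstein-far — even when
        the Euclidean gaps are identical."""
        genes = list(path6.nodes)
        s1 = [1.0, 1.0, 0.0, 0.0, 0.0, 0.0]
        s2 = [1.0, 0.0, 1.0, 0.0, 0.0, 0.0]
        s3 = [1.0, 0.0, 0.0, 0.0, 0.0, 1.0]
        m = make_matrix(np.array([s1, s2, s3]).T, genes=genes, samples=["s1", "s2", "s3"])
        euclid_near = np.linalg.norm(np.array(s1) - np.array(s2))
        euclid_far = np.linalg.norm(np.array(s2) - np.array(s3))
        assert euclid_near == pytest.approx(euclid_far)
        D = distance_matrix(m, path6)
        near = D.D[0, 1]
        far = D.D[1, 2]
        assert near == pytest.approx(0.5, abs=1e-8)
        assert far == pytest.approx(1.5, abs=1e-8)
        assert near < far

    def test_error_names_offending_sample(self, path3):
        m = make_matrix([[0, 1], [0, 1], [0, 1]], genes=["A", "B", "C"])
        with pytest.raises(ValidationError, match="s0"):
            distance_matrix(m, path3)

    def test_requires_gene_alignment(self, path3):
        m = make_matrix([[1, 2]], genes=["A"])
        with pytest.raises(ValidationError, match="restrict"):
            distance_matrix(m, path3)


class TestWassersteinNetworkMetricEstimator:
    def test_fit_transform_matches_distance_matrix(self, path6, rng):
        X = rng.uniform(0.1, 5.0, size=(4, 6))
        est = WassersteinNetworkMetric(path6)
        D = est.fit_transform(X)
        m = make_matrix(X.T, genes=list(path6.nodes))
        expected = distance_matrix(m, path6).D
        np.testing.assert_allclose(D, expected, atol=1e-12)

    def test_transform_against_fitted_samples(self, path6, rng):
        X = rng.uniform(0.1, 5.0, size=(3, 6))
        est = WassersteinNetworkMetric(path6).fit(X)
        row = est.transform(X[:1])
        assert row.shape == (1, 3)
        assert row[0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_sklearn_params_roundtrip(self, path6):
        est = WassersteinNetworkMetric(path6, mode="density", pseudocount=0.5)
        params = est.get_params()
        assert params["pseudocount"] == 0.5
        est.set_params(pseudocount=1.0)
        assert est.pseudocount == 1.0
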