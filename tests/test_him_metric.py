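import itertools

import numpy as np
import pytest

from himnet.graph import cycle_graph, empty_graph, full_graph, graph_from_edges
from himnet.him import (
    HIMParams,
    SpectralDensity,
    calibrate_gamma_bar,
    epsilon_gamma,
    hamming_distance,
    him_distance,
    him_similarity,
    im_distance,
    pairwise_him_matrix,
    worked_example_graphs,
)

from conftest import random_binary_graph, random_weighted_graph

# regression constant: bisection/Brent oracle at tolerance 1e-12
GAMMA_BAR_6 = 0.434749181077


class TestHamming:
    def test_empty_vs_full_is_one(self):
        assert hamming_distance(empty_graph(6), full_graph(6)) == 1.0

    def test_identity(self, rng):
        g = random_weighted_graph(8, rng)
        assert hamming_distance(g, g) == 0.0

    def test_one_differing_edge_counts_twice(self):
        g1 = graph_from_edges(3, [(0, 1)], "abc")
        g2 = graph_from_edges(3, [(0, 1), (1, 2)], "abc")
        assert hamming_distance(g1, g2) == pytest.approx(2 / 6)

    def test_mismatched_node_sets_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            hamming_distance(empty_graph(4, "abcd"), empty_graph(4, "abce"))


class TestSpectralDensity:
    @pytest.mark.parametrize("maker", [lambda: empty_graph(6), lambda: full_graph(6), lambda: cycle_graph(7)])
    def test_density_integrates_to_one(self, maker):
        from scipy.integrate import quad

        rho = SpectralDensity.from_graph(maker(), gamma=0.45)
        w_hi = float(rho.omegas.max(initial=0.0)) + 50 * 0.45
        body, _ = quad(lambda w: float(rho(w)[0]), 0, w_hi, limit=300)
        tail, _ = quad(lambda w: float(rho(w)[0]), w_hi, np.inf, limit=200)
        assert body + tail == pytest.approx(1.0, abs=1e-8)

    def test_density_integrates_to_one_random_graph(self, rng):
        from scipy.integrate import quad

        rho = SpectralDensity.from_graph(random_weighted_graph(8, rng), gamma=0.3)
        total = quad(lambda w: float(rho(w)[0]), 0, np.inf, limit=500)[0]
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError, match="gamma"):
            SpectralDensity(np.zeros(3), 0.0)


class TestEpsilonGamma:
    def test_zero_for_identical_graph(self, rng):
        g = random_binary_graph(8, 0.4, rng)
        assert epsilon_gamma(g, g, 0.5) == pytest.approx(0.0, abs=1e-12)

    def test_calibrated_endpoint_pair_equals_one(self):
        gb = calibrate_gamma_bar(6)
        assert epsilon_gamma(empty_graph(6), full_graph(6), gb) == pytest.approx(1.0, abs=1e-10)

    def test_zero_for_relabeled_graph(self):
        g = cycle_graph(6)
        perm = [2, 3, 4, 5, 0, 1]
        edges = [(perm[i], perm[(i + 1) % 6]) for i in range(6)]
        g2 = graph_from_edges(6, edges)
        assert epsilon_gamma(g, g2, 0.45) == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_closed_form_matches_quadrature(self, seed):
        rng = np.random.default_rng(seed)
        g1 = random_weighted_graph(7, rng)
        g2 = random_binary_graph(7, 0.4, rng)
        e_closed = epsilon_gamma(g1, g2, 0.45, method="closed")
        e_quad = epsilon_gamma(g1, g2, 0.45, method="quad")
        assert e_closed == pytest.approx(e_quad, abs=1e-8)

    def test_nonpositive_gamma_rejected(self):
        with pytest.raises(ValueError, match="gamma"):
            epsilon_gamma(empty_graph(4), full_graph(4), -0.1)


class TestCalibration:
    def test_regression_value_n6(self):
        assert calibrate_gamma_bar(6) == pytest.approx(GAMMA_BAR_6, abs=1e-9)

    def test_epsilon_monotone_in_gamma_near_root(self):
        # uniqueness: the calibration function is strictly decreasing there
        vals = [
            epsilon_gamma(empty_graph(6), full_graph(6), g)
            for g in np.linspace(0.05, 3.0, 25)
        ]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("n", [4, 10])
    def test_calibration_identity_holds(self, n):
        gb = calibrate_gamma_bar(n)
        assert epsilon_gamma(empty_graph(n), full_graph(n), gb) == pytest.approx(1.0, abs=1e-10)

    def test_cache_returns_same_object(self):
        assert calibrate_gamma_bar(6) == calibrate_gamma_bar(6)


class TestIMDistance:
    def test_endpoint_pair(self):
        assert im_distance(empty_graph(6), full_graph(6)) == pytest.approx(1.0, abs=1e-10)

    def test_identity(self, rng):
        g = random_weighted_graph(6, rng)
        assert im_distance(g, g) == 0.0

    def test_spectral_closeness_ordering(self):
        gs = worked_example_graphs()
        # the lattice is spectrally closer to the ring than the star is
        assert im_distance(gs["ring"], gs["lattice"]) < im_distance(gs["ring"], gs["star"])


class TestHIMDistance:
    def test_worked_example_values(self):
        gs = worked_example_graphs()
        assert him_distance(gs["prism"], gs["lattice"]) == pytest.approx(0.217, abs=0.005)
        assert him_distance(gs["star"], gs["prism"]) == pytest.approx(0.495, abs=0.005)

    def test_upper_bound_only_on_endpoint_pair(self):
        assert him_distance(empty_graph(6), full_graph(6)) == pytest.approx(1.0, abs=1e-10)

    def test_identity(self, rng):
        g = random_binary_graph(8, 0.3, rng)
        assert him_distance(g, g) == 0.0

    def test_xi_zero_is_exactly_hamming(self, rng):
        g1, g2 = random_weighted_graph(7, rng), random_weighted_graph(7, rng)
        assert him_distance(g1, g2, xi=0.0) == hamming_distance(g1, g2)

    def test_large_xi_approaches_im(self, rng):
        g1, g2 = random_binary_graph(7, 0.4, rng), random_binary_graph(7, 0.4, rng)
        assert him_distance(g1, g2, xi=1e6) == pytest.approx(im_distance(g1, g2), abs=1e-3)

    def test_positive_for_isospectral_nonidentical_graphs(self):
        g = cycle_graph(6)
        # transposition (1 2) is not a cycle automorphism: same spectrum, new edges
        perm = [0, 2, 1, 3, 4, 5]
        g2 = graph_from_edges(6, [(perm[i], perm[(i + 1) % 6]) for i in range(6)])
        assert im_distance(g, g2) == pytest.approx(0.0, abs=1e-8)
        assert hamming_distance(g, g2) > 0
        assert him_distance(g, g2) > 0

    def test_negative_xi_rejected(self):
        with pytest.raises(ValueError, match="xi"):
            HIMParams(xi=-1.0)


class TestMetricAxioms:
    def test_triangle_inequality_on_random_triples(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            a, b, c = (random_binary_graph(8, rng.uniform(0.2, 0.8), rng) for _ in range(3))
            for fn in (hamming_distance, im_distance, him_distance):
                dab, dbc, dac = fn(a, b), fn(b, c), fn(a, c)
                assert dac <= dab + dbc + 1e-10
                assert dab == pytest.approx(fn(b, a), abs=1e-12)
                assert 0.0 <= dab <= 1.0 + 1e-12

    def test_bounds_on_weighted_graphs(self, rng):
        for _ in range(10):
            g1, g2 = random_weighted_graph(6, rng), random_weighted_graph(6, rng)
            for fn in (hamming_distance, im_distance, him_distance):
                assert 0.0 <= fn(g1, g2) <= 1.0 + 1e-12


class TestSimilarityAndMatrix:
    def test_similarity_complements_distance(self, rng):
        g1, g2 = random_binary_graph(6, 0.5, rng), random_binary_graph(6, 0.5, rng)
        assert him_similarity(g1, g2) == pytest.approx(1.0 - him_distance(g1, g2))
        assert him_similarity(g1, g1) == 1.0
        assert him_similarity(empty_graph(6), full_graph(6)) == pytest.approx(0.0, abs=1e-10)

    def test_pairwise_matrix_consistency(self, rng):
        graphs = [random_binary_graph(6, 0.4, rng) for _ in range(4)]
        m = pairwise_him_matrix(graphs)
        assert np.array_equal(m, m.T)
        assert np.all(np.diag(m) == 0)
        for i, j in itertools.combinations(range(4), 2):
            assert m[i, j] == pytest.approx(him_distance(graphs[i], graphs[j]), abs=1e-12)

    def test_endpoint_pair_matrix(self):
        m = pairwise_him_matrix([empty_graph(6), full_graph(6)])
        assert m[0, 1] == pytest.approx(1.0, abs=1e-10)
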