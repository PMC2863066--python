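"""Floyd–Warshall distances and the two homology-weighted graph kernels."""

import math

import numpy as np
import pytest

from netortho.graph_kernels import (
    RandomWalkConvergenceError,
    floyd_warshall,
    random_walk_kernel,
    shortest_path_kernel,
)
from netortho.network_model import HomologyMap, Neighborhood, khop_neighborhood

from conftest import make_graph, random_labeled_graph, random_neighborhood_pair
from oracles import dijkstra_all_pairs, rw_kernel_full_matrix, sp_kernel_double_sum


def as_neighborhood(g, seed=None, k=99):
    seed = seed or sorted(g.nodes)[0]
    return khop_neighborhood(g, seed, k)


class TestFloydWarshall:
    def test_unit_path(self, path_abc):
        dm = floyd_warshall(path_abc, "unit")
        assert dm.distance("a", "c") == pytest.approx(2.0)

    def test_correlation_distance_sums_one_minus_weight(self):
        g = make_graph([("a", "b", 0.9), ("b", "c", 0.8)], weighted=True)
        dm = floyd_warshall(g, "correlation_distance")
        assert dm.distance("a", "c") == pytest.approx(0.3)

    def test_disconnected_pairs_are_infinite(self):
        g = make_graph([("a", "b"), ("c", "d")])
        dm = floyd_warshall(g, "unit")
        assert math.isinf(dm.distance("a", "c"))
        assert dm.distance("a", "a") == 0.0

    def test_correlation_mode_requires_weights(self, path_abc):
        with pytest.raises(ValueError, match="weighted"):
            floyd_warshall(path_abc, "correlation_distance")

    @pytest.mark.parametrize("weighted", [False, True])
    def test_matches_per_source_dijkstra(self, weighted):
        rng = np.random.default_rng(5)
        mode = "correlation_distance" if weighted else "unit"
        for _ in range(30):
            g = random_labeled_graph(rng, n_max=15, weighted=weighted)
            dm = floyd_warshall(g, mode)
            oracle = dijkstra_all_pairs(g, mode)
            for i, u in enumerate(dm.nodes):
                for j, v in enumerate(dm.nodes):
                    expected = oracle[u].get(v, math.inf)
                    assert dm.d[i, j] == pytest.approx(expected, abs=1e-9)


class TestShortestPathKernel:
    def test_matched_single_edges(self):
        C = as_neighborhood(make_graph([("a", "b")]))
        Z = as_neighborhood(make_graph([("a'", "b'")]))
        hom = {("a", "a'"): 1.0, ("b", "b'"): 1.0}
        # ordered pairs (a,b)~(a',b') and (b,a)~(b',a') both match at length 1
        assert shortest_path_kernel(C, Z, hom) == pytest.approx(2.0)

    def test_empty_homology_gives_zero(self):
        C = as_neighborhood(make_graph([("a", "b")]))
        Z = as_neighborhood(make_graph([("x", "y")]))
        assert shortest_path_kernel(C, Z, {}) == 0.0

    def test_self_similarity_positive(self, path_abc):
        C = as_neighborhood(path_abc)
        hom = {(v, v): 1.0 for v in C.nodes}
        assert shortest_path_kernel(C, C, hom) > 0

    def test_matches_double_sum_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(60):
            weighted = bool(rng.random() < 0.5)
            mode = "correlation_distance" if weighted else "unit"
            eps = 0.0 if mode == "unit" else 0.05
            C, Z, hom = random_neighborhood_pair(rng, n_max=8, weighted=weighted)
            got = shortest_path_kernel(C, Z, hom, weight_mode=mode, epsilon=eps)
            want = sp_kernel_double_sum(C, Z, hom, mode, eps)
            assert got == pytest.approx(want, abs=1e-9)

    def test_symmetric_under_swap(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            C, Z, hom = random_neighborhood_pair(rng, n_max=8)
            hom_t = {(v, u): h for (u, v), h in hom.items()}
            assert shortest_path_kernel(C, Z, hom) == pytest.approx(
                shortest_path_kernel(Z, C, hom_t), abs=1e-9
            )


class TestRandomWalkKernel:
    def test_edgeless_neighborhoods_give_nm(self):
        # K vanishes without edges, so the kernel is the all-ones sum n*m
        C = Neighborhood(seed="a", k=1, subgraph=make_graph([], nodes=["a", "b"]))
        Z = Neighborhood(seed="x", k=1, subgraph=make_graph([], nodes=["x", "y", "z"]))
        hom = {("a", "x"): 1.0}
        assert random_walk_kernel(C, Z, hom, lam=0.01) == pytest.approx(6.0)

    def test_hand_solved_single_edge_pair(self):
        # identical single-edge graphs, identity homology: the homology-
        # supported 2x2 block is [[0,1],[1,0]], so the kernel equals
        # (nm - 2) + sum of inv([[1,-lam],[-lam,1]]) = 2 + 2/(1-lam)
        C = as_neighborhood(make_graph([("a", "b")]))
        Z = as_neighborhood(make_graph([("a'", "b'")]))
        hom = {("a", "a'"): 1.0, ("b", "b'"): 1.0}
        lam = 0.01
        assert random_walk_kernel(C, Z, hom, lam=lam) == pytest.approx(
            2.0 + 2.0 / (1.0 - lam), abs=1e-12
        )

    def test_matches_neumann_series_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(60):
            weighted = bool(rng.random() < 0.5)
            mode = "correlation_distance" if weighted else "unit"
            C, Z, hom = random_neighborhood_pair(rng, n_max=8, weighted=weighted)
            got = random_walk_kernel(C, Z, hom, lam=0.01, weight_mode=mode)
            want = rw_kernel_full_matrix(C, Z, hom, lam=0.01, weight_mode=mode)
            assert got == pytest.approx(want, abs=1e-9)

    def test_monotone_in_lambda(self):
        rng = np.random.default_rng(29)
        for _ in range(20):
            C, Z, hom = random_neighborhood_pair(rng, n_max=8)
            values = [random_walk_kernel(C, Z, hom, lam=l) for l in (0.001, 0.01, 0.02)]
            assert values[0] <= values[1] + 1e-12
            assert values[1] <= values[2] + 1e-12

    def test_symmetric_under_swap(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            C, Z, hom = random_neighborhood_pair(rng, n_max=8)
            hom_t = {(v, u): h for (u, v), h in hom.items()}
            assert random_walk_kernel(C, Z, hom) == pytest.approx(
                random_walk_kernel(Z, C, hom_t), abs=1e-9
            )

    def test_divergence_raises_named_error(self):
        C = as_neighborhood(make_graph([("a", "b")]))
        Z = as_neighborhood(make_graph([("a'", "b'")]))
        hom = {("a", "a'"): 1.0, ("b", "b'"): 1.0}
        # spectral radius of the supported block is 1, so lam >= 1 diverges
        with pytest.raises(RandomWalkConvergenceError, match="spectral radius"):
            random_walk_kernel(C, Z, hom, lam=1.5)

    def test_normalizes_homology_map_input(self):
        C = as_neighborhood(make_graph([("a", "b")]))
        Z = as_neighborhood(make_graph([("a'", "b'")]))
        P = HomologyMap(scores={("a", "a'"): 480.0, ("b", "b'"): 480.0})
        # equal scores normalize to 1.0 each: same closed form as above
        assert random_walk_kernel(C, Z, P, lam=0.01) == pytest.approx(
            2.0 + 2.0 / 0.99, abs=1e-12
        )
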