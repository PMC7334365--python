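"""Graph-measure correctness against hand values and brute-force oracles."""

import numpy as np
import pytest

from svdnet import metrics

import oracles


def path_graph(n=3):
    W = np.zeros((n, n))
    for i in range(n - 1):
        W[i, i + 1] = W[i + 1, i] = 1.0
    return W


def complete_graph(n):
    return np.ones((n, n)) - np.eye(n)


def star_graph(leaves=3):
    W = np.zeros((leaves + 1, leaves + 1))
    W[0, 1:] = 1.0
    W[1:, 0] = 1.0
    return W


class TestHandExamples:
    def test_global_efficiency_complete(self):
        assert metrics.global_efficiency(complete_graph(4),
                                         weighted=False) == 1.0

    def test_global_efficiency_path(self):
        # distances 1, 1, 2 -> E = (1 + 1 + 1/2) / 3
        assert metrics.global_efficiency(path_graph(3), weighted=False) \
            == pytest.approx(5.0 / 6.0)

    def test_disconnected_pair_zero_efficiency(self):
        assert metrics.global_efficiency(np.zeros((2, 2)),
                                         weighted=False) == 0.0

    def test_char_path_length_path(self):
        assert metrics.char_path_length(path_graph(3), weighted=False) \
            == pytest.approx(4.0 / 3.0)

    def test_char_path_length_complete(self):
        assert metrics.char_path_length(complete_graph(4),
                                        weighted=False) == 1.0

    def test_char_path_length_isolated_node_infinite(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[1, 2] = W[2, 1] = 1.0
        assert metrics.char_path_length(W, weighted=False) == np.inf

    def test_local_efficiency_complete(self):
        assert metrics.local_efficiency(complete_graph(4),
                                        weighted=False) == 1.0

    def test_local_efficiency_star(self):
        assert metrics.local_efficiency(star_graph(3), weighted=False) == 0.0

    def test_clustering_triangle_and_star(self):
        assert metrics.clustering_transitivity(complete_graph(3)) == (1.0, 1.0)
        assert metrics.clustering_transitivity(star_graph(3)) == (0.0, 0.0)

    def test_modularity_two_triangles(self):
        W = np.zeros((6, 6))
        for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            W[a, b] = W[b, a] = 1.0
        assert metrics.modularity(W, weighted=False) == pytest.approx(0.5)

    def test_modularity_complete_graph_near_zero(self):
        assert metrics.modularity(complete_graph(8), weighted=False) \
            == pytest.approx(0.0, abs=1e-12)

    def test_betweenness_path_midpoint(self):
        # only the middle node routes the single 0-2 pair
        W = path_graph(3)
        assert metrics.mean_betweenness(W, weighted=False) \
            == pytest.approx(1.0 / 3.0)
        assert metrics.mean_betweenness(complete_graph(4),
                                        weighted=False) == 0.0

    def test_rich_club_complete(self):
        assert metrics.rich_club(complete_graph(4)) == 1.0

    def test_rich_club_star_level_skipped(self):
        # at k=1 only the hub qualifies -> no defined level
        assert metrics.rich_club(star_graph(3)) == 0.0


@pytest.mark.parametrize("weighted", [False, True])
def test_metrics_match_bruteforce_oracle(oracle_rng, weighted):
    """Efficiency/path/clustering/betweenness/rich-club vs enumeration on
    50 random graphs of up to 12 nodes."""
    for _ in range(50):
        n = int(oracle_rng.integers(4, 13))
        p = float(oracle_rng.uniform(0.2, 0.8))
        W = oracles.random_graph(oracle_rng, n, p, weighted)
        assert metrics.global_efficiency(W, weighted=weighted) == \
            pytest.approx(oracles.global_efficiency(W, weighted), rel=1e-9)
        assert metrics.local_efficiency(W, weighted=weighted) == \
            pytest.approx(oracles.local_efficiency(W, weighted), rel=1e-9)
        cpl = metrics.char_path_length(W, weighted=weighted)
        cpl_o = oracles.char_path_length(W, weighted)
        if np.isinf(cpl_o):
            assert np.isinf(cpl)
        else:
            assert cpl == pytest.approx(cpl_o, rel=1e-9)
        assert metrics.mean_betweenness(W, weighted=weighted) == \
            pytest.approx(oracles.mean_betweenness(W, weighted), rel=1e-7)
        if weighted:
            cw, _ = metrics.clustering_transitivity(W, weighted=True)
            assert cw == pytest.approx(oracles.weighted_clustering(W),
                                       rel=1e-9)
        else:
            cb, tb = metrics.clustering_transitivity(W, weighted=False)
            cb_o, tb_o = oracles.clustering_and_transitivity(W)
            assert cb == pytest.approx(cb_o, rel=1e-9)
            assert tb == pytest.approx(tb_o, rel=1e-9)
        if not weighted:
            assert metrics.rich_club(W) == \
                pytest.approx(oracles.rich_club_mean(W), rel=1e-9)


def test_modularity_beats_spectral_two_way_split(oracle_rng):
    for _ in range(20):
        n = int(oracle_rng.integers(6, 13))
        W = oracles.random_graph(oracle_rng, n, 0.35, weighted=False)
        if W.sum() == 0:
            continue
        q = metrics.modularity(W, weighted=False)
        q_spec = oracles.best_two_way_spectral_modularity(W, weighted=False)
        assert q >= q_spec - 1e-9


class TestInvariances:
    def test_binary_metrics_scale_invariant(self, oracle_rng):
        W = oracles.random_graph(oracle_rng, 10, 0.4, weighted=True)
        A = (W > 0).astype(float)
        for c in (0.1, 7.3):
            Ac = (c * W > 0).astype(float)
            assert np.array_equal(A, Ac)
            assert metrics.global_efficiency(Ac, weighted=False) == \
                metrics.global_efficiency(A, weighted=False)

    def test_weighted_global_efficiency_scales_linearly(self, oracle_rng):
        W = oracles.random_graph(oracle_rng, 10, 0.5, weighted=True)
        e = metrics.global_efficiency(W, weighted=True)
        assert metrics.global_efficiency(3.0 * W, weighted=True) == \
            pytest.approx(3.0 * e, rel=1e-12)

    def test_efficiency_vs_path_length_jensen(self, oracle_rng):
        # for connected graphs, mean(1/d) >= 1/mean(d)
        for _ in range(20):
            W = oracles.random_graph(oracle_rng, 9, 0.6, weighted=False)
            cpl = metrics.char_path_length(W, weighted=False)
            if np.isinf(cpl):
                continue
            assert metrics.global_efficiency(W, weighted=False) >= \
                1.0 / cpl - 1e-12

    def test_compute_all_permutation_invariant(self, oracle_rng):
        W = oracles.random_graph(oracle_rng, 12, 0.5, weighted=True)
        perm = oracle_rng.permutation(12)
        Wp = W[np.ix_(perm, perm)]
        a = metrics.compute_all(W, n_nulls=5, seed=3)
        b = metrics.compute_all(Wp, n_nulls=5, seed=3)
        for key in ("density", "mean_degree", "global_efficiency_b",
                    "local_efficiency_b", "clustering_b", "transitivity_b",
                    "mean_strength", "global_efficiency_w",
                    "local_efficiency_w", "clustering_w", "transitivity_w",
                    "betweenness_b", "betweenness_w", "assortativity",
                    "rich_club"):
            assert a[key] == pytest.approx(b[key], rel=1e-9), key


class TestNullModels:
    def test_rewiring_preserves_degree_sequence(self, oracle_rng):
        for _ in range(10):
            W = oracles.random_graph(oracle_rng, 12, 0.4, weighted=False)
            A = (W > 0)
            null = metrics.rewire_degree_preserving(A, 10, oracle_rng)
            assert np.array_equal(null.sum(axis=1), A.sum(axis=1))

    def test_triangle_has_no_valid_swap(self, oracle_rng):
        K3 = complete_graph(3)
        null = metrics.rewire_degree_preserving(K3 > 0, 50, oracle_rng)
        assert np.array_equal(null, (K3 > 0).astype(np.int8))

    def test_null_clustering_below_lattice(self):
        import networkx as nx
        G = nx.watts_strogatz_graph(40, 6, 0.0, seed=1)
        A = nx.to_numpy_array(G)
        c_obs, _ = metrics.clustering_transitivity(A, weighted=False)
        rng = np.random.default_rng(5)
        cs = []
        for _ in range(20):
            null = metrics.rewire_degree_preserving(A > 0, 10, rng)
            c, _ = metrics.clustering_transitivity(null.astype(float),
                                                   weighted=False)
            cs.append(c)
        assert np.mean(cs) <= c_obs

    def test_self_normalization_is_unity(self, oracle_rng):
        W = oracles.random_graph(oracle_rng, 10, 0.5, weighted=True)
        ens = metrics.NullEnsemble(n_nulls=3, swaps_per_edge=0, seed=0)
        eg = metrics.global_efficiency(W, weighted=True)
        el = metrics.local_efficiency(W, weighted=True)
        ens.global_efficiencies = [eg] * 3
        ens.local_efficiencies = [el] * 3
        assert metrics.normalized_efficiencies(W, ens) == \
            pytest.approx((1.0, 1.0))

    def test_normalized_ratio_weight_scale_invariant(self, oracle_rng):
        W = oracles.random_graph(oracle_rng, 12, 0.5, weighted=True)
        e1 = metrics.degree_preserving_nulls(W, n_nulls=5, seed=9)
        e2 = metrics.degree_preserving_nulls(4.0 * W, n_nulls=5, seed=9)
        r1 = metrics.normalized_efficiencies(W, e1)
        r2 = metrics.normalized_efficiencies(4.0 * W, e2)
        assert r1 == pytest.approx(r2, rel=1e-9)


def test_compute_all_has_21_measures(oracle_rng):
    W = oracles.random_graph(oracle_rng, 10, 0.6, weighted=True)
    vec = metrics.compute_all(W, n_nulls=3, seed=1)
    assert len(metrics.METRIC_NAMES) == 21
    assert set(metrics.METRIC_NAMES) <= set(vec)
    finite = [k for k in metrics.METRIC_NAMES
              if not k.startswith("char_path_length")]
    assert all(np.isfinite(vec[k]) for k in finite)
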