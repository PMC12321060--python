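import itertools

import networkx as nx
import numpy as np
import pytest

from fatiguenet import graphmetrics as gm
from fatiguenet.montage import default_montage


def random_weighted_graph(rng, n, density=0.5):
    w = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    mask = rng.random(iu[0].size) < density
    vals = rng.random(iu[0].size)
    w[iu[0][mask], iu[1][mask]] = vals[mask]
    return w + w.T


def floyd_warshall(weights):
    """Brute-force all-pairs shortest paths with length = 1/weight."""
    n = weights.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    nz = weights > 0
    d[nz] = 1.0 / weights[nz]
    for k in range(n):
        d = np.minimum(d, d[:, k, None] + d[None, k, :])
    return d


class TestProportionalThreshold:
    def test_keeps_exactly_the_largest_edges(self):
        rng = np.random.default_rng(0)
        w = random_weighted_graph(rng, 4, density=1.0)  # K4, distinct weights
        net = gm.proportional_threshold(w, 0.5)
        assert net.n_edges == 3
        kept = np.sort(net.weights[np.triu_indices(4, 1)])[-3:]
        expected = np.sort(w[np.triu_indices(4, 1)])[-3:]
        assert np.allclose(kept, expected)
        # min retained >= max discarded
        discarded = w[(w > 0) & (net.weights == 0)]
        assert kept.min() >= discarded.max()

    def test_full_proportion_is_identity(self):
        w = random_weighted_graph(np.random.default_rng(1), 6, 1.0)
        assert np.allclose(gm.proportional_threshold(w, 1.0).weights, w)

    def test_tie_break_is_deterministic(self):
        w = np.ones((6, 6)) - np.eye(6)
        nets = [gm.proportional_threshold(w, 0.5) for _ in range(3)]
        assert nets[0].n_edges == round(0.5 * 15)
        for net in nets[1:]:
            assert np.array_equal(net.weights, nets[0].weights)

    def test_out_of_range_proportion_rejected(self):
        w = np.ones((4, 4)) - np.eye(4)
        for p in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                gm.proportional_threshold(w, p)


class TestDistancesAgainstOracle:
    def test_matches_floyd_warshall_on_random_graphs(self):
        """Dijkstra distances equal the brute-force oracle, 500 fuzz seeds."""
        for seed in range(500):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(3, 13))
            w = random_weighted_graph(rng, n, density=float(rng.uniform(0.2, 0.9)))
            got = gm.shortest_path_lengths(w)
            want = floyd_warshall(w)
            assert np.allclose(got, want, equal_nan=True), f"seed {seed}"


class TestGlobalMetrics:
    def test_complete_triangle_identities(self):
        w = np.ones((3, 3)) - np.eye(3)
        g = gm.global_metrics(w, n_null=5, null_seed=0)
        assert g.Cp == pytest.approx(1.0)
        assert g.Lp == pytest.approx(1.0)
        assert g.Eg == pytest.approx(1.0)

    def test_path_graph_hand_oracle(self):
        # A-B-C with unit weights: pairs (1, 1, 2) by hand
        w = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float)
        g = gm.global_metrics(w, n_null=5, null_seed=0)
        assert g.Lp == pytest.approx(4 / 3)
        assert g.Eg == pytest.approx(5 / 6)
        assert g.Cp == pytest.approx(0.0)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            gm.global_metrics(np.zeros((4, 4)), n_null=5)

    def test_clustering_matches_networkx_oracle(self):
        """Onnela clustering agrees with networkx when max weight is 1."""
        rng = np.random.default_rng(7)
        w = random_weighted_graph(rng, 10, density=0.6)
        w /= w.max()  # same normalization convention as networkx
        G = nx.from_numpy_array(w)
        want = np.array([nx.clustering(G, weight="weight")[i] for i in range(10)])
        assert np.allclose(gm._onnela_clustering(w), want)

    def test_erdos_renyi_sigma_near_one(self):
        """A random graph is its own null: Sigma ≈ 1."""
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            w = np.zeros((80, 80))
            iu = np.triu_indices(80, 1)
            mask = rng.random(iu[0].size) < 0.15
            w[iu[0][mask], iu[1][mask]] = 1.0
            w += w.T
            g = gm.global_metrics(w, n_null=100, null_seed=seed + 10)
            assert abs(g.Sigma - 1.0) < 0.1

    def test_small_world_ring_lattice_sigma_above_one(self):
        G = nx.watts_strogatz_graph(30, 6, 0.1, seed=3)
        w = nx.to_numpy_array(G)
        g = gm.global_metrics(w, n_null=50, null_seed=4)
        assert g.Sigma > 1.0

    def test_node_relabeling_invariance(self):
        rng = np.random.default_rng(11)
        w = random_weighted_graph(rng, 9, 0.6)
        perm = rng.permutation(9)
        wp = w[np.ix_(perm, perm)]
        a = gm.global_metrics(w, n_null=30, null_seed=5)
        b = gm.global_metrics(wp, n_null=30, null_seed=5)
        for key in ("Eg", "Eloc", "Cp", "Lp"):
            assert getattr(a, key) == pytest.approx(getattr(b, key), abs=1e-12)
        nm_a = gm.nodal_metrics(w)
        nm_b = gm.nodal_metrics(wp)
        assert np.allclose(nm_a.NE[perm], nm_b.NE)
        assert np.allclose(nm_a.DC[perm], nm_b.DC)


class TestRewiring:
    def test_preserves_degree_sequence_and_weights(self):
        rng = np.random.default_rng(2)
        w = random_weighted_graph(rng, 12, 0.4)
        s = gm.rewire_preserving_degree(w, rng)
        assert np.array_equal((s > 0).sum(axis=1), (w > 0).sum(axis=1))
        assert np.allclose(
            np.sort(s[np.triu_indices(12, 1)]), np.sort(w[np.triu_indices(12, 1)]))
        assert np.array_equal(s, s.T)
        assert np.all(np.diag(s) == 0)


class TestNodalMetrics:
    def test_complete_graph_identities(self):
        w = np.ones((4, 4)) - np.eye(4)
        nm = gm.nodal_metrics(w)
        assert np.allclose(nm.NE, 1.0)
        assert np.allclose(nm.DC, 3.0)

    def test_path_graph_hand_oracle(self):
        w = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float)
        nm = gm.nodal_metrics(w)
        assert np.allclose(nm.NE, [0.75, 1.0, 0.75])
        assert np.allclose(nm.DC, [1.0, 2.0, 1.0])

    def test_isolated_node_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.8
        nm = gm.nodal_metrics(w)
        assert nm.NE[2] == 0.0 and nm.DC[2] == 0.0

    def test_region_means_aggregate_correctly(self):
        montage = default_montage()
        rng = np.random.default_rng(5)
        w = random_weighted_graph(rng, 56, 0.3)
        nm = gm.nodal_metrics(w, montage)
        from fatiguenet.montage import region_mask

        idx = region_mask(montage, "central")
        assert nm.region_means.loc["central", "NE"] == pytest.approx(
            nm.NE[idx].mean())
        assert nm.region_means.loc["central", "DC"] == pytest.approx(
            nm.DC[idx].mean())

    def test_montage_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gm.nodal_metrics(np.ones((4, 4)) - np.eye(4), default_montage())


class TestThresholdSweep:
    def test_monotone_efficiency_and_path_length(self):
        """More retained edges: Eg never falls, Lp never rises (connected)."""
        rng = np.random.default_rng(3)
        w = random_weighted_graph(rng, 20, 1.0)
        sweep = gm.threshold_sweep(w, [0.2, 0.3, 0.4, 0.5, 0.7, 1.0],
                                   n_null=5, null_seed=0)
        eg = sweep["Eg"].to_numpy()
        lp = sweep["Lp"].to_numpy()
        assert np.all(np.diff(eg) >= -1e-12)
        assert np.all(np.diff(lp) <= 1e-12)

    def test_single_proportion_consistent_with_global_metrics(self):
        rng = np.random.default_rng(4)
        w = random_weighted_graph(rng, 12, 0.8)
        sweep = gm.threshold_sweep(w, [0.4], n_null=20, null_seed=9)
        direct = gm.global_metrics(gm.proportional_threshold(w, 0.4),
                                   n_null=20, null_seed=9)
        for key in ("Eg", "Eloc", "Cp", "Lp", "Sigma"):
            assert sweep[key].iloc[0] == pytest.approx(getattr(direct, key))

    def test_empty_and_unsorted_proportions_rejected(self):
        w = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError):
            gm.threshold_sweep(w, [])
        with pytest.raises(ValueError):
            gm.threshold_sweep(w, [0.5, 0.2])
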