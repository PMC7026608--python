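"""Pre-clustering, max-weight-clique extraction and cluster statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from noeme.clustering import (
    cluster_ensemble,
    cluster_report,
    cluster_statistics,
    max_clique_clustering,
    max_weight_clique,
    neighbor_matrix,
    precluster,
    weighted_median,
)
from noeme.geometry import DistanceCache, chi_conformation, pairwise_ermsd


def brute_force_best_clique(adjacency, weights):
    """Enumerate all cliques; max weight, ties by lexicographic members."""
    n = adjacency.shape[0]
    best, best_key = [0], None
    for size in range(1, n + 1):
        for combo in itertools.combinations(range(n), size):
            if all(adjacency[a, b] for a, b in itertools.combinations(combo, 2)):
                key = (-sum(weights[list(combo)]), list(combo))
                if best_key is None or key < best_key:
                    best, best_key = list(combo), key
    return best


def random_graph(rng, n, p=0.5):
    adj = rng.random((n, n)) < p
    adj = np.triu(adj, 1)
    adj = adj | adj.T
    np.fill_diagonal(adj, True)
    return adj


class TestPrecluster:
    def test_identical_bitstrings(self):
        pcs = precluster(["0101"] * 4)
        assert len(pcs) == 1
        assert pcs[0].weight_fraction == pytest.approx(1.0)
        assert pcs[0].members == [0, 1, 2, 3]

    def test_two_groups_with_fractions(self):
        pcs = precluster(["00", "01", "00"])
        assert [(p.bitstring, p.members) for p in pcs] == [("00", [0, 2]), ("01", [1])]
        assert pcs[0].weight_fraction == pytest.approx(2 / 3)
        assert pcs[1].weight_fraction == pytest.approx(1 / 3)

    def test_matches_grouping_oracle(self, rng):
        bits = ["".join(rng.choice(["0", "1"], size=3)) for _ in range(40)]
        w = rng.random(40)
        pcs = precluster(bits, w)
        # partition property
        all_members = sorted(m for p in pcs for m in p.members)
        assert all_members == list(range(40))
        assert sum(p.weight_fraction for p in pcs) == pytest.approx(1.0)
        groups = {}
        for i, b in enumerate(bits):
            groups.setdefault(b, []).append(i)
        assert {p.bitstring: p.members for p in pcs} == groups


class TestNeighborMatrix:
    def test_identical_snapshots_fully_connected(self, rng):
        from conftest import random_snapshot

        s = random_snapshot(rng)
        cache = DistanceCache([s, s, s])
        M = neighbor_matrix([0, 1, 2], cache)
        assert np.all(M == 1)

    def test_cutoff_is_strict(self):
        mat = np.array([[0.0, 0.7], [0.7, 0.0]])
        cache = DistanceCache.from_matrix([None, None], mat)
        M = neighbor_matrix([0, 1], cache, cutoff=0.7)
        assert M[0, 1] == 0 and M[1, 0] == 0 and M[0, 0] == 1

    def test_matches_thresholding_oracle(self, rng):
        n = 6
        d = rng.random((n, n)) * 1.4
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        cache = DistanceCache.from_matrix([None] * n, d)
        M = neighbor_matrix(list(range(n)), cache, cutoff=0.7)
        expect = (d < 0.7).astype(int)
        assert np.array_equal(M, expect)


class TestMaxWeightClique:
    def test_complete_graph_takes_everything(self, rng):
        n = 6
        adj = np.ones((n, n), bool)
        w = rng.random(n)
        assert max_weight_clique(adj, w) == list(range(n))

    def test_matches_bruteforce_on_random_graphs(self, rng):
        for _ in range(60):
            n = int(rng.integers(2, 9))
            adj = random_graph(rng, n)
            w = rng.random(n)
            assert max_weight_clique(adj, w) == brute_force_best_clique(adj, w)

    def test_uniform_weight_ties_lexicographic(self):
        # two disjoint triangles: {0,2,4} and {1,3,5}; equal weights must
        # select the lexicographically smallest member set
        adj = np.eye(6, dtype=bool)
        for tri in ([0, 2, 4], [1, 3, 5]):
            for a, b in itertools.combinations(tri, 2):
                adj[a, b] = adj[b, a] = True
        got = max_weight_clique(adj, np.ones(6))
        assert got == [0, 2, 4]

    def test_zero_weights_terminate(self):
        adj = np.ones((3, 3), bool)
        assert max_weight_clique(adj, np.zeros(3)) == [0]


class TestCliqueClustering:
    def test_complete_graph_single_cluster(self, rng):
        adj = np.ones((5, 5), bool)
        out = max_clique_clustering(adj, rng.random(5))
        assert out == [[0, 1, 2, 3, 4]]

    def test_disconnected_components_split(self):
        adj = np.eye(6, dtype=bool)
        adj[np.ix_([0, 1, 2], [0, 1, 2])] = True
        adj[np.ix_([3, 4, 5], [3, 4, 5])] = True
        out = max_clique_clustering(adj, np.array([1.0, 1, 1, 2, 2, 2]))
        assert sorted(map(sorted, out)) == [[0, 1, 2], [3, 4, 5]]
        # extraction order follows weight
        assert out[0] == [3, 4, 5]

    def test_greedy_fallback_is_valid_partition(self, rng):
        adj = random_graph(rng, 12, p=0.4)
        out = max_clique_clustering(adj, rng.random(12), exact=False)
        flat = sorted(m for c in out for m in c)
        assert flat == list(range(12))
        for c in out:
            for a, b in itertools.combinations(c, 2):
                assert adj[a, b]


class TestWeightedMedian:
    def test_three_uniform_values(self):
        # cumulative mass of {<=1} is 1/3 < 0.5; of {<=2} is 2/3
        assert weighted_median(np.array([1.0, 2.0, 3.0]), np.ones(3)) == 1.0

    def test_single_value(self):
        assert weighted_median(np.array([4.2]), np.array([0.3])) == 4.2

    def test_first_value_carries_half_mass(self):
        # no value has cumulative mass < 0.5: fall back to the smallest
        assert weighted_median(np.array([1.0, 2.0]), np.array([0.5, 0.5])) == 1.0

    def test_matches_definition_bruteforce(self, rng):
        for _ in range(30):
            v = rng.choice([1.0, 2.0, 2.0, 3.0, 5.0], size=6)
            w = rng.random(6)
            got = weighted_median(v, w)
            total = w.sum()
            candidates = [
                x for x in np.unique(v) if w[v <= x].sum() / total < 0.5
            ]
            expect = max(candidates) if candidates else v.min()
            assert got == expect


class TestClusterEnsemble:
    def test_two_state_fixture_recovers_states(self, two_state):
        ensemble, labels = two_state
        clusters = cluster_ensemble(ensemble)
        assert len(clusters) == 2
        assert sum(c.population for c in clusters) == pytest.approx(1.0)
        # cluster numbering is by descending population
        assert clusters[0].population >= clusters[1].population
        for c in clusters:
            member_labels = set(labels[m] for m in c.members)
            assert len(member_labels) == 1

    def test_partition_and_homogeneity(self, two_state):
        ensemble, _ = two_state
        clusters = cluster_ensemble(ensemble)
        flat = sorted(m for c in clusters for m in c.members)
        assert flat == list(range(len(ensemble)))
        mat = pairwise_ermsd(list(ensemble))
        bits = [chi_conformation(s) for s in ensemble]
        for c in clusters:
            for a, b in itertools.combinations(c.members, 2):
                assert mat[a, b] < 0.7
            assert all(bits[m] == c.bitstring for m in c.members)

    def test_zero_weight_precluster_becomes_singletons(self, two_state):
        ensemble, labels = two_state
        w = np.where(labels == "anti", 0.0, 1.0)
        clusters = cluster_ensemble(ensemble, w)
        zero_clusters = [c for c in clusters if c.population == 0.0]
        n_anti = int((labels == "anti").sum())
        assert len(zero_clusters) == n_anti
        assert all(len(c.members) == 1 for c in zero_clusters)

    def test_report_table(self, two_state):
        ensemble, _ = two_state
        clusters = cluster_ensemble(ensemble)
        df = cluster_report(clusters)
        assert list(df.columns) == ["cluster_id", "population", "chi_bitstring", "n_members"]
        assert df.population.sum() == pytest.approx(1.0)


class TestClusterStatistics:
    def test_single_member(self, rng):
        F = rng.random((4, 5))
        avg, med = cluster_statistics([2], F, np.full(5, 0.2))
        assert np.allclose(avg, F[:, 2])
        assert np.allclose(med, F[:, 2])

    def test_average_matches_oracle_and_bounds(self, rng):
        F = rng.random((3, 8)) + 0.5
        w = rng.random(8)
        members = [1, 3, 4, 6]
        avg, med = cluster_statistics(members, F, w)
        wm = w[members] / w[members].sum()
        for i in range(3):
            brute = sum(wm[k] * F[i, m] for k, m in enumerate(members))
            assert avg[i] == pytest.approx(brute, rel=1e-12)
            assert F[i, members].min() - 1e-12 <= avg[i] <= F[i, members].max() + 1e-12
            assert med[i] in F[i, members]

    def test_zero_weight_cluster_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_statistics([0, 1], rng.random((2, 3)), np.zeros(3))
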