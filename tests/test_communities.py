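"""Community-detection tests: modularity, greedy optimizer, co-membership."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import plastnet.communities as comm
from plastnet.communities import (
    Partition,
    co_membership,
    community_count_series,
    community_sync_report,
    detect_communities,
    modularity,
)
from plastnet.fixtures import make_fixture
from plastnet.sync import SIGMA_FLOOR


def adjacency_of(graph: nx.Graph, n: int) -> np.ndarray:
    return nx.to_numpy_array(graph, nodelist=range(n), dtype=int)


def two_triangles() -> np.ndarray:
    g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
    return adjacency_of(g, 6)


def brute_force_modularity(adj: np.ndarray, labels: np.ndarray) -> float:
    """Definition oracle: (1/2m) sum_ij (A_ij - k_i k_j / 2m) delta(c_i, c_j)."""
    adj = np.asarray(adj, dtype=float)
    k = adj.sum(axis=1)
    two_m = adj.sum()
    q = 0.0
    n = adj.shape[0]
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += adj[i, j] - k[i] * k[j] / two_m
    return q / two_m


def set_partitions(items):
    """All set partitions (Bell-number enumeration) of a small item list."""
    items = list(items)
    if not items:
        yield []
        return
    head, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [[head] + part[k]] + part[k + 1 :]
        yield [[head]] + part


def exhaustive_best_q(adj: np.ndarray) -> float:
    n = adj.shape[0]
    best = -np.inf
    for part in set_partitions(range(n)):
        labels = np.empty(n, dtype=int)
        for cid, block in enumerate(part):
            labels[block] = cid
        best = max(best, modularity(adj, labels))
    return best


class TestModularity:
    def test_two_disjoint_triangles_halves(self):
        adj = two_triangles()
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert modularity(adj, labels) == pytest.approx(0.5)

    def test_single_community_is_zero(self):
        for g in (nx.path_graph(5), nx.complete_graph(4), nx.cycle_graph(6)):
            adj = adjacency_of(g, g.number_of_nodes())
            assert modularity(adj, np.zeros(adj.shape[0], dtype=int)) == pytest.approx(0.0)

    @given(seed=st.integers(0, 200))
    def test_matches_double_sum_oracle_and_networkx(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        g = nx.gnp_random_graph(n, 0.6, seed=seed)
        if g.number_of_edges() == 0:
            return
        adj = adjacency_of(g, n)
        labels = rng.integers(0, 3, size=n)
        q = modularity(adj, labels)
        assert q == pytest.approx(brute_force_modularity(adj, labels), abs=1e-12)
        groups = [set(np.flatnonzero(labels == c)) for c in np.unique(labels)]
        assert q == pytest.approx(nx.community.modularity(g, groups), abs=1e-12)

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ValueError):
            modularity(np.zeros((4, 4), dtype=int), np.arange(4))


class TestDetectCommunities:
    def test_two_k4_cliques_recovered(self):
        adj = make_fixture("two-cliques")["adjacency"]
        part = detect_communities(adj)
        assert part.n_communities == 2
        assert len(set(part.labels[:4])) == 1
        assert len(set(part.labels[4:])) == 1
        assert part.q == pytest.approx(0.5)

    def test_edgeless_graph_gives_singletons(self):
        part = detect_communities(np.zeros((5, 5), dtype=int))
        assert part.n_communities == 5
        assert part.q == 0.0

    def test_single_edge_matches_exhaustive_choice(self):
        adj = np.array([[0, 1], [1, 0]])
        part = detect_communities(adj)
        q_merged = modularity(adj, np.array([0, 0]))
        q_split = modularity(adj, np.array([0, 1]))
        assert part.q == pytest.approx(max(q_merged, q_split))

    @pytest.mark.parametrize(
        "edges,n",
        [
            ([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)], 6),  # two triangles
            ([(i, j) for i in range(4) for j in range(i + 1, 4)]
             + [(i, j) for i in range(4, 8) for j in range(i + 1, 8)], 8),  # two K4
            ([(i, j) for i in range(4) for j in range(i + 1, 4)]
             + [(i, j) for i in range(4, 8) for j in range(i + 1, 8)] + [(3, 4)], 8),  # bridged K4s
            ([(0, 1)], 2),
            ([(0, 1), (1, 2), (2, 3)], 4),  # path
            ([(0, 1), (1, 2), (0, 2), (2, 3), (3, 4), (4, 5), (3, 5)], 6),  # bridged triangles
        ],
    )
    def test_greedy_reaches_exhaustive_optimum_on_fixture_graphs(self, edges, n):
        adj = adjacency_of(nx.Graph(edges), n)
        part = detect_communities(adj)
        assert part.q == pytest.approx(exhaustive_best_q(adj), abs=1e-12)

    def test_never_worse_than_singletons_and_seed_stable(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(3, 10))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1e6)))
            if g.number_of_edges() == 0:
                continue
            adj = adjacency_of(g, n)
            p1 = detect_communities(adj, seed=0)
            p2 = detect_communities(adj, seed=99)
            assert np.array_equal(p1.labels, p2.labels)
            assert p1.q >= modularity(adj, np.arange(n)) - 1e-12

    def test_comparable_to_networkx_greedy(self):
        # independent greedy-modularity implementation finds the same Q on
        # clean modular graphs
        for fixture in ("two-cliques",):
            adj = make_fixture(fixture)["adjacency"]
            ours = detect_communities(adj)
            g = nx.from_numpy_array(adj)
            nx_comms = nx.community.greedy_modularity_communities(g)
            q_nx = nx.community.modularity(g, nx_comms)
            assert ours.q == pytest.approx(q_nx, abs=1e-12)

    def test_disconnected_components_never_merged(self, lattice16_partitions, lattice16_trace):
        from scipy.sparse.csgraph import connected_components

        for part, snap in zip(lattice16_partitions[:50], lattice16_trace.snapshots[:50]):
            _, comp = connected_components(snap.coupling, directed=False)
            for label in np.unique(part.labels):
                members = np.flatnonzero(part.labels == label)
                assert len(set(comp[members])) == 1


class TestCoMembership:
    def _parts(self, label_rows):
        return [Partition(labels=np.asarray(r), q=0.0) for r in label_rows]

    def test_identical_partitions_give_binary_p(self):
        parts = self._parts([[0, 0, 1, 1]] * 5)
        cm = co_membership(parts)
        assert set(np.unique(cm.p)) <= {0.0, 1.0}
        assert [sorted(g.tolist()) for g in cm.stable_groups] == [[0, 1], [2, 3]]

    def test_threshold_inclusive_at_70_percent(self):
        rows = [[0, 0]] * 7 + [[0, 1]] * 3
        cm = co_membership(self._parts(rows), threshold=0.70)
        assert cm.p[0, 1] == pytest.approx(0.7)
        assert len(cm.stable_groups) == 1  # the pair counts at exactly 70%

    @given(seed=st.integers(0, 100))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, w = 5, 12
        rows = rng.integers(0, 3, size=(w, n))
        cm = co_membership(self._parts(rows))
        for i in range(n):
            assert cm.p[i, i] == 1.0
            for j in range(n):
                expect = np.mean(rows[:, i] == rows[:, j])
                assert cm.p[i, j] == pytest.approx(expect, abs=1e-12)
                assert cm.p[i, j] == cm.p[j, i]

    def test_threshold_one_requires_total_consistency(self):
        rows = [[0, 0, 1], [0, 0, 1], [0, 1, 1]]
        cm = co_membership(self._parts(rows), threshold=1.0)
        assert [sorted(g.tolist()) for g in cm.stable_groups] == [[0], [1], [2]]

    def test_empty_partition_list_rejected(self):
        with pytest.raises(ValueError):
            co_membership([])


class TestTracePipeline:
    def test_count_series_sizes_sum_to_n(self, lattice16_trace, lattice16_partitions):
        df = community_count_series(lattice16_partitions)
        assert len(df) == len(lattice16_trace.snapshots)
        for sizes in df["sizes"]:
            assert sum(sizes) == 16

    def test_detection_independent_of_dynamics(self, lattice16_trace, lattice16_partitions):
        import copy

        shuffled = copy.copy(lattice16_trace)
        rng = np.random.default_rng(0)
        shuffled.states = lattice16_trace.states[:, rng.permutation(16), :] * 0.5
        parts2 = comm.window_partitions(shuffled)
        for a, b in zip(lattice16_partitions, parts2):
            assert np.array_equal(a.labels, b.labels)

    def test_sync_report_skips_empty_groups(self, pair_trace):
        with pytest.warns(UserWarning):
            out = community_sync_report(pair_trace, [np.array([0, 1]), np.array([], dtype=int)])
        assert len(out) == 1

    def test_whole_network_group_equals_global_series(self, pair_trace):
        from plastnet.sync import sync_series

        (series,) = community_sync_report(pair_trace, [np.array([0, 1])])
        ref = sync_series(pair_trace.times, pair_trace.states[:, :, 0])
        assert np.allclose(series.s, ref.s)

    def test_perfectly_synchronized_group_clamps(self):
        parts = [Partition(labels=np.zeros(3, dtype=int), q=0.0)]

        class FakeTrace:
            times = np.arange(3.0)
            states = np.full((3, 3, 4), -60.0)

        (series,) = community_sync_report(FakeTrace(), [np.arange(3)])
        assert np.allclose(series.s, -np.log(SIGMA_FLOOR))
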