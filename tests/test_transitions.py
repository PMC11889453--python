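import numpy as np
import pytest
import scipy.sparse as sp

from ltnn.states import NeighborGraph
from ltnn.transitions import (
    ClusterGraph,
    apply_threshold,
    compute_threshold,
    filter_edges_by_time,
    prune_mst,
    transition_confidence,
)


def graph_from_edges(n, edges):
    a = sp.lil_matrix((n, n))
    for i, j in edges:
        a[i, j] = a[j, i] = 1.0
    return NeighborGraph(n_neighbors=1, adjacency=a.tocsr())


def brute_force_filter(edges, t, labels, epsilon):
    means = {c: t[labels == c].mean() for c in np.unique(labels)}
    out = set()
    for i, j in edges:
        for s, d in ((i, j), (j, i)):
            if t[s] < t[d] and means[labels[d]] > means[labels[s]] - epsilon:
                out.add((s, d))
    return out


class TestEdgeFilter:
    def test_forward_edge_retained(self):
        g = graph_from_edges(2, [(0, 1)])
        t = np.array([0.3, 0.5])
        labels = np.array([0, 1])  # cluster means 0.3, 0.5
        got = set(map(tuple, filter_edges_by_time(g, t, labels)))
        assert got == {(0, 1)}

    def test_backward_cell_order_reorients(self):
        g = graph_from_edges(2, [(0, 1)])
        t = np.array([0.5, 0.3])
        labels = np.array([0, 0])
        got = set(map(tuple, filter_edges_by_time(g, t, labels)))
        assert got == {(1, 0)}

    def test_cluster_condition_blocks_large_backward_step(self):
        # cell times increase, but the target cluster sits 0.15 earlier
        # than the source cluster, beyond the epsilon = 0.1 slack
        t = np.array([0.3, 0.4, 0.6, 0.2])
        labels = np.array([0, 1, 0, 1])  # cluster means: 0.45 and 0.30
        g = graph_from_edges(4, [(0, 1)])
        got = set(map(tuple, filter_edges_by_time(g, t, labels, epsilon=0.1)))
        assert got == set()

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = 30
            t = rng.uniform(0, 1, n)
            labels = rng.integers(0, 4, n)
            pairs = {tuple(sorted(p)) for p in rng.integers(0, n, (60, 2)) if p[0] != p[1]}
            g = graph_from_edges(n, list(pairs))
            got = set(map(tuple, filter_edges_by_time(g, t, labels, epsilon=0.1)))
            assert got == brute_force_filter(pairs, t, labels, 0.1)


class TestConfidence:
    def test_two_cluster_formula(self):
        labels = np.array([0, 0, 1, 1])
        edges = np.array([[0, 2], [0, 3], [1, 2], [1, 3]])
        cg = transition_confidence(edges, labels)
        assert cg.confidence[0, 1] == 1.0
        assert cg.confidence[1, 0] == 0.0

    def test_three_cluster_toy_matches_hand_count(self):
        labels = np.array([0] * 3 + [1] * 3 + [2] * 4)
        edges = np.array(
            [
                (0, 3), (1, 3), (2, 4),       # 3 edges 0 -> 1
                (3, 6), (4, 7), (5, 8), (5, 9),  # 4 edges 1 -> 2
                (6, 0),                        # 1 edge 2 -> 0
                (0, 1), (7, 8),                # intra-cluster, ignored
            ]
        )
        cg = transition_confidence(edges, labels)
        w_expected = np.array([[0, 3, 0], [0, 0, 4], [1, 0, 0]], dtype=float)
        np.testing.assert_array_equal(cg.weights, w_expected)
        np.testing.assert_allclose(
            cg.confidence,
            w_expected / np.outer([3, 3, 4], [3, 3, 4]),
        )

    def test_brute_force_equivalence_on_random_instance(self):
        rng = np.random.default_rng(1)
        n, k = 200, 6
        labels = rng.integers(0, k, n)
        edges = rng.integers(0, n, (500, 2))
        edges = edges[edges[:, 0] != edges[:, 1]]
        cg = transition_confidence(edges, labels)
        w = np.zeros((k, k))
        for s, d in edges:
            if labels[s] != labels[d]:
                w[labels[s], labels[d]] += 1
        sizes = np.bincount(labels, minlength=k)
        np.testing.assert_array_equal(cg.weights, w)
        np.testing.assert_allclose(cg.confidence, w / np.outer(sizes, sizes))


def oracle_threshold(t, floor=0.01):
    maxima = []
    for j in range(t.shape[1]):
        pos = [t[i, j] for i in range(t.shape[0]) if t[i, j] > 0]
        if pos:
            maxima.append(max(pos))
    if not maxima:
        return None
    return max(min(maxima) - 1e-6, floor)


class TestThreshold:
    def _graph(self, t):
        t = np.asarray(t, dtype=float)
        n = t.shape[0]
        return ClusterGraph(
            sizes=np.ones(n, dtype=int), weights=t.copy(), confidence=t
        )

    def test_column_maxima_formula(self):
        t = np.array([[0.0, 0.2, 0.3], [0.5, 0.0, 0.1], [0.2, 0.1, 0.0]])
        assert np.isclose(compute_threshold(t), 0.2 - 1e-6)

    def test_floor_applies_and_nothing_retained(self):
        t = np.array([[0.0, 0.005], [0.002, 0.0]])
        cg = apply_threshold(self._graph(t))
        assert cg.threshold == 0.01
        assert cg.retained_edges == []

    def test_single_positive_entry_retained(self):
        t = np.zeros((3, 3))
        t[0, 1] = 0.8
        cg = apply_threshold(self._graph(t))
        assert np.isclose(cg.threshold, 0.8 - 1e-6)
        assert cg.retained_edges == [(0, 1)]

    def test_all_zero_matrix_yields_empty_set(self):
        cg = apply_threshold(self._graph(np.zeros((3, 3))))
        assert cg.threshold is None and cg.retained_edges == []

    def test_matches_oracle_on_random_matrices(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = rng.integers(2, 7)
            t = rng.uniform(0, 0.5, (n, n)) * (rng.random((n, n)) < 0.5)
            np.fill_diagonal(t, 0)
            got = compute_threshold(t)
            want = oracle_threshold(t)
            assert (got is None and want is None) or np.isclose(got, want)
            cg = apply_threshold(self._graph(t))
            expect = [
                (i, j)
                for i in range(n)
                for j in range(n)
                if i != j and want is not None and t[i, j] >= want
            ]
            assert cg.retained_edges == expect


class TestMST:
    def _triangle(self):
        conf = np.zeros((3, 3))
        conf[0, 1] = 0.5
        conf[1, 2] = 0.4
        conf[0, 2] = 0.1
        return ClusterGraph(
            sizes=np.ones(3, dtype=int),
            weights=conf.copy(),
            confidence=conf,
            cluster_times=np.array([0.1, 0.5, 0.9]),
            retained_edges=[(0, 1), (1, 2), (0, 2)],
        )

    def test_triangle_drops_weak_chord(self):
        pruned = prune_mst(self._triangle())
        assert set(pruned.retained_edges) == {(0, 1), (1, 2)}

    def test_heavier_chord_joins_the_tree_instead(self):
        # raising the chord above an old tree edge re-routes the maximum
        # spanning tree through it; the displaced edge becomes the chord
        # and is dropped by the bottleneck rule
        cg = self._triangle()
        cg.confidence[0, 2] = 0.45
        cg.weights[0, 2] = 0.45
        pruned = prune_mst(cg)
        assert set(pruned.retained_edges) == {(0, 1), (0, 2)}

    def test_non_tree_chords_never_survive(self):
        """Cycle property: a non-tree edge of a maximum spanning tree is
        minimal on its cycle, so it can never beat the path bottleneck —
        the pruned graph is exactly the tree."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = 6
            conf = np.triu(rng.uniform(0.01, 1.0, (n, n)), k=1)
            conf = conf * (rng.random((n, n)) < 0.7)
            edges = [(i, j) for i in range(n) for j in range(n) if conf[i, j] > 0]
            if not edges:
                continue
            cg = ClusterGraph(
                sizes=np.ones(n, dtype=int), weights=conf.copy(),
                confidence=conf, cluster_times=np.arange(n, dtype=float),
                retained_edges=edges,
            )
            pruned = prune_mst(cg)
            n_nodes = len({v for e in edges for v in e})
            assert len(pruned.retained_edges) <= n_nodes - 1

    def test_tree_input_unchanged(self):
        cg = self._triangle()
        cg.retained_edges = [(0, 1), (1, 2)]
        pruned = prune_mst(cg)
        assert set(pruned.retained_edges) == {(0, 1), (1, 2)}

    def test_tree_edges_follow_cluster_time_direction(self):
        cg = self._triangle()
        cg.retained_edges = [(1, 0), (1, 2)]  # 1->0 points against time
        pruned = prune_mst(cg)
        assert (0, 1) in pruned.retained_edges


def test_retained_edges_respect_time_direction(branching_result):
    """Every retained inter-cluster edge points forward in mean
    pseudotime, up to the epsilon slack of the edge filter."""
    res, _, cfg = branching_result
    cg = res.graph
    for i, j in cg.retained_edges:
        assert cg.cluster_times[j] > cg.cluster_times[i] - cfg.epsilon


def test_graph_recovery_on_branching_fixture():
    """The transition graph over annotated cell-type groups recovers
    every true milestone transition with positive confidence."""
    from ltnn import RunConfig, run_pipeline, simulate_trajectory, simulate_training_time
    from ltnn.metrics import inferred_network, transitions_rate
    from ltnn.transitions import annotation_transition_graph

    for seed in range(3):
        matrix, truth = simulate_trajectory(
            n_cells=400, n_genes=300, n_branches=2, seed=seed
        )
        training = simulate_training_time(truth, seed=seed + 50)
        cfg = RunConfig(hvg_count=250, epochs=40, seed=seed)
        res = run_pipeline(matrix, training, cfg)
        acg = annotation_transition_graph(
            res.neighbor_graph,
            res.table.columns["ltnn_time"],
            res.matrix.cell_meta["milestone"].to_numpy(),
        )
        net = inferred_network(acg, retained_only=False)
        assert truth.network.edge_set() <= net.edge_set()
        assert transitions_rate(acg, sorted(truth.network.edge_set())) == 1.0
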