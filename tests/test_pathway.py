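"""Residue-graph fusion, shortest paths vs brute force, SPM extraction."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import allopath as ap
from allopath.correlation import ContactMatrix, DCCM
from allopath.structure_io import ValidationError


def mats(C, freq, residues=None):
    C = np.asarray(C, dtype=float)
    freq = np.asarray(freq, dtype=float)
    res = np.arange(1, C.shape[0] + 1) if residues is None else np.asarray(residues)
    return (
        DCCM(C=C, residues=res),
        ContactMatrix(freq=freq, cutoff=10.0, distance_mode="ca", residues=res),
    )


class TestBuildGraph:
    def test_perfect_correlation_zero_weight(self):
        C = np.array([[1.0, 1.0], [1.0, 1.0]])
        freq = np.ones((2, 2))
        g = ap.build_rdcm_graph(*mats(C, freq))
        assert g[1][2]["weight"] == pytest.approx(0.0, abs=1e-12)

    def test_contact_gate_blocks_low_frequency_pairs(self):
        C = np.array([[1.0, 0.9], [0.9, 1.0]])
        freq = np.array([[1.0, 0.2], [0.2, 1.0]])
        g = ap.build_rdcm_graph(*mats(C, freq), f_min=0.5)
        assert g.number_of_edges() == 0

    def test_correlation_floor_blocks_weak_pairs(self):
        C = np.array([[1.0, 0.01], [0.01, 1.0]])
        freq = np.ones((2, 2))
        g = ap.build_rdcm_graph(*mats(C, freq), c_min=0.05)
        assert g.number_of_edges() == 0

    def test_four_residue_hand_computed_weights(self):
        # printed C and freq values; expected edges/weights by hand (-ln|C|)
        C = np.array([
            [1.0, 0.9, 0.1, 0.02],
            [0.9, 1.0, -0.5, 0.3],
            [0.1, -0.5, 1.0, 0.6],
            [0.02, 0.3, 0.6, 1.0],
        ])
        freq = np.array([
            [1.0, 1.0, 1.0, 1.0],
            [1.0, 1.0, 0.4, 1.0],
            [1.0, 0.4, 1.0, 0.9],
            [1.0, 1.0, 0.9, 1.0],
        ])
        g = ap.build_rdcm_graph(*mats(C, freq), f_min=0.5, c_min=0.05)
        expected = {
            (1, 2): -math.log(0.9),
            (1, 3): -math.log(0.1),
            (2, 4): -math.log(0.3),
            (3, 4): -math.log(0.6),
        }  # (2,3) gated by freq, (1,4) by |C|
        assert {tuple(sorted(e)) for e in g.edges} == set(expected)
        for (i, j), w in expected.items():
            assert g[i][j]["weight"] == pytest.approx(w, abs=1e-12)

    def test_weight_is_neg_log_abs_corr_for_every_edge(self, planted_path_system):
        _, traj, _ = planted_path_system
        corr = ap.dccm(ap.covariance_matrix(traj))
        cm = ap.contact_matrix(traj)
        g = ap.build_rdcm_graph(corr, cm)
        for i, j, data in g.edges(data=True):
            assert data["weight"] == pytest.approx(-math.log(data["corr"]), abs=1e-12)
            assert data["freq"] >= 0.5
            assert data["corr"] >= 0.05

    def test_dimension_mismatch_rejected(self):
        d, _ = mats(np.eye(3), np.ones((3, 3)))
        _, c = mats(np.eye(2), np.ones((2, 2)))
        with pytest.raises(ValidationError):
            ap.build_rdcm_graph(d, c)


def brute_force_shortest(graph, s, t):
    """Exhaustive enumeration over all simple paths."""
    best = None
    for path in nx.all_simple_paths(graph, s, t):
        w = sum(graph[a][b]["weight"] for a, b in zip(path, path[1:]))
        if best is None or w < best:
            best = w
    return best


class TestShortestPaths:
    def test_two_node_graph(self):
        g = nx.Graph()
        g.add_edge(1, 2, weight=0.5)
        out = ap.shortest_paths(g, [1], [2])
        assert out[(1, 2)] == ([1, 2], 0.5)

    def test_triangle_two_hop_beats_direct(self):
        g = nx.Graph()
        g.add_edge(1, 2, weight=1.0)
        g.add_edge(2, 3, weight=1.0)
        g.add_edge(1, 3, weight=3.0)
        path, w = ap.shortest_paths(g, [1], [3])[(1, 3)]
        assert path == [1, 2, 3]
        assert w == pytest.approx(2.0)

    def test_unreachable_pair_reported(self):
        g = nx.Graph()
        g.add_edge(1, 2, weight=1.0)
        g.add_node(3)
        assert ap.shortest_paths(g, [1], [3])[(1, 3)] is None

    def test_unknown_node_rejected(self):
        g = nx.Graph()
        g.add_edge(1, 2, weight=1.0)
        with pytest.raises(ValidationError):
            ap.shortest_paths(g, [1], [99])

    def test_dijkstra_equals_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = rng.integers(3, 8)
            g = nx.gnp_random_graph(int(n), 0.6, seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {k: k + 1 for k in range(n)})
            for a, b in g.edges:
                g[a][b]["weight"] = float(rng.uniform(0.01, 3.0))
            nodes = sorted(g.nodes)
            out = ap.shortest_paths(g, nodes, nodes)
            for (s, t), got in out.items():
                expected = brute_force_shortest(g, s, t)
                if expected is None:
                    assert got is None
                else:
                    assert got[1] == pytest.approx(expected, abs=1e-9)


def brute_force_importance(graph):
    """Edge traversal counts over *all* co-optimal shortest paths, by
    exhaustive simple-path enumeration (feasible for <=10 nodes)."""
    counts = {tuple(sorted(e)): 0.0 for e in graph.edges}
    nodes = sorted(graph.nodes)
    for s, t in itertools.combinations(nodes, 2):
        paths = list(nx.all_simple_paths(graph, s, t))
        if not paths:
            continue
        weights = [
            sum(graph[a][b]["weight"] for a, b in zip(p, p[1:])) for p in paths
        ]
        best = min(weights)
        for p, w in zip(paths, weights):
            if abs(w - best) < 1e-9:
                for a, b in zip(p, p[1:]):
                    counts[tuple(sorted((a, b)))] += 1
    mx = max(counts.values())
    return {e: c / mx for e, c in counts.items()}


class TestExtractSpm:
    def test_path_graph_all_edges_equal_importance(self):
        g = nx.Graph()
        g.add_edge(1, 2, weight=1.0, corr=0.4, freq=1.0)
        g.add_edge(2, 3, weight=1.0, corr=0.4, freq=1.0)
        res = ap.extract_spm(g, importance_threshold=0.3)
        imps = {imp for *_ , imp in res.edges}
        assert imps == {1.0}  # each edge carries 2 of the 3 pair paths
        assert res.hotspots == [1, 2, 3]

    def test_star_graph_symmetric_importance(self):
        g = nx.Graph()
        for leaf in (2, 3, 4, 5):
            g.add_edge(1, leaf, weight=1.0, corr=0.4, freq=1.0)
        res = ap.extract_spm(g, importance_threshold=0.5)
        assert {imp for *_, imp in res.edges} == {1.0}
        assert res.hotspots == [1, 2, 3, 4, 5]

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(77)
        for _ in range(30):
            n = int(rng.integers(4, 10))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0:
                continue
            g = nx.relabel_nodes(g, {k: k + 1 for k in range(n)})
            for a, b in g.edges:
                w = float(rng.uniform(0.05, 2.0))
                g[a][b].update(weight=w, corr=math.exp(-w), freq=1.0)
            res = ap.extract_spm(g, importance_threshold=0.0)
            expected = brute_force_importance(g)
            got = {tuple(sorted((i, j))): imp for i, j, *_, imp in res.edges}
            for e, imp in expected.items():
                assert got[e] == pytest.approx(imp, abs=1e-9), (e, g.edges(data=True))

    def test_importance_invariant_under_monotone_relabeling(self):
        # scaling all |C| toward 1 by a power <1 preserves weight ordering
        # and scales all path weights uniformly: same importance ranking
        rng = np.random.default_rng(55)
        g = nx.gnp_random_graph(8, 0.5, seed=4)
        g = nx.relabel_nodes(g, {k: k + 1 for k in range(8)})
        for a, b in g.edges:
            c = float(rng.uniform(0.1, 0.9))
            g[a][b].update(weight=-math.log(c), corr=c, freq=1.0)
        g2 = g.copy()
        for a, b in g2.edges:
            c2 = g[a][b]["corr"] ** 0.5  # closer to 1, order preserved
            g2[a][b].update(weight=-math.log(c2), corr=c2)
        r1 = ap.extract_spm(g, importance_threshold=0.0)
        r2 = ap.extract_spm(g2, importance_threshold=0.0)
        imp1 = {tuple(sorted((i, j))): imp for i, j, *_, imp in r1.edges}
        imp2 = {tuple(sorted((i, j))): imp for i, j, *_, imp in r2.edges}
        for e in imp1:
            assert imp1[e] == pytest.approx(imp2[e], abs=1e-9)

    def test_planted_chain_recovered(self, planted_path_system):
        _, traj, truth = planted_path_system
        corr = ap.dccm(ap.covariance_matrix(traj))
        cm = ap.contact_matrix(traj)
        g = ap.build_rdcm_graph(corr, cm)
        res = ap.extract_spm(g)
        recovered = len(set(truth) & set(res.hotspots)) / len(truth)
        assert recovered >= 0.9

    def test_empty_graph_rejected(self):
        with pytest.raises(ValidationError):
            ap.extract_spm(nx.Graph())

    def test_hotspots_lie_on_retained_edges(self, planted_path_system):
        _, traj, _ = planted_path_system
        corr = ap.dccm(ap.covariance_matrix(traj))
        cm = ap.contact_matrix(traj)
        res = ap.extract_spm(ap.build_rdcm_graph(corr, cm))
        endpoints = set()
        for i, j, _ in res.retained_edges:
            endpoints.update((i, j))
        assert set(res.hotspots) == endpoints
        assert res.hotspots == sorted(res.hotspots)
        assert max(imp for *_, imp in res.edges) == pytest.approx(1.0)


class TestCommonResidues:
    def test_identical_sets(self):
        out = ap.common_residues([{3, 7, 9}, {3, 7, 9}], window=0)
        assert out == [3, 7, 9]

    def test_disjoint_sets_empty(self):
        assert ap.common_residues([{1, 2}, {5, 6}], window=0) == []

    def test_window_matches_near_misses(self):
        out = ap.common_residues([{10, 50}, {11, 50}], window=1)
        assert out == [10, 50]  # tie reported as the smallest index

    def test_three_systems(self):
        out = ap.common_residues([{1, 5, 9}, {5, 9, 12}, {2, 5, 9}], window=0)
        assert out == [5, 9]

    def test_needs_two_systems(self):
        with pytest.raises(ValidationError):
            ap.common_residues([{1, 2}])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.sets(st.integers(min_value=1, max_value=60), min_size=1, max_size=12),
            min_size=2, max_size=4,
        )
    )
    def test_window_zero_equals_exact_set_intersection(self, sets):
        assert ap.common_residues(sets, window=0) == sorted(
            set.intersection(*sets)
        )
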