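"""Contact-network construction and topological descriptors.

Centrality and path descriptors are checked against independent
brute-force oracles (Floyd-Warshall, exact-rational shortest-path
counting, literal path enumeration, triangle counting) on random
geometric graphs.
"""

import math

import numpy as np
import pytest

import pcnkit.network as pn
from pcnkit.constants import HYDROPHOBIC, POLAR
from pcnkit.structure_io import ResidueRecord, StructureFrame
from pcnkit.synth import make_fold

from conftest import net_from_edges, random_geometric_net
from oracles import (
    enumerate_betweenness,
    floyd_warshall_sp,
    path_count_betweenness,
    triangle_clustering,
)


def frame_from_coords(coords, names=None):
    from pcnkit.structure_io import assign_residue_annotations

    names = names or ["ALA"] * len(coords)
    recs = []
    for i, (xyz, nm) in enumerate(zip(coords, names)):
        mass, kd, hp = assign_residue_annotations(nm)
        recs.append(ResidueRecord("A", i + 1, nm, tuple(map(float, xyz)), mass, kd, hp))
    return StructureFrame(recs)


class TestBuildPCN:
    def test_distance_band_closed_interval(self):
        fr = frame_from_coords([(0, 0, 0), (5.0, 0, 0)])
        assert pn.build_pcn(fr).adjacency[0, 1] == 1
        fr = frame_from_coords([(0, 0, 0), (3.8, 0, 0)])
        assert pn.build_pcn(fr).adjacency[0, 1] == 0  # backbone neighbours excluded
        for d, expect in [(4.0, 1), (8.0, 1), (8.0001, 0)]:
            fr = frame_from_coords([(0, 0, 0), (d, 0, 0)])
            assert pn.build_pcn(fr).adjacency[0, 1] == expect

    def test_collinear_chain(self):
        fr = frame_from_coords([(0, 0, 0), (6, 0, 0), (12, 0, 0)])
        A = pn.build_pcn(fr).adjacency
        assert A[0, 1] == A[1, 2] == 1 and A[0, 2] == 0

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(11)
        coords = rng.uniform(0, 20, size=(40, 3))
        fr = frame_from_coords(coords)
        # random rotation (QR of a Gaussian matrix) + translation
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = frame_from_coords(coords @ Q.T + np.array([5.0, -3.0, 12.0]))
        np.testing.assert_array_equal(
            pn.build_pcn(fr).adjacency, pn.build_pcn(moved).adjacency
        )

    def test_too_few_residues(self):
        with pytest.raises(ValueError):
            pn.build_pcn(frame_from_coords([(0, 0, 0)]))


class TestNodeDescriptors:
    def test_path_graph_closed_forms(self):
        net = net_from_edges(3, [(0, 1), (1, 2)])
        np.testing.assert_array_equal(pn.node_degrees(net), [1, 2, 1])
        np.testing.assert_allclose(pn.betweenness(net), [0, 1, 0])
        sp = pn.shortest_path_matrix(net)
        assert sp[0, 2] == 2
        np.testing.assert_allclose(pn.closeness(net), [1 / 3, 1 / 2, 1 / 3])

    def test_k4_and_triangle(self):
        k4 = net_from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])
        np.testing.assert_array_equal(pn.node_degrees(k4), [3, 3, 3, 3])
        tri = net_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        np.testing.assert_allclose(pn.clustering_coefficients(tri), [1, 1, 1])
        np.testing.assert_allclose(pn.closeness(tri), [0.5, 0.5, 0.5])

    def test_star_centre_clustering_zero(self):
        star = net_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        assert pn.clustering_coefficients(star)[0] == 0

    def test_four_cycle_betweenness(self):
        c4 = net_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
        np.testing.assert_allclose(pn.betweenness(c4), [0.5] * 4)

    def test_disconnected_pairs_flagged(self):
        net = net_from_edges(4, [(0, 1), (2, 3)])
        sp = pn.shortest_path_matrix(net)
        assert np.isinf(sp[0, 2]) and np.isfinite(sp[0, 1])
        close = pn.closeness(net)
        np.testing.assert_allclose(close, [1, 1, 1, 1])  # component-wise farness

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        net = random_geometric_net(rng.integers(20, 45), rng)
        A = net.adjacency
        np.testing.assert_array_equal(pn.node_degrees(net), A.sum(1))
        np.testing.assert_allclose(
            pn.shortest_path_matrix(net), floyd_warshall_sp(A)
        )
        oracle_btw = np.array([float(b) for b in path_count_betweenness(A)])
        np.testing.assert_allclose(pn.betweenness(net), oracle_btw, atol=1e-9)
        np.testing.assert_allclose(
            pn.clustering_coefficients(net), triangle_clustering(A), atol=1e-12
        )

    def test_betweenness_oracle_matches_literal_enumeration(self):
        # validates the counting oracle itself on tiny graphs
        rng = np.random.default_rng(99)
        for _ in range(10):
            net = random_geometric_net(7, rng, box=2.5)
            a = path_count_betweenness(net.adjacency)
            b = enumerate_betweenness(net.adjacency)
            assert a == b


class TestGraphEnergy:
    def test_closed_forms(self):
        k2 = net_from_edges(2, [(0, 1)])
        assert pn.graph_energy(k2) == pytest.approx(2.0, abs=1e-12)
        p3 = net_from_edges(3, [(0, 1), (1, 2)])
        assert pn.graph_energy(p3) == pytest.approx(2 * math.sqrt(2), abs=1e-10)

    def test_matches_dense_eigensolve(self):
        rng = np.random.default_rng(3)
        net = random_geometric_net(20, rng)
        lam = np.linalg.eigvals(net.adjacency.astype(float))
        assert pn.graph_energy(net) == pytest.approx(np.abs(lam).sum(), abs=1e-8)


class TestMixing:
    def test_segregated_cliques(self):
        edges = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        edges += [(i, j) for i in range(4, 8) for j in range(i + 1, 8)]
        edges += [(0, 4)]  # single cross edge keeps it connected
        net = net_from_edges(8, edges)
        classes = np.array([HYDROPHOBIC] * 4 + [POLAR] * 4, dtype=object)
        dy, h = pn.dyadicity_heterophilicity(net, classes)
        assert dy > 1 and h < 1

    def test_regular_graph_dba_flagged(self):
        c4 = net_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
        assert math.isnan(pn.degree_assortativity(c4))

    def test_mixing_against_explicit_expectation(self):
        rng = np.random.default_rng(7)
        net = random_geometric_net(30, rng)
        classes = rng.choice([HYDROPHOBIC, POLAR], size=30)
        dy, h = pn.dyadicity_heterophilicity(net, classes)
        n1 = (classes == HYDROPHOBIC).sum()
        n0 = 30 - n1
        m = net.n_edges
        hh = hp = 0
        for i in range(30):
            for j in range(i + 1, 30):
                if net.adjacency[i, j]:
                    a, b = classes[i] == HYDROPHOBIC, classes[j] == HYDROPHOBIC
                    hh += a and b
                    hp += a != b
        assert dy == pytest.approx(hh / (m * n1 * (n1 - 1) / (30 * 29)))
        assert h == pytest.approx(hp / (m * 2 * n1 * n0 / (30 * 29)))

    def test_value_assortativity_matches_manual_pearson(self):
        rng = np.random.default_rng(13)
        net = random_geometric_net(25, rng)
        vals = rng.normal(size=25)
        x, y = [], []
        for i in range(25):
            for j in range(25):
                if i != j and net.adjacency[i, j]:
                    x.append(vals[i])
                    y.append(vals[j])
        assert pn.value_assortativity(net, vals) == pytest.approx(
            np.corrcoef(x, y)[0, 1]
        )


class TestJaccard:
    def test_identity_disjoint_and_arithmetic(self):
        a = net_from_edges(5, [(0, 1), (1, 2), (2, 3)])
        assert pn.jaccard_similarity(a, a) == 1.0
        b = net_from_edges(5, [(0, 2), (1, 3)])
        assert pn.jaccard_similarity(a, b) == 0.0
        # M11 = 7, M10 = 2, M01 = 1  ->  0.7
        shared = [(0, i) for i in range(1, 6)] + [(1, 6), (2, 7)]
        a = net_from_edges(12, shared + [(3, 8), (4, 9)])
        b = net_from_edges(12, shared + [(5, 10)])
        assert pn.jaccard_similarity(a, b) == pytest.approx(0.7)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(21)
        a = random_geometric_net(20, rng)
        b = random_geometric_net(20, rng)
        jab = pn.jaccard_similarity(a, b)
        assert jab == pn.jaccard_similarity(b, a)
        assert 0 <= jab <= 1

    def test_node_mismatch_rejected(self):
        a = net_from_edges(3, [(0, 1)])
        b = net_from_edges(4, [(0, 1)])
        with pytest.raises(ValueError):
            pn.jaccard_similarity(a, b)


class TestDifferenceMap:
    def test_identical_descriptors_empty_selection(self):
        net = net_from_edges(5, [(0, 1), (1, 2), (2, 3), (3, 4)])
        d = pn.node_descriptors(net)
        dm = pn.difference_map(d, d)
        assert not dm.selected_k and not dm.selected_btw
        np.testing.assert_array_equal(dm.delta_k, 0)

    def test_strict_threshold_selection(self):
        net = net_from_edges(2, [(0, 1)])
        d_i = pn.node_descriptors(net)
        d_a = pn.node_descriptors(net)
        d_a.k = np.array([5, 9])
        d_i.k = np.array([5, 7])
        dm = pn.difference_map(d_a, d_i, theta_k=1)
        assert dm.selected_k == {"A:2"}
        np.testing.assert_array_equal(dm.delta_k, [0, 2])

    def test_threshold_nodes_strictness(self):
        assert pn.threshold_nodes(np.array([10.0, 11.0]), 10) == {1}
        assert pn.threshold_nodes(np.array([1.0, 2.0]), 5) == set()
        btw = np.zeros(10)
        btw[4] = 2000.0
        assert pn.threshold_nodes(btw, 1200) == {4}


class TestSummaryInvariants:
    def test_adeg_edge_identity_and_asp(self):
        rng = np.random.default_rng(17)
        net = random_geometric_net(30, rng)
        s = pn.network_summary(net, kd_values=rng.normal(size=30),
                               hp_classes=rng.choice([HYDROPHOBIC, POLAR], 30))
        assert s.adeg * 30 == pytest.approx(2 * net.n_edges)

    def test_summary_from_fold_frame(self):
        fold = make_fold(40, seed=2)
        net = pn.build_pcn(fold)
        s = pn.network_summary(net)
        assert 0 <= s.acc <= 1
        assert s.E >= 0
        assert -1 <= s.HBAKD <= 1 or math.isnan(s.HBAKD)

    def test_edge_removal_never_shortens_paths(self):
        rng = np.random.default_rng(23)
        net = random_geometric_net(25, rng)
        sp0 = pn.shortest_path_matrix(net)
        pairs = net.edge_index_pairs()
        i, j = pairs[len(pairs) // 2]
        A = net.adjacency.copy()
        A[i, j] = A[j, i] = 0
        sp1 = pn.shortest_path_matrix(pn.ContactNetwork(A, net.node_labels))
        assert np.all(sp1 >= sp0 - 1e-12)
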