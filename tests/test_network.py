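import numpy as np
import networkx as nx
import pytest
from scipy.spatial.transform import Rotation

from dimerlink import synthgen
from dimerlink.ensemble import Ensemble
from dimerlink.network import (
    ContactNetwork,
    NetworkParams,
    build_network,
    contact_occupancy,
    critical_edges,
    edge_betweenness,
    interprotomer_edges,
    residue_centers,
    shortest_path,
)

from graph_oracles import adj_from_edges, brute_edge_betweenness, min_weight_paths


def graph_network(edges, params=None) -> ContactNetwork:
    """ContactNetwork wrapper around an explicit weighted graph."""
    G = nx.Graph()
    for u, v, w in edges:
        G.add_edge(u, v, weight=w, occupancy=1.0, mean_distance=1.0)
    return ContactNetwork(graph=G, params=params or NetworkParams(), nodes=[])


def two_residue_ensemble(structure_factory, distances, name1="CA", name2="CA"):
    """Two single-atom residues on different chains at given per-frame distances."""
    top = structure_factory([
        ("A", 1, "GLY", name1, "C", (0.0, 0.0, 0.0)),
        ("B", 1, "GLY", name2, "C", (1.0, 0.0, 0.0)),
    ])
    frames = np.zeros((len(distances), 2, 3))
    frames[:, 1, 0] = distances
    return Ensemble(topology=top, frames=frames)


class TestResidueCenters:
    def test_hand_computed_mass_weighted_center(self, structure_factory):
        # glycine backbone N, CA, C, O with hand-picked coordinates
        xyz = {"N": (0.0, 0.0, 0.0), "CA": (1.5, 0.0, 0.0),
               "C": (2.0, 1.4, 0.0), "O": (2.0, 1.4, 1.2)}
        st = structure_factory([("A", 1, "GLY", n, n[0], x) for n, x in xyz.items()])
        ens = Ensemble(topology=st, frames=st.coords()[None])
        [node] = residue_centers(ens)
        m = {"N": 14.007, "C": 12.011, "O": 15.999}
        masses = np.array([m["N"], m["C"], m["C"], m["O"]])
        expected = (np.array(list(xyz.values())) * masses[:, None]).sum(0) / masses.sum()
        np.testing.assert_allclose(node.centers[0], expected, atol=1e-12)

    def test_single_atom_residue(self, structure_factory):
        st = structure_factory([("A", 7, "GLY", "CA", "C", (3.0, -2.0, 1.0))])
        ens = Ensemble(topology=st, frames=st.coords()[None])
        [node] = residue_centers(ens)
        np.testing.assert_allclose(node.centers[0], [3.0, -2.0, 1.0], atol=1e-12)

    def test_translation_equivariance(self, planted_small):
        ens, _ = planted_small
        sub = Ensemble(topology=ens.topology, frames=ens.frames[:3])
        shifted = Ensemble(topology=ens.topology, frames=ens.frames[:3] + np.array([1.0, 2.0, 3.0]))
        for a, b in zip(residue_centers(sub), residue_centers(shifted)):
            np.testing.assert_allclose(b.centers - a.centers, [[1.0, 2.0, 3.0]] * 3, atol=1e-12)

    def test_hydrogens_excluded_from_center(self, structure_factory):
        st = structure_factory([
            ("A", 1, "GLY", "CA", "C", (0.0, 0.0, 0.0)),
            ("A", 1, "GLY", "HA2", "H", (9.0, 9.0, 9.0)),
        ])
        ens = Ensemble(topology=st, frames=st.coords()[None])
        [node] = residue_centers(ens)
        np.testing.assert_array_equal(node.centers[0], [0.0, 0.0, 0.0])


class TestContactOccupancy:
    @pytest.mark.parametrize("distance,expected", [(4.4, 1.0), (4.6, 0.0)])
    def test_static_threshold(self, structure_factory, distance, expected):
        ens = two_residue_ensemble(structure_factory, [distance])
        occ, keys = contact_occupancy(ens, cutoff=4.5)
        assert occ[0, 1] == expected

    def test_fraction_of_frames(self, structure_factory):
        ens = two_residue_ensemble(structure_factory, [4.0, 4.4, 4.6, 5.0])
        occ, _ = contact_occupancy(ens, cutoff=4.5)
        assert occ[0, 1] == 0.5

    def test_brute_force_oracle_random_ensemble(self, structure_factory):
        rng = np.random.default_rng(11)
        atoms = []
        n_res, n_atoms_per, F = 20, 3, 4
        for i in range(1, n_res + 1):
            base = rng.uniform(0, 18, 3)
            for k, name in enumerate(["N", "CA", "C"][:n_atoms_per]):
                atoms.append(("A", i, "GLY", name, name[0], base + rng.uniform(-1, 1, 3)))
        top = structure_factory(atoms)
        frames = np.stack([top.coords() + rng.normal(0, 0.8, (len(atoms), 3)) for _ in range(F)])
        ens = Ensemble(topology=top, frames=frames)
        occ, keys = contact_occupancy(ens, cutoff=4.5)
        # brute force: min over all heavy-atom pairs, all frames
        expected = np.zeros((n_res, n_res))
        for f in range(F):
            X = frames[f].reshape(n_res, n_atoms_per, 3)
            for i in range(n_res):
                for j in range(i + 1, n_res):
                    d = np.linalg.norm(X[i][:, None] - X[j][None], axis=2).min()
                    if d <= 4.5:
                        expected[i, j] += 1
        expected = (expected + expected.T) / F
        np.testing.assert_allclose(occ, expected, atol=1e-12)


class TestEdgeWeights:
    def test_constant_distance_zero_weight(self, structure_factory):
        for convention in ("literal_var_over_mean", "sqrt_var_over_mean"):
            ens = two_residue_ensemble(structure_factory, [5.0, 5.0, 5.0])
            params = NetworkParams(contact_cutoff=6.0, weight_convention=convention)
            net = build_network(ens, params)
            assert net.graph.edges[("A", 1), ("B", 1)]["weight"] == 0.0

    def test_hand_computed_cv_series(self, structure_factory):
        # distances {4, 6, 8}: population mean 6, variance 8/3
        ens = two_residue_ensemble(structure_factory, [4.0, 6.0, 8.0])
        params = NetworkParams(contact_cutoff=10.0, occupancy_min=0.75)
        net = build_network(ens, params)
        w = net.graph.edges[("A", 1), ("B", 1)]
        assert abs(w["weight"] - (8.0 / 3.0) / 6.0) < 1e-12
        assert abs(w["mean_distance"] - 6.0) < 1e-12
        params_sqrt = NetworkParams(contact_cutoff=10.0, weight_convention="sqrt_var_over_mean")
        net2 = build_network(ens, params_sqrt)
        assert abs(net2.graph.edges[("A", 1), ("B", 1)]["weight"] - np.sqrt(8.0 / 3.0) / 6.0) < 1e-12

    def test_neighbor_exclusion(self, structure_factory):
        top = structure_factory([
            ("A", 1, "GLY", "CA", "C", (0.0, 0.0, 0.0)),
            ("A", 2, "GLY", "CA", "C", (3.0, 0.0, 0.0)),
            ("A", 3, "GLY", "CA", "C", (3.0, 3.0, 0.0)),
        ])
        ens = Ensemble(topology=top, frames=top.coords()[None].repeat(2, axis=0))
        net = build_network(ens, NetworkParams(contact_cutoff=5.0, neighbor_exclusion=1))
        assert not net.graph.has_edge(("A", 1), ("A", 2))
        assert net.graph.has_edge(("A", 1), ("A", 3))  # |Δ| = 2, distance 4.24
        net0 = build_network(ens, NetworkParams(contact_cutoff=5.0, neighbor_exclusion=0))
        assert net0.graph.has_edge(("A", 1), ("A", 2))

    def test_rigid_motion_invariance(self, planted_small):
        ens, _ = planted_small
        sub = Ensemble(topology=ens.topology, frames=ens.frames[:20])
        rng = np.random.default_rng(2)
        moved = sub.frames.copy()
        for f in range(moved.shape[0]):
            R = Rotation.random(random_state=np.random.RandomState(f + 1)).as_matrix()
            moved[f] = moved[f] @ R.T + rng.uniform(-20, 20, 3)
        net_a = build_network(sub)
        net_b = build_network(Ensemble(topology=sub.topology, frames=moved))
        assert set(net_a.graph.edges) == set(net_b.graph.edges)
        for e in net_a.graph.edges:
            assert abs(net_a.graph.edges[e]["weight"] - net_b.graph.edges[e]["weight"]) < 1e-9


class TestBetweenness:
    def test_three_node_path(self):
        net = graph_network([("a", "b", 1.0), ("b", "c", 1.0)])
        edge_betweenness(net)
        assert net.graph.edges["a", "b"]["betweenness"] == 2.0
        assert net.graph.edges["b", "c"]["betweenness"] == 2.0

    def test_single_edge(self):
        net = graph_network([("a", "b", 0.3)])
        edge_betweenness(net)
        assert net.graph.edges["a", "b"]["betweenness"] == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_random_graphs_match_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        nodes = list(range(n))
        edges = []
        for i in nodes:
            for j in nodes[i + 1:]:
                if rng.random() < 0.5:
                    edges.append((i, j, float(rng.uniform(0.1, 2.0))))
        if not edges:
            edges = [(0, 1, 1.0)]
        net = graph_network(edges)
        edge_betweenness(net)
        oracle = brute_edge_betweenness(adj_from_edges(edges))
        for u, v, d in net.graph.edges(data=True):
            assert abs(d["betweenness"] - oracle[frozenset((u, v))]) < 1e-9

    def test_co_optimal_split(self):
        # two equal-weight parallel routes s-a-t and s-b-t
        net = graph_network([("s", "a", 1.0), ("a", "t", 1.0), ("s", "b", 1.0), ("b", "t", 1.0)])
        edge_betweenness(net)
        # pair (s,t) splits 0.5/0.5 across routes; each edge also serves its endpoints
        oracle = brute_edge_betweenness(adj_from_edges(
            [("s", "a", 1.0), ("a", "t", 1.0), ("s", "b", 1.0), ("b", "t", 1.0)]))
        for u, v, d in net.graph.edges(data=True):
            assert abs(d["betweenness"] - oracle[frozenset((u, v))]) < 1e-12


class TestCriticalEdges:
    def test_uniform_distribution_yields_none(self):
        net = graph_network([("a", "b", 1.0), ("c", "d", 1.0), ("e", "f", 1.0)])
        edge_betweenness(net)
        assert critical_edges(net) == []

    def test_star_with_appended_path_flags_bridge(self):
        edges = [("hub", f"leaf{i}", 1.0) for i in range(5)]
        edges += [("hub", "p1", 1.0), ("p1", "p2", 1.0), ("p2", "p3", 1.0)]
        net = graph_network(edges)
        edge_betweenness(net)
        oracle = brute_edge_betweenness(adj_from_edges(edges))
        vals = np.array(list(oracle.values()))
        thresh = vals.mean() + 2.0 * vals.std()
        expected = {e for e, b in oracle.items() if b >= thresh}
        got = {frozenset(e) for e in critical_edges(net, sigma_k=2.0)}
        assert got == expected
        assert frozenset(("hub", "p1")) in got  # the bridge into the path

    def test_fewer_than_two_edges_warns_empty(self):
        net = graph_network([("a", "b", 1.0)])
        edge_betweenness(net)
        with pytest.warns(UserWarning):
            assert critical_edges(net) == []


class TestShortestPath:
    def test_two_node(self):
        net = graph_network([(("A", 1), ("B", 1), 0.27)])
        res = shortest_path(net, ("A", 1), ("B", 1))
        assert res.nodes == [("A", 1), ("B", 1)]
        assert abs(res.path_weight - 0.27) < 1e-12

    def test_planted_cheap_chain_vs_direct_edge(self):
        edges = [("s", "t", 1.0)]
        chain = ["s", "m1", "m2", "m3", "m4", "t"]
        edges += [(u, v, 0.1) for u, v in zip(chain, chain[1:])]
        net = graph_network(edges)
        res = shortest_path(net, "s", "t")
        best, co = min_weight_paths(adj_from_edges(edges), "s", "t")
        assert res.nodes == sorted(co)[0]
        assert abs(res.path_weight - best) < 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_random_graphs_match_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = 7
        edges = []
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.6:
                    edges.append((i, j, float(rng.uniform(0.05, 1.0))))
        net = graph_network(edges)
        adj = adj_from_edges(edges)
        for s in adj:
            for t in adj:
                if s >= t:
                    continue
                res = shortest_path(net, s, t)
                best, co = min_weight_paths(adj, s, t)
                if best is None:
                    assert not res.found
                else:
                    assert abs(res.path_weight - best) < 1e-9
                    assert res.nodes in co

    def test_disconnected_pair(self):
        net = graph_network([("a", "b", 1.0), ("c", "d", 1.0)])
        res = shortest_path(net, "a", "c")
        assert not res.found and res.nodes == []

    def test_co_optimal_alternates_enumerated(self):
        net = graph_network([("s", "a", 1.0), ("a", "t", 1.0), ("s", "b", 1.0), ("b", "t", 1.0)])
        res = shortest_path(net, "s", "t")
        assert len(res.alternates) == 1
        assert {tuple(res.nodes), tuple(res.alternates[0])} == {("s", "a", "t"), ("s", "b", "t")}


class TestScaleProperties:
    def test_doubling_weights_doubles_path_weight_only(self):
        rng = np.random.default_rng(9)
        edges = []
        for i in range(8):
            for j in range(i + 1, 8):
                if rng.random() < 0.5:
                    edges.append((i, j, float(rng.uniform(0.1, 1.0))))
        net1 = graph_network(edges)
        net2 = graph_network([(u, v, 2 * w) for u, v, w in edges])
        edge_betweenness(net1), edge_betweenness(net2)
        assert {frozenset(e) for e in critical_edges(net1)} == {frozenset(e) for e in critical_edges(net2)}
        for s in range(8):
            for t in range(s + 1, 8):
                if net1.graph.has_node(s) and net1.graph.has_node(t):
                    r1 = shortest_path(net1, s, t)
                    r2 = shortest_path(net2, s, t)
                    assert r1.nodes == r2.nodes
                    if r1.found:
                        assert abs(r2.path_weight - 2 * r1.path_weight) < 1e-9


class TestInterprotomer:
    def test_no_cross_contacts_empty(self, structure_factory):
        top = structure_factory([
            ("A", 1, "GLY", "CA", "C", (0.0, 0.0, 0.0)),
            ("A", 3, "GLY", "CA", "C", (4.0, 0.0, 0.0)),
            ("B", 1, "GLY", "CA", "C", (100.0, 0.0, 0.0)),
            ("B", 3, "GLY", "CA", "C", (104.0, 0.0, 0.0)),
        ])
        ens = Ensemble(topology=top, frames=top.coords()[None].repeat(2, 0))
        net = build_network(ens, NetworkParams(contact_cutoff=4.5))
        assert interprotomer_edges(net) == []

    def test_planted_three_cross_contacts(self):
        spec = synthgen.PlantedEnsembleSpec(seed=5, n_frames=300,
                                            interface_columns=(14, 15, 16), cross_column=14)
        ens, truth = synthgen.make_planted_ensemble(spec)
        assert len(truth.cross_contacts) == 3
        net = build_network(ens)
        got = {frozenset(e) for e in interprotomer_edges(net)}
        assert got == truth.cross_contacts

    def test_single_chain_warns(self, structure_factory):
        top = structure_factory([
            ("A", 1, "GLY", "CA", "C", (0.0, 0.0, 0.0)),
            ("A", 3, "GLY", "CA", "C", (4.0, 0.0, 0.0)),
        ])
        ens = Ensemble(topology=top, frames=top.coords()[None].repeat(2, 0))
        net = build_network(ens, NetworkParams(contact_cutoff=4.5))
        with pytest.warns(UserWarning):
            assert interprotomer_edges(net) == []


def test_planted_path_recovery(planted_small):
    ens, truth = planted_small
    net = build_network(ens)
    res = shortest_path(net, truth.path[0], truth.path[-1])
    assert res.nodes == truth.path
    assert set(net.graph.edges) == {tuple(sorted(e)) for e in truth.expected_edges()}
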