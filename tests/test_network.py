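"""DCCM, contact graph, optimal paths, communities."""

import itertools

import networkx as nx
import numpy as np
import pytest

from allodyn.core import Atom, Selection, Structure, Trajectory, select
from allodyn.network import (
    ContactEdge,
    CorrelationMatrix,
    _canonical_betweenness,
    _floyd_warshall,
    build_network,
    community_connectivity,
    contact_edges,
    dccm,
    girvan_newman_communities,
    threshold_for_display,
)


def _chain_structure(n, chain="A", spacing=10.0):
    atoms = [
        Atom(i + 1, "CA", "C", "ALA", i + 1, chain,
             np.array([i * spacing, 0.0, 0.0]))
        for i in range(n)
    ]
    return Structure(atoms=atoms)


def _traj(frames, top=None):
    frames = np.asarray(frames, dtype=float)
    top = top or _chain_structure(frames.shape[1])
    return Trajectory(topology=top, frames=frames)


def _brute_force_dccm(coords):
    """Literal per-frame evaluation of the displacement correlation."""
    mean = coords.mean(axis=0)
    disp = coords - mean
    n = coords.shape[1]
    c = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = np.mean([np.dot(disp[f, i], disp[f, j]) for f in range(len(coords))])
            den = np.sqrt(
                np.mean([np.dot(disp[f, i], disp[f, i]) for f in range(len(coords))])
                * np.mean([np.dot(disp[f, j], disp[f, j]) for f in range(len(coords))])
            )
            c[i, j] = num / den
    return c


class TestDccm:
    def test_self_correlation_is_one(self, rng):
        frames = rng.normal(size=(6, 3, 3)) + np.arange(3)[None, :, None] * 10
        m = dccm(_traj(frames), Selection(np.arange(3)), superpose=False)
        np.testing.assert_allclose(np.diag(m.C), 1.0, atol=1e-12)

    def test_mirror_motion_is_anticorrelated(self):
        base = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        frames = []
        for d in (-1.0, 1.0, -0.5, 0.5):
            f = base.copy()
            f[0, 0] += d
            f[1, 0] -= d
            frames.append(f)
        m = dccm(_traj(np.array(frames)), Selection(np.arange(2)), superpose=False)
        assert m.C[0, 1] == pytest.approx(-1.0)

    def test_orthogonal_motion_uncorrelated(self, rng):
        base = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        frames = []
        signs = [(1, 1), (1, -1), (-1, 1), (-1, -1)]
        for sx, sy in signs:
            f = base.copy()
            f[0, 0] += sx
            f[1, 1] += sy
            frames.append(f)
        m = dccm(_traj(np.array(frames)), Selection(np.arange(2)), superpose=False)
        assert m.C[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            n_atoms = rng.integers(2, 6)
            n_frames = rng.integers(2, 11)
            frames = rng.normal(size=(n_frames, n_atoms, 3))
            top = _chain_structure(int(n_atoms))
            m = dccm(_traj(frames, top), Selection(np.arange(n_atoms)),
                     superpose=False)
            np.testing.assert_allclose(m.C, _brute_force_dccm(frames), atol=1e-9)

    def test_zero_fluctuation_named(self):
        frames = np.zeros((4, 2, 3))
        frames[:, 1, 0] = [0.0, 1.0, 0.0, 1.0]
        with pytest.raises(ValueError, match="A/1/CA"):
            dccm(_traj(frames), Selection(np.arange(2)), superpose=False)

    def test_superposition_removes_rigid_motion(self, rng):
        """A rigidly translating pair plus noise shows no spurious strong
        correlation once frames are superposed."""
        base = np.array([[0.0, 0, 0], [5.0, 3, 0], [2.0, 7, 4]])
        frames = np.stack(
            [base + t * np.array([1.0, 2.0, 0.0]) +
             rng.normal(scale=0.1, size=base.shape)
             for t in range(20)]
        )
        m = dccm(_traj(frames), Selection(np.arange(3)), superpose=True)
        assert np.all(np.abs(m.C[np.triu_indices(3, 1)]) < 0.9)


class TestThreshold:
    def test_cutoff_rule(self):
        c = np.array([[1.0, 0.29, -0.31], [0.29, 1.0, 0.5], [-0.31, 0.5, 1.0]])
        labels = [("A", 1), ("A", 2), ("A", 3)]
        masked = threshold_for_display(CorrelationMatrix(labels=labels, C=c))
        assert masked.mask[0, 1] and not masked.mask[0, 2]
        assert not masked.mask[1, 2]
        assert not masked.mask.diagonal().any()

    def test_identity_unchanged(self):
        labels = [("A", 1), ("A", 2)]
        masked = threshold_for_display(
            CorrelationMatrix(labels=labels, C=np.eye(2))
        )
        assert masked.mask.sum() == 2  # only the zero off-diagonals


class TestContactEdges:
    def _two_residue_traj(self, distances, chain_b="B"):
        atoms = [
            Atom(1, "CA", "C", "ALA", 1, "A", np.zeros(3)),
            Atom(2, "CA", "C", "ALA", 1, chain_b, np.array([1.0, 0, 0])),
        ]
        top = Structure(atoms=atoms)
        frames = np.stack(
            [np.array([[0.0, 0, 0], [d, 0, 0]]) for d in distances]
        )
        return Trajectory(topology=top, frames=frames)

    def test_persistent_contact(self):
        traj = self._two_residue_traj([4.0] * 8)
        edges = contact_edges(traj)
        assert len(edges) == 1
        assert edges[0].occupancy == 1.0

    def test_half_occupancy_excluded(self):
        traj = self._two_residue_traj([4.0] * 4 + [6.0] * 4)
        assert contact_edges(traj) == []

    def test_sequence_neighbors_excluded(self):
        atoms = [
            Atom(1, "CA", "C", "ALA", 1, "A", np.zeros(3)),
            Atom(2, "CA", "C", "ALA", 2, "A", np.array([3.8, 0, 0])),
        ]
        traj = Trajectory(
            topology=Structure(atoms=atoms),
            frames=np.stack([np.array([[0.0, 0, 0], [3.8, 0, 0]])] * 3),
        )
        assert contact_edges(traj) == []
        assert len(contact_edges(traj, exclude_sequence_neighbors=False)) == 1

    def test_planted_topology_recovered(self, network_study):
        """Edges are exactly the planted intra-block contacts (minus the
        sequence-neighbour pairs) plus the inter-block bridge pairs."""
        model, traj = network_study
        part = model.planted_partition
        label_of = {
            (model.chain_ids[i], int(model.residue_ids[i])): int(part[i])
            for i in range(model.n_beads)
        }
        edges = contact_edges(traj)
        inter = [e for e in edges if label_of[e.a] != label_of[e.b]]
        intra = [e for e in edges if label_of[e.a] == label_of[e.b]]
        assert len(inter) == 6  # one bridge per adjacent block pair per chain
        # every intra-block non-neighbour rest-contact pair is recovered
        assert len(intra) == 8 * (45 - 9)


def _matrix_for(nodes, strength=0.5):
    labels = [("A", i + 1) for i in range(nodes)]
    c = np.full((nodes, nodes), strength)
    np.fill_diagonal(c, 1.0)
    return CorrelationMatrix(labels=labels, C=c)


def _edge(i, j, occ=1.0):
    return ContactEdge(a=("A", i + 1), b=("A", j + 1), occupancy=occ)


class TestBuildNetwork:
    def test_path_graph_betweenness(self):
        m = _matrix_for(3)
        net = build_network([_edge(0, 1), _edge(1, 2)], m)
        assert net.path(0, 2) == [0, 1, 2]
        assert net.edge_betweenness == {(0, 1): 2, (1, 2): 2}

    def test_weak_edge_bypassed_in_triangle(self):
        labels = [("A", 1), ("A", 2), ("A", 3)]
        c = np.array(
            [[1.0, 0.9, 0.05], [0.9, 1.0, 0.9], [0.05, 0.9, 1.0]]
        )
        m = CorrelationMatrix(labels=labels, C=c)
        net = build_network([_edge(0, 1), _edge(1, 2), _edge(0, 2)], m)
        assert net.path(0, 2) == [0, 1, 2]  # the weak direct edge is longer
        # even its endpoint pair routes around it, so it carries no paths
        assert net.edge_betweenness.get((0, 2), 0) == 0
        assert net.edge_betweenness[(0, 1)] == 2

    def test_single_edge(self):
        net = build_network([_edge(0, 1)], _matrix_for(2))
        assert net.edge_betweenness == {(0, 1): 1}

    def test_disconnected_pairs_carry_no_paths(self):
        net = build_network([_edge(0, 1)], _matrix_for(3))
        assert not np.isfinite(net.dist[0, 2])
        assert sum(net.edge_betweenness.values()) == 1

    def test_floyd_warshall_matches_dijkstra(self, rng):
        """All-pairs costs equal networkx Dijkstra on random graphs."""
        for _ in range(100):
            n = int(rng.integers(2, 31))
            g = nx.gnp_random_graph(n, 0.25, seed=int(rng.integers(1 << 30)))
            for u, v in g.edges:
                g.edges[u, v]["weight"] = float(rng.uniform(0.05, 3.0))
            dist, nxt = _floyd_warshall(
                n, [(u, v, g.edges[u, v]["weight"]) for u, v in g.edges]
            )
            lengths = dict(nx.all_pairs_dijkstra_path_length(g))
            for i in range(n):
                for j in range(n):
                    if j in lengths[i]:
                        assert dist[i, j] == pytest.approx(lengths[i][j], abs=1e-9)
                    else:
                        assert not np.isfinite(dist[i, j])

    def test_betweenness_sums_to_total_path_edges(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 15))
            g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(1 << 30)))
            edges = [(u, v, float(rng.uniform(0.1, 2.0))) for u, v in g.edges]
            dist, nxt = _floyd_warshall(n, edges)
            bet = _canonical_betweenness(n, dist, nxt)
            total = 0
            for i in range(n):
                for j in range(i + 1, n):
                    if np.isfinite(dist[i, j]):
                        u = i
                        while u != j:
                            u = int(nxt[u, j])
                            total += 1
            assert sum(bet.values()) == total


def _exhaustive_best_modularity(g):
    """Maximum Newman-Girvan modularity over all partitions (oracle)."""
    nodes = list(g.nodes)

    def partitions(collection):
        if len(collection) == 1:
            yield [collection]
            return
        first, rest = collection[0], collection[1:]
        for smaller in partitions(rest):
            for i, subset in enumerate(smaller):
                yield smaller[:i] + [[first] + subset] + smaller[i + 1:]
            yield [[first]] + smaller

    best_q, best_p = -1.0, None
    for p in partitions(nodes):
        q = nx.community.modularity(g, [set(s) for s in p])
        if q > best_q:
            best_q, best_p = q, p
    return best_q, best_p


class TestGirvanNewman:
    def _net_from_graph(self, g, strength=0.5):
        n = g.number_of_nodes()
        m = _matrix_for(n, strength)
        edges = [_edge(u, v) for u, v in g.edges]
        return build_network(edges, m)

    def test_barbell_cliques_match_exhaustive_optimum(self):
        g = nx.Graph()
        for base in (0, 4):
            for u, v in itertools.combinations(range(base, base + 4), 2):
                g.add_edge(u, v)
        g.add_edge(0, 4)
        part = girvan_newman_communities(self._net_from_graph(g))
        groups = {}
        for node, cid in enumerate(part.community):
            groups.setdefault(int(cid), set()).add(node)
        assert sorted(map(sorted, groups.values())) == [
            [0, 1, 2, 3], [4, 5, 6, 7],
        ]
        best_q, _ = _exhaustive_best_modularity(g)
        assert part.modularity == pytest.approx(best_q, abs=1e-12)
        assert part.discarded == set()

    def test_complete_graph_single_community(self):
        g = nx.complete_graph(5)
        part = girvan_newman_communities(self._net_from_graph(g))
        assert len(set(part.community.tolist())) == 1

    def test_small_community_discarded(self):
        g = nx.complete_graph(4)
        g.add_edge(4, 5)
        part = girvan_newman_communities(self._net_from_graph(g))
        pair_cid = int(part.community[4])
        assert part.community[5] == pair_cid
        assert pair_cid in part.discarded
        assert part.reported_communities == [int(part.community[0])]

    def test_edgeless_graph(self):
        m = _matrix_for(3)
        part = girvan_newman_communities(build_network([], m))
        assert part.modularity == 0.0
        assert len(set(part.community.tolist())) == 3
        assert part.discarded == {0, 1, 2}

    def test_planted_partition_recovered(self, network_study):
        from sklearn.metrics import adjusted_rand_score

        model, traj = network_study
        matrix = dccm(traj, select(traj.topology, atom_names={"CA"}))
        edges = contact_edges(traj)
        net = build_network(edges, matrix)
        part = girvan_newman_communities(net)
        ari = adjusted_rand_score(model.planted_partition, part.community)
        assert ari == pytest.approx(1.0)


class TestCommunityConnectivity:
    def test_bridge_scores(self):
        g = nx.Graph()
        for base in (0, 4):
            for u, v in itertools.combinations(range(base, base + 4), 2):
                g.add_edge(u, v)
        g.add_edge(0, 4)
        m = _matrix_for(8)
        net = build_network([_edge(u, v) for u, v in g.edges], m)
        part = girvan_newman_communities(net)
        conn = community_connectivity(net, part)
        assert len(conn) == 1
        ((pair, score),) = conn.items()
        assert score == net.edge_betweenness[(0, 4)]

    def test_max_rule_over_parallel_bridges(self):
        labels = [("A", i + 1) for i in range(4)]
        c = np.full((4, 4), 0.5)
        np.fill_diagonal(c, 1.0)
        m = CorrelationMatrix(labels=labels, C=c)
        net = build_network(
            [_edge(0, 1), _edge(2, 3), _edge(0, 2), _edge(1, 3)], m
        )
        net.edge_betweenness = {(0, 1): 1, (2, 3): 1, (0, 2): 5, (1, 3): 9}
        from allodyn.network import CommunityPartition

        part = CommunityPartition(
            node_labels=labels,
            community=np.array([0, 0, 1, 1]),
            discarded=set(),
            modularity=0.0,
        )
        conn = community_connectivity(net, part)
        assert conn == {(0, 1): 9}

    def test_unconnected_pair_absent(self):
        labels = [("A", i + 1) for i in range(4)]
        c = np.full((4, 4), 0.5)
        np.fill_diagonal(c, 1.0)
        m = CorrelationMatrix(labels=labels, C=c)
        net = build_network([_edge(0, 1), _edge(2, 3)], m)
        from allodyn.network import CommunityPartition

        part = CommunityPartition(
            node_labels=labels,
            community=np.array([0, 0, 1, 1]),
            discarded=set(),
            modularity=0.0,
        )
        assert community_connectivity(net, part) == {}
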