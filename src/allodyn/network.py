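"""Dynamic cross-correlation and dynamical community networks.

The dynamic cross-correlation matrix (DCCM) between C-alpha displacement
vectors measures how residue pairs move together:

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2> <|dr_j|^2>)

with dr_i(t) the displacement of atom i from its mean position after
rigid-body superposition of every frame onto the iteratively refined mean
structure; +1 is fully correlated motion, -1 fully anticorrelated.

The dynamical network puts one node per residue (its C-alpha) and an
undirected edge between residues whose minimum heavy-atom distance stays
within a cutoff (default 4.5 A) for at least an occupancy fraction of the
trajectory (default 75%); same-chain sequence neighbours are excluded.
Edges are weighted w = -ln|C_ij| so strongly correlated contacts are
short.  Optimal paths between all node pairs come from the
Floyd-Warshall algorithm with a deterministic tie-break (paths through
lower-index intermediates win); the betweenness of an edge is the number
of pairwise optimal paths crossing it.  Communities are found by
Girvan-Newman edge removal, keeping the intermediate partition that
maximizes Newman-Girvan modularity on the original contact graph;
communities with fewer than three residues are discarded from reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .core import Selection, Trajectory
from .landscape import kabsch_superpose

ResidueLabel = tuple[str, int]  # (chain_id, residue_id)

_MIN_ABS_CORRELATION = 1e-6  # floor for |C_ij| in edge weights


@dataclass
class CorrelationMatrix:
    """Residue-residue correlation coefficients in [-1, 1]."""

    labels: list[ResidueLabel]
    C: np.ndarray

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=float)
        r = len(self.labels)
        if self.C.shape != (r, r):
            raise ValueError("C must be square with one row per label")
        if not np.allclose(self.C, self.C.T, atol=1e-9):
            raise ValueError("C must be symmetric")
        if not np.allclose(np.diag(self.C), 1.0, atol=1e-9):
            raise ValueError("diagonal of C must be 1")
        if np.any(np.abs(self.C) > 1.0 + 1e-9):
            raise ValueError("entries of C must lie in [-1, 1]")

    def to_dataframe(self):
        import pandas as pd

        names = [f"{c}{r}" for c, r in self.labels]
        return pd.DataFrame(self.C, index=names, columns=names)


def _superpose_to_mean(
    coords: np.ndarray, tol: float = 1e-6, max_iter: int = 20
) -> np.ndarray:
    """Superpose frames onto the iteratively recomputed mean structure."""
    ref = coords[0]
    fitted = coords.copy()
    for _ in range(max_iter):
        for f in range(coords.shape[0]):
            rot, trans, _ = kabsch_superpose(coords[f], ref)
            fitted[f] = coords[f] @ rot.T + trans
        mean = fitted.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((mean - ref) ** 2, axis=1))))
        ref = mean
        if shift < tol:
            break
    return fitted


def dccm(
    traj: Trajectory, ca_selection: Selection, superpose: bool = True
) -> CorrelationMatrix:
    """Dynamic cross-correlation matrix over the selected C-alpha atoms.

    Frames are first superposed onto the iteratively recomputed mean
    structure (whole selection, i.e. the whole dimer) so that global
    rotation/translation does not masquerade as correlated motion;
    ``superpose=False`` computes raw displacement correlations for
    pre-aligned input.
    """
    idx = ca_selection.indices
    if idx.size < 2:
        raise ValueError("correlation needs at least 2 selected atoms")
    if traj.n_frames < 2:
        raise ValueError("correlation needs at least 2 frames")
    coords = traj.frames[:, idx, :]
    fitted = _superpose_to_mean(coords) if superpose else coords.copy()
    mean = fitted.mean(axis=0)
    disp = fitted - mean  # (F, R, 3)
    msf = np.mean(np.sum(disp**2, axis=2), axis=0)  # <|dr_i|^2>
    zero = np.nonzero(msf <= 0)[0]
    if zero.size:
        a = traj.topology.atoms[idx[zero[0]]]
        raise ValueError(
            f"atom {a.chain_id}/{a.residue_id}/{a.name} has zero total "
            "fluctuation; correlation undefined"
        )
    cov = np.einsum("fik,fjk->ij", disp, disp) / disp.shape[0]
    c = cov / np.sqrt(np.outer(msf, msf))
    c = np.clip(c, -1.0, 1.0)
    c = 0.5 * (c + c.T)
    np.fill_diagonal(c, 1.0)
    labels = [
        (traj.topology.atoms[i].chain_id, traj.topology.atoms[i].residue_id)
        for i in idx
    ]
    return CorrelationMatrix(labels=labels, C=c)


def threshold_for_display(
    matrix: CorrelationMatrix, cutoff: float = 0.3
) -> np.ma.MaskedArray:
    """Mask weak entries (|C_ij| < cutoff) for display; diagonal retained."""
    mask = np.abs(matrix.C) < cutoff
    np.fill_diagonal(mask, False)
    return np.ma.masked_array(matrix.C, mask=mask)


@dataclass(frozen=True)
class ContactEdge:
    a: ResidueLabel
    b: ResidueLabel
    occupancy: float


def contact_edges(
    traj: Trajectory,
    cutoff: float = 4.5,
    occupancy: float = 0.75,
    mode: str = "heavy",
    exclude_sequence_neighbors: bool = True,
) -> list[ContactEdge]:
    """Persistent residue-residue contacts over the trajectory.

    A residue pair is in contact in a frame when its minimum inter-residue
    distance over heavy atoms (``mode="heavy"``) or C-alpha atoms
    (``mode="ca"``) is within ``cutoff``; an edge is emitted when the
    contact holds in at least the ``occupancy`` fraction of frames.
    Same-chain i, i+-1 pairs are excluded by default.
    """
    top = traj.topology
    if mode == "heavy":
        atom_idx = [i for i, a in enumerate(top.atoms) if a.element != "H"]
    elif mode == "ca":
        atom_idx = [i for i, a in enumerate(top.atoms) if a.name == "CA"]
    else:
        raise ValueError("mode must be 'heavy' or 'ca'")
    if not atom_idx:
        return []
    atom_idx = np.asarray(atom_idx, dtype=int)
    res_of_atom = np.empty(atom_idx.size, dtype=int)
    labels: list[ResidueLabel] = []
    lookup: dict[ResidueLabel, int] = {}
    for k, i in enumerate(atom_idx):
        a = top.atoms[i]
        key = (a.chain_id, a.residue_id)
        if key not in lookup:
            lookup[key] = len(labels)
            labels.append(key)
        res_of_atom[k] = lookup[key]

    pair_counts: dict[tuple[int, int], int] = {}
    for f in range(traj.n_frames):
        pts = traj.frames[f][atom_idx]
        tree = cKDTree(pts)
        seen: set[tuple[int, int]] = set()
        for ia, ib in tree.query_pairs(cutoff):
            ra, rb = res_of_atom[ia], res_of_atom[ib]
            if ra == rb:
                continue
            key = (min(ra, rb), max(ra, rb))
            seen.add(key)
        for key in seen:
            pair_counts[key] = pair_counts.get(key, 0) + 1

    edges = []
    for (ra, rb), cnt in sorted(pair_counts.items()):
        la, lb = labels[ra], labels[rb]
        if (
            exclude_sequence_neighbors
            and la[0] == lb[0]
            and abs(la[1] - lb[1]) <= 1
        ):
            continue
        frac = cnt / traj.n_frames
        if frac >= occupancy:
            edges.append(ContactEdge(a=la, b=lb, occupancy=frac))
    return edges


@dataclass
class DynamicalNetwork:
    """Residue nodes, occupancy-filtered weighted edges and optimal paths."""

    labels: list[ResidueLabel]
    edges: list[tuple[int, int, float, float]]  # (i, j, occupancy, weight)
    dist: np.ndarray = field(repr=False, default=None)
    nxt: np.ndarray = field(repr=False, default=None)
    edge_betweenness: dict[tuple[int, int], int] = field(default_factory=dict)

    def path(self, i: int, j: int) -> list[int]:
        """The canonical optimal node path from i to j (inclusive)."""
        if not np.isfinite(self.dist[i, j]):
            raise ValueError(f"nodes {i} and {j} are disconnected")
        out = [i]
        while i != j:
            i = int(self.nxt[i, j])
            out.append(i)
        return out

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.labels)))
        for i, j, occ, w in self.edges:
            g.add_edge(
                i,
                j,
                occupancy=occ,
                weight=w,
                betweenness=self.edge_betweenness.get((min(i, j), max(i, j)), 0),
            )
        return g


def _floyd_warshall(
    n: int, weighted_edges: list[tuple[int, int, float]]
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs shortest paths with successor table.

    Updates are strict improvements, so among co-optimal paths the one
    routed through the lowest-index intermediate node is kept.
    """
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    nxt = np.full((n, n), -1, dtype=int)
    nxt[np.diag_indices(n)] = np.arange(n)
    for i, j, w in weighted_edges:
        if w < dist[i, j]:
            dist[i, j] = dist[j, i] = w
            nxt[i, j] = j
            nxt[j, i] = i
    for k in range(n):
        alt = dist[:, k, None] + dist[None, k, :]
        better = alt < dist - 1e-12
        dist = np.where(better, alt, dist)
        nxt = np.where(better, nxt[:, k, None], nxt)
    return dist, nxt


def _canonical_betweenness(
    n: int, dist: np.ndarray, nxt: np.ndarray
) -> dict[tuple[int, int], int]:
    """Count, per edge, the canonical optimal paths over connected pairs."""
    bet: dict[tuple[int, int], int] = {}
    for i in range(n):
        for j in range(i + 1, n):
            if not np.isfinite(dist[i, j]):
                continue
            u = i
            while u != j:
                v = int(nxt[u, j])
                key = (min(u, v), max(u, v))
                bet[key] = bet.get(key, 0) + 1
                u = v
    return bet


def build_network(
    edges: list[ContactEdge],
    matrix: CorrelationMatrix,
    weight: str = "neglog",
) -> DynamicalNetwork:
    """Assemble the dynamical network from contacts and correlations.

    Edge weights default to w = -ln|C_ij| (|C_ij| floored at 1e-6), the
    standard choice making highly correlated contacts short.  Optimal
    paths and canonical edge betweenness are computed immediately;
    disconnected node pairs simply contribute no paths.
    """
    if weight != "neglog":
        raise ValueError("only the 'neglog' weight functional is implemented")
    index = {lab: k for k, lab in enumerate(matrix.labels)}
    n = len(matrix.labels)
    net_edges: list[tuple[int, int, float, float]] = []
    for e in edges:
        if e.a not in index or e.b not in index:
            raise ValueError(
                f"contact edge {e.a}-{e.b} has no correlation row"
            )
        i, j = index[e.a], index[e.b]
        c = max(abs(matrix.C[i, j]), _MIN_ABS_CORRELATION)
        w = -np.log(c)
        if w <= 0:  # |C| == 1 would give a zero-length edge
            w = 1e-12
        net_edges.append((min(i, j), max(i, j), e.occupancy, float(w)))
    net_edges.sort()
    dist, nxt = _floyd_warshall(n, [(i, j, w) for i, j, _, w in net_edges])
    bet = _canonical_betweenness(n, dist, nxt)
    return DynamicalNetwork(
        labels=list(matrix.labels),
        edges=net_edges,
        dist=dist,
        nxt=nxt,
        edge_betweenness=bet,
    )


@dataclass
class CommunityPartition:
    """Community label per node; small communities marked discarded."""

    node_labels: list[ResidueLabel]
    community: np.ndarray  # community id per node
    discarded: set[int]  # community ids with < 3 residues
    modularity: float

    def members(self, cid: int) -> list[int]:
        return [i for i, c in enumerate(self.community) if c == cid]

    @property
    def reported_communities(self) -> list[int]:
        return sorted(set(self.community.tolist()) - self.discarded)


def _components_partition(n: int, edge_set: set[tuple[int, int]]) -> np.ndarray:
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for i, j in edge_set:
        adj[i].add(j)
        adj[j].add(i)
    labels = np.full(n, -1, dtype=int)
    cid = 0
    for start in range(n):
        if labels[start] != -1:
            continue
        stack = [start]
        labels[start] = cid
        while stack:
            for nb in adj[stack.pop()]:
                if labels[nb] == -1:
                    labels[nb] = cid
                    stack.append(nb)
        cid += 1
    return labels


def _modularity(
    original: nx.Graph, labels: np.ndarray, weighted: bool
) -> float:
    if original.number_of_edges() == 0:
        return 0.0
    groups: dict[int, set[int]] = {}
    for node, lab in enumerate(labels):
        groups.setdefault(int(lab), set()).add(node)
    return nx.community.modularity(
        original,
        list(groups.values()),
        weight="weight" if weighted else None,
    )


def girvan_newman_communities(
    net: DynamicalNetwork, weighted_modularity: bool = False
) -> CommunityPartition:
    """Girvan-Newman partition maximizing modularity on the original graph.

    The highest-betweenness edge (canonical optimal-path betweenness,
    recomputed after every removal; ties broken by lexicographic edge
    order) is removed iteratively; each intermediate connected-component
    partition is scored by Newman-Girvan modularity on the original,
    unweighted contact graph (weighted on request) and the first partition
    achieving the maximum is returned.  Communities with fewer than three
    residues are marked discarded.
    """
    n = len(net.labels)
    if n < 1:
        raise ValueError("network has no nodes")
    original = net.to_graph()
    current: set[tuple[int, int]] = {(i, j) for i, j, _, _ in net.edges}
    weights = {(i, j): w for i, j, _, w in net.edges}

    best_labels = _components_partition(n, current)
    best_q = _modularity(original, best_labels, weighted_modularity)
    while current:
        dist, nxt = _floyd_warshall(
            n, [(i, j, weights[(i, j)]) for i, j in current]
        )
        bet = _canonical_betweenness(n, dist, nxt)
        target = max(sorted(bet), key=lambda e: bet[e])
        current.discard(target)
        labels = _components_partition(n, current)
        q = _modularity(original, labels, weighted_modularity)
        if q > best_q + 1e-12:
            best_q = q
            best_labels = labels
    sizes: dict[int, int] = {}
    for lab in best_labels:
        sizes[int(lab)] = sizes.get(int(lab), 0) + 1
    discarded = {cid for cid, s in sizes.items() if s < 3}
    return CommunityPartition(
        node_labels=list(net.labels),
        community=best_labels,
        discarded=discarded,
        modularity=float(best_q),
    )


def community_connectivity(
    net: DynamicalNetwork, partition: CommunityPartition
) -> dict[tuple[int, int], int]:
    """Max edge betweenness between each connected pair of communities.

    Discarded communities are excluded; community pairs with no
    connecting edge are absent from the result.
    """
    scores: dict[tuple[int, int], int] = {}
    for i, j, _, _ in net.edges:
        ca = int(partition.community[i])
        cb = int(partition.community[j])
        if ca == cb or ca in partition.discarded or cb in partition.discarded:
            continue
        key = (min(ca, cb), max(ca, cb))
        b = net.edge_betweenness.get((min(i, j), max(i, j)), 0)
        if b > scores.get(key, -1):
            scores[key] = b
    return scores
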