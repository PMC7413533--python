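"""Reaction coordinates and 2-D free-energy landscapes.

Two reaction coordinates summarize the conformational ensemble of a
homodimeric DNA-binding regulator: (x) the C-alpha RMSD of the
DNA-binding domain to a reference structure, pooled over both chains, and
(y) the separation of the two recognition helices, measured between the
C-alpha atoms of the probe residue on each chain (A71/A71' for ZitR).

The potential of mean force over a trajectory is estimated from the
normalized joint histogram g(x, y) on a 30 x 30 grid as

    dG(x, y) = -kB T ln g(x, y),

shifted so the most populated (defined) bin sits at dG = 0; empty bins
are undefined (NaN).  Energy basins are bins strictly lower than every
defined 8-neighbor; each basin's representative frame is the medoid of
the dominant cluster of its member frames under average-linkage
hierarchical clustering on domain RMSD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core import KB, RegionConfig, Structure, Trajectory, select


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns (rotation, translation, rmsd) such that
    ``mobile @ rotation.T + translation`` best fits ``reference``; the
    rotation is proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must both have shape (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    for pts, which in ((mob_c, "mobile"), (ref_c, "reference")):
        sv = np.linalg.svd(pts, compute_uv=False)
        if sv[0] < 1e-12 or sv[1] / sv[0] < 1e-9:
            raise ValueError(f"{which} points are degenerate (collinear)")
    h = mob_c.T @ ref_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = reference.mean(axis=0) - mobile.mean(axis=0) @ rot.T
    fitted = mobile @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return rot, trans, rmsd


def _domain_ca_keys(structure: Structure, region: RegionConfig) -> list[tuple]:
    lo, hi = region.dna_binding_domain
    keys = []
    for a in structure.atoms:
        if (
            a.name == "CA"
            and a.chain_id in region.protein_chains
            and lo <= a.residue_id <= hi
        ):
            keys.append((a.chain_id, a.residue_id))
    return keys


def _matched_domain_indices(
    traj_top: Structure, reference: Structure, region: RegionConfig
) -> tuple[np.ndarray, np.ndarray]:
    traj_keys = _domain_ca_keys(traj_top, region)
    ref_keys = _domain_ca_keys(reference, region)
    if not traj_keys or not ref_keys:
        raise ValueError(
            "DNA-binding-domain C-alpha selection is empty; check the "
            "dna_binding_domain range and chain ids of the region config"
        )
    if set(traj_keys) != set(ref_keys):
        missing = sorted(set(traj_keys) ^ set(ref_keys))
        raise ValueError(
            "domain C-alpha sets differ between trajectory and reference; "
            f"unmatched (chain, residue) entries: {missing}"
        )

    def ca_indices(structure):
        lookup = {}
        lo, hi = region.dna_binding_domain
        for i, a in enumerate(structure.atoms):
            if (
                a.name == "CA"
                and a.chain_id in region.protein_chains
                and lo <= a.residue_id <= hi
            ):
                lookup[(a.chain_id, a.residue_id)] = i
        return lookup

    order = sorted(traj_keys)
    tl = ca_indices(traj_top)
    rl = ca_indices(reference)
    return (
        np.array([tl[k] for k in order], dtype=int),
        np.array([rl[k] for k in order], dtype=int),
    )


def domain_rmsd(
    traj: Trajectory,
    reference: Structure,
    region: RegionConfig,
    fit_indices: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame C-alpha RMSD of the DNA-binding domain, both chains pooled.

    Each frame is superposed onto the reference over the domain C-alpha
    atoms themselves (or, if ``fit_indices`` names a different atom set of
    the trajectory topology, over that set, e.g. the dimerization core)
    and the RMSD is reported over the domain set.
    """
    ti, ri = _matched_domain_indices(traj.topology, reference, region)
    ref_domain = reference.coordinates[ri]
    out = np.empty(traj.n_frames)
    if fit_indices is None:
        for f in range(traj.n_frames):
            _, _, out[f] = kabsch_superpose(traj.frames[f][ti], ref_domain)
    else:
        fit_idx = np.asarray(fit_indices, dtype=int)
        ref_fit = reference.coordinates[fit_idx]
        for f in range(traj.n_frames):
            rot, trans, _ = kabsch_superpose(traj.frames[f][fit_idx], ref_fit)
            fitted = traj.frames[f][ti] @ rot.T + trans
            out[f] = np.sqrt(np.mean(np.sum((fitted - ref_domain) ** 2, axis=1)))
    return out


def _probe_indices(structure: Structure, region: RegionConfig) -> tuple[int, int]:
    hits = [
        i
        for i, a in enumerate(structure.atoms)
        if a.name == "CA"
        and a.residue_id == region.probe_residue
        and a.chain_id in region.protein_chains
    ]
    if len(hits) != 2:
        raise ValueError(
            f"probe residue {region.probe_residue} must have exactly one "
            f"C-alpha in each of the two protein chains; found {len(hits)}"
        )
    return hits[0], hits[1]


def interhelix_distance(
    traj: Trajectory | Structure, region: RegionConfig
) -> np.ndarray | float:
    """Recognition-helix separation: distance between the two probe C-alphas.

    Accepts a Trajectory (returns a per-frame array) or a single Structure
    (returns a float).
    """
    if isinstance(traj, Structure):
        i, j = _probe_indices(traj, region)
        coords = traj.coordinates
        return float(np.linalg.norm(coords[i] - coords[j]))
    i, j = _probe_indices(traj.topology, region)
    return np.linalg.norm(traj.frames[:, i] - traj.frames[:, j], axis=1)


def helix_centroid_distance(
    structure: Structure, region: RegionConfig, element: str = "alpha4"
) -> float:
    """Distance between the per-chain C-alpha centroids of one element.

    Alternative recognition-helix separation metric to the probe-residue
    distance, for comparing against helix-centroid readings.
    """
    if element not in region.elements:
        raise ValueError(f"element {element!r} not defined in the region config")
    lo, hi = region.elements[element]
    centroids = []
    coords = structure.coordinates
    for chain in region.protein_chains:
        sel = select(structure, chain=chain, residue_range=(lo, hi), atom_names={"CA"})
        if len(sel) == 0:
            raise ValueError(f"no C-alpha atoms for {element} in chain {chain}")
        centroids.append(coords[sel.indices].mean(axis=0))
    return float(np.linalg.norm(centroids[1] - centroids[0]))


@dataclass
class ReactionCoordinateSeries:
    """Per-frame (RMSD, distance) reaction coordinates, Angstrom."""

    rmsd: np.ndarray
    distance: np.ndarray
    reference_id: str = ""

    def __post_init__(self):
        self.rmsd = np.asarray(self.rmsd, dtype=float)
        self.distance = np.asarray(self.distance, dtype=float)
        if self.rmsd.shape != self.distance.shape or self.rmsd.ndim != 1:
            raise ValueError("rmsd and distance must be equal-length 1-D arrays")
        if np.any(self.rmsd < 0) or np.any(self.distance < 0):
            raise ValueError("reaction coordinates must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.rmsd.size


def reaction_coordinates(
    traj: Trajectory, reference: Structure, region: RegionConfig
) -> ReactionCoordinateSeries:
    """Compute both reaction coordinates for a trajectory."""
    return ReactionCoordinateSeries(
        rmsd=domain_rmsd(traj, reference, region),
        distance=np.asarray(interhelix_distance(traj, region)),
        reference_id=reference.metadata,
    )


@dataclass
class FreeEnergySurface:
    """Binned 2-D free-energy surface.

    ``deltaG`` is -kBT ln g shifted so its minimum over defined bins is 0;
    empty bins are NaN.  ``frame_bins`` records the (i, j) bin of every
    frame so basins can list their member frames.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    deltaG: np.ndarray
    temperature: float
    frame_bins: np.ndarray = field(default=None, repr=False)

    @property
    def n_bins(self) -> tuple[int, int]:
        return self.counts.shape

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            0.5 * (self.x_edges[:-1] + self.x_edges[1:]),
            0.5 * (self.y_edges[:-1] + self.y_edges[1:]),
        )

    def to_dataframe(self):
        import pandas as pd

        xc, yc = self.bin_centers()
        rows = []
        for i in range(self.counts.shape[0]):
            for j in range(self.counts.shape[1]):
                rows.append(
                    (xc[i], yc[j], int(self.counts[i, j]), self.deltaG[i, j])
                )
        return pd.DataFrame(
            rows, columns=["x_center", "y_center", "count", "deltaG"]
        )


def pmf_2d(
    series: ReactionCoordinateSeries,
    n_bins: int = 30,
    temperature: float = 300.0,
    weights: np.ndarray | None = None,
    x_range: tuple[float, float] | None = None,
    y_range: tuple[float, float] | None = None,
) -> FreeEnergySurface:
    """2-D PMF from the joint histogram of the reaction coordinates.

    Bin ranges default to the observed [min, max] per axis; explicit
    ranges allow different systems to share axes.  Optional frame weights
    (e.g. from exponential reweighting) replace raw counts in g.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x, y = series.rmsd, series.distance
    if x.size < 1:
        raise ValueError("need at least one frame")
    xr = x_range if x_range is not None else (float(x.min()), float(x.max()))
    yr = y_range if y_range is not None else (float(y.min()), float(y.max()))
    if xr[1] <= xr[0] or yr[1] <= yr[0]:
        raise ValueError(
            "degenerate landscape: a reaction coordinate has zero variance"
        )
    x_edges = np.linspace(xr[0], xr[1], n_bins + 1)
    y_edges = np.linspace(yr[0], yr[1], n_bins + 1)
    counts, _, _ = np.histogram2d(x, y, bins=[x_edges, y_edges])
    counts = counts.astype(int)
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != x.shape:
            raise ValueError("weights must have one entry per frame")
        g, _, _ = np.histogram2d(x, y, bins=[x_edges, y_edges], weights=weights)
    else:
        g = counts.astype(float)
    total = g.sum()
    if total <= 0:
        raise ValueError("no frames fall inside the requested ranges")
    g = g / total
    kt = KB * temperature
    with np.errstate(divide="ignore"):
        deltaG = np.where(g > 0, -kt * np.log(g), np.nan)
    deltaG -= np.nanmin(deltaG)

    ix = np.clip(np.digitize(x, x_edges) - 1, 0, n_bins - 1)
    iy = np.clip(np.digitize(y, y_edges) - 1, 0, n_bins - 1)
    frame_bins = np.stack([ix, iy], axis=1)
    return FreeEnergySurface(
        x_edges=x_edges,
        y_edges=y_edges,
        counts=counts,
        deltaG=deltaG,
        temperature=temperature,
        frame_bins=frame_bins,
    )


@dataclass
class Basin:
    """A strict local minimum bin of the surface and its member frames."""

    i: int
    j: int
    deltaG: float
    member_frames: np.ndarray
    x_center: float
    y_center: float
    representative_frame: int | None = None


def find_basins(surface: FreeEnergySurface) -> list[Basin]:
    """Bins strictly lower than every defined 8-neighbor, sorted by dG.

    Undefined neighbors count as +inf; ties with any neighbor disqualify
    a bin.  A surface with a single defined bin has that bin as its basin.
    """
    dg = surface.deltaG
    nx, ny = dg.shape
    if not np.any(np.isfinite(dg)):
        raise ValueError("surface has no defined bins")
    xc, yc = surface.bin_centers()
    basins = []
    for i in range(nx):
        for j in range(ny):
            if not np.isfinite(dg[i, j]):
                continue
            is_min = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    ni, nj = i + di, j + dj
                    if 0 <= ni < nx and 0 <= nj < ny and np.isfinite(dg[ni, nj]):
                        if dg[ni, nj] <= dg[i, j]:
                            is_min = False
                            break
                if not is_min:
                    break
            if not is_min:
                continue
            if surface.frame_bins is not None:
                members = np.nonzero(
                    (surface.frame_bins[:, 0] == i)
                    & (surface.frame_bins[:, 1] == j)
                )[0]
            else:
                members = np.array([], dtype=int)
            basins.append(
                Basin(
                    i=i,
                    j=j,
                    deltaG=float(dg[i, j]),
                    member_frames=members,
                    x_center=float(xc[i]),
                    y_center=float(yc[j]),
                )
            )
    basins.sort(key=lambda b: (b.deltaG, b.i, b.j))
    return basins


@dataclass
class Conformer:
    """A connected low-free-energy region of the surface (major conformer).

    ``bins`` are the member (i, j) bins with dG at most the cutoff;
    ``basin`` is the deepest strict-minimum bin inside the region (or the
    deepest member bin when the region contains no strict minimum).
    """

    bins: list[tuple[int, int]]
    basin: Basin
    deltaG: float
    member_frames: np.ndarray
    population: float


def major_conformers(
    surface: FreeEnergySurface, deltaG_cutoff: float = 1.0
) -> list[Conformer]:
    """Distinct major conformers: connected regions of low free energy.

    Bins with dG <= ``deltaG_cutoff`` (kcal/mol above the global minimum)
    are grouped into 8-connected components; each component is one major
    conformer, mirroring the visual reading of a landscape as areas deeper
    than their surroundings and not connected to each other.  Sorted by
    the component's minimum dG.
    """
    dg = surface.deltaG
    low = np.isfinite(dg) & (dg <= deltaG_cutoff)
    nx_, ny_ = dg.shape
    seen = np.zeros_like(low, dtype=bool)
    basins = find_basins(surface)
    basin_at = {(b.i, b.j): b for b in basins}
    out: list[Conformer] = []
    total = surface.counts.sum()
    for i0 in range(nx_):
        for j0 in range(ny_):
            if not low[i0, j0] or seen[i0, j0]:
                continue
            stack = [(i0, j0)]
            seen[i0, j0] = True
            comp: list[tuple[int, int]] = []
            while stack:
                i, j = stack.pop()
                comp.append((i, j))
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ni, nj = i + di, j + dj
                        if (
                            0 <= ni < nx_
                            and 0 <= nj < ny_
                            and low[ni, nj]
                            and not seen[ni, nj]
                        ):
                            seen[ni, nj] = True
                            stack.append((ni, nj))
            comp.sort()
            deepest = min(comp, key=lambda ij: dg[ij])
            in_comp = [b for b in basins if (b.i, b.j) in set(comp)]
            if in_comp:
                anchor = min(in_comp, key=lambda b: b.deltaG)
            else:
                xc, yc = surface.bin_centers()
                members = (
                    np.nonzero(
                        (surface.frame_bins[:, 0] == deepest[0])
                        & (surface.frame_bins[:, 1] == deepest[1])
                    )[0]
                    if surface.frame_bins is not None
                    else np.array([], dtype=int)
                )
                anchor = Basin(
                    i=deepest[0],
                    j=deepest[1],
                    deltaG=float(dg[deepest]),
                    member_frames=members,
                    x_center=float(xc[deepest[0]]),
                    y_center=float(yc[deepest[1]]),
                )
            if surface.frame_bins is not None:
                comp_set = set(comp)
                members = np.nonzero(
                    [
                        (fi, fj) in comp_set
                        for fi, fj in map(tuple, surface.frame_bins)
                    ]
                )[0]
            else:
                members = np.array([], dtype=int)
            out.append(
                Conformer(
                    bins=comp,
                    basin=anchor,
                    deltaG=float(dg[deepest]),
                    member_frames=members,
                    population=float(members.size / total) if total else 0.0,
                )
            )
    out.sort(key=lambda c: (c.deltaG, c.bins[0]))
    return out


def _pairwise_domain_rmsd(coords: np.ndarray) -> np.ndarray:
    """Condensed pairwise RMSD matrix after per-pair superposition."""
    m = coords.shape[0]
    out = np.zeros(m * (m - 1) // 2)
    k = 0
    for a in range(m):
        for b in range(a + 1, m):
            _, _, out[k] = kabsch_superpose(coords[a], coords[b])
            k += 1
    return out


def representative_frame(
    traj: Trajectory,
    basin: Basin,
    region: RegionConfig,
    max_cluster_frames: int = 200,
) -> int:
    """Medoid frame of the dominant conformational cluster of a basin.

    Member frames are clustered by average-linkage hierarchical clustering
    on pairwise domain C-alpha RMSD, the dendrogram is cut into two
    clusters, and the medoid (smallest summed RMSD to its cluster mates)
    of the larger cluster is returned.  Singleton basins return their only
    frame.  Basins with more than ``max_cluster_frames`` members are
    subsampled evenly before clustering.
    """
    members = np.asarray(basin.member_frames, dtype=int)
    if members.size == 0:
        raise ValueError("basin has no member frames")
    if members.size == 1:
        return int(members[0])
    if members.size > max_cluster_frames:
        pick = np.linspace(0, members.size - 1, max_cluster_frames).astype(int)
        members = members[np.unique(pick)]
    ti, _ = _matched_domain_indices(traj.topology, traj.topology, region)
    coords = traj.frames[np.ix_(members, ti)]
    condensed = _pairwise_domain_rmsd(coords)
    if np.allclose(condensed, 0.0):
        return int(members[0])
    z = linkage(condensed, method="average")
    labels = fcluster(z, t=2, criterion="maxclust")
    sizes = {lab: int(np.sum(labels == lab)) for lab in np.unique(labels)}
    best = max(sorted(sizes), key=lambda lab: sizes[lab])
    in_cluster = np.nonzero(labels == best)[0]
    dmat = squareform(condensed)
    sums = dmat[np.ix_(in_cluster, in_cluster)].sum(axis=1)
    medoid_local = in_cluster[int(np.argmin(sums))]
    return int(members[medoid_local])


def bin_gap_bootstrap(
    series: ReactionCoordinateSeries,
    surface: FreeEnergySurface,
    bin_a: tuple[int, int],
    bin_b: tuple[int, int],
    n_boot: int = 200,
    block_len: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Block-bootstrap samples of dG(bin_b) - dG(bin_a) (kcal/mol).

    Frames are resampled in contiguous blocks (to respect time
    correlation) and the free-energy difference of the two fixed bins is
    recomputed from the resampled occupancies.
    """
    fb = surface.frame_bins
    in_a = (fb[:, 0] == bin_a[0]) & (fb[:, 1] == bin_a[1])
    in_b = (fb[:, 0] == bin_b[0]) & (fb[:, 1] == bin_b[1])
    n = fb.shape[0]
    rng = np.random.default_rng(seed)
    n_blocks = int(np.ceil(n / block_len))
    kt = KB * surface.temperature
    gaps = np.empty(n_boot)
    for it in range(n_boot):
        starts = rng.integers(0, n - block_len + 1, size=n_blocks)
        idx = (starts[:, None] + np.arange(block_len)[None, :]).ravel()[:n]
        na, nb = int(in_a[idx].sum()), int(in_b[idx].sum())
        if na == 0 or nb == 0:
            gaps[it] = np.nan
            continue
        gaps[it] = -kt * np.log(nb / na)
    return gaps
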