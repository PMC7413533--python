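"""Coarse-grained two-chain dimer generator with planted ground truth.

The generator emulates, at bead resolution, the features of a homodimeric
DNA-binding regulator that the analysis stages measure:

* a two-state "breathing" coordinate — the distance between the centroids
  of two symmetric recognition groups (one per chain) moves in a quartic
  double well with analytically known minima, so free-energy-landscape
  recovery has closed-form targets;
* planted correlated (same rigid block) and anticorrelated (opposite
  chains of the breathing mode) bead pairs for cross-correlation checks;
* a planted contact-community layout: each chain is a string of compact
  bead blocks whose intra-block pairs sit well inside the 4.5 A contact
  cutoff while inter-block pairs (except single bridge pairs) sit outside
  it, giving a known community partition for network recovery.

Dynamics are overdamped Langevin (Euler-Maruyama) on the elastic +
double-well potential; every source of randomness takes an explicit seed.
Because intra-chain elastic energies depend only on coordinate differences
within a chain, the stationary marginal of the inter-group centroid
distance s is exactly p(s) ~ s^2 exp(-U(s)/kBT) (the s^2 factor is the
3-D radial Jacobian), which the quadrature helpers below integrate.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from .amd import boost_force_scale, boost_potential
from .core import (
    KB,
    Atom,
    RegionConfig,
    Structure,
    Trajectory,
    write_structure,
    write_trajectory,
)

GROUND_TRUTH_SCHEMA_VERSION = 1

_BLOCK_RADIUS = 1.6  # A, bead-to-center distance within a block
_BRIDGE_GAP = 4.0  # A, rest distance of the single inter-block contact pair
_K_INTRA = 10.0  # kcal/mol/A^2, springs within a block and on the bridge
_K_HINGE = 5.0  # kcal/mol/A^2, diagonal springs stiffening the hinge


@dataclass(frozen=True)
class DoubleWell:
    """Quartic double well on the inter-group centroid distance.

    U(s) = barrier * ((s-c)^2 - w^2)^2 / w^4 - tilt * (s - c)
    with c = (d1+d2)/2 and w = (d2-d1)/2, so for tilt = 0 the minima are
    exactly at d1 and d2 with U = 0 and the barrier top is ``barrier``
    (kcal/mol) at s = c.  A small ``tilt`` (kcal/mol/A) biases one well to
    plant unequal populations.
    """

    group_a: tuple[int, ...]
    group_b: tuple[int, ...]
    d1: float
    d2: float
    barrier: float
    tilt: float = 0.0

    def __post_init__(self):
        if self.d1 == self.d2:
            raise ValueError("well centers d1 and d2 must differ")
        if self.barrier <= 0:
            raise ValueError("barrier height must be positive")
        if not self.group_a or not self.group_b:
            raise ValueError("both double-well groups must be non-empty")

    @property
    def center(self) -> float:
        return 0.5 * (self.d1 + self.d2)

    @property
    def half_width(self) -> float:
        return abs(self.d2 - self.d1) / 2.0

    def energy(self, s):
        s = np.asarray(s, dtype=float)
        u = (s - self.center) ** 2 - self.half_width**2
        out = self.barrier * u**2 / self.half_width**4 - self.tilt * (
            s - self.center
        )
        return float(out) if out.ndim == 0 else out

    def gradient(self, s):
        s = np.asarray(s, dtype=float)
        x = s - self.center
        out = (
            4.0 * self.barrier * x * (x**2 - self.half_width**2)
            / self.half_width**4
            - self.tilt
        )
        return float(out) if out.ndim == 0 else out


@dataclass
class DimerModel:
    """Bead model of a two-chain dimer with planted analysis ground truth."""

    chain_ids: list[str]
    residue_ids: np.ndarray
    rest_coordinates: np.ndarray  # (N, 3), A
    elastic_edges: list[tuple[int, int, float, float]]  # (i, j, k, rest len)
    doublewell: DoubleWell
    planted_partition: np.ndarray  # community label per bead
    planted_sign_pairs: list[tuple[int, int, int]]  # (i, j, expected sign)
    block_ranges: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.rest_coordinates = np.asarray(self.rest_coordinates, dtype=float)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.planted_partition = np.asarray(self.planted_partition, dtype=int)
        n = self.rest_coordinates.shape[0]
        if not (len(self.chain_ids) == self.residue_ids.size == n):
            raise ValueError("inconsistent bead table sizes")
        self._check_connected()

    def _check_connected(self):
        for chain in sorted(set(self.chain_ids)):
            members = [i for i, c in enumerate(self.chain_ids) if c == chain]
            adj = {i: set() for i in members}
            for i, j, _, _ in self.elastic_edges:
                if i in adj and j in adj:
                    adj[i].add(j)
                    adj[j].add(i)
            seen = {members[0]}
            stack = [members[0]]
            while stack:
                for nb in adj[stack.pop()]:
                    if nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
            if len(seen) != len(members):
                raise ValueError(f"elastic graph of chain {chain} disconnected")

    @property
    def n_beads(self) -> int:
        return self.rest_coordinates.shape[0]

    def to_structure(self) -> Structure:
        atoms = [
            Atom(
                serial=i + 1,
                name="CA",
                element="C",
                residue_name="ALA",
                residue_id=int(self.residue_ids[i]),
                chain_id=self.chain_ids[i],
                coordinates=self.rest_coordinates[i],
            )
            for i in range(self.n_beads)
        ]
        return Structure(atoms=atoms, metadata="synthetic dimer")

    def region_config(self, temperature: float = 300.0) -> RegionConfig:
        chains = []
        for c in self.chain_ids:
            if c not in chains:
                chains.append(c)
        elements = {}
        per_chain = [b for b in self.block_ranges if b[0] == chains[0]]
        # The recognition block plays the role of the DNA-recognition helix.
        names = ["alpha4"] + [f"segment{k}" for k in range(1, len(per_chain))]
        for name, (_, lo, hi) in zip(names, per_chain):
            elements[name] = (lo, hi)
        domain = elements["alpha4"]
        probe = int(self.residue_ids[self.doublewell.group_a[0]])
        return RegionConfig(
            protein_chains=(chains[0], chains[1]),
            dna_binding_domain=domain,
            elements=elements,
            probe_residue=probe,
            temperature=temperature,
        )


@dataclass(frozen=True)
class SimulationParams:
    """Overdamped-Langevin integration parameters.

    ``friction`` is the damping coefficient zeta in kcal mol^-1 ps A^-2;
    the bead diffusion constant is kBT / zeta.  ``boost`` optionally applies
    the accelerated-MD boost (E_thresh, alpha) to the double-well energy
    term, scaling its force by dV*/dV.  ``stride`` controls how many
    integration steps separate stored frames.
    """

    n_steps: int
    seed: int
    dt: float = 0.005  # ps
    temperature: float = 300.0  # K
    friction: float = 1.0
    stride: int = 10
    boost: tuple[float, float] | None = None  # (E_thresh, alpha), kcal/mol

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


def _block_template(m: int) -> tuple[np.ndarray, int, int]:
    """Rest coordinates of one compact block: two axial poles + a ring.

    All pairwise distances are <= 2 * _BLOCK_RADIUS = 3.2 A, well inside
    the 4.5 A contact cutoff.  Returns (coords, south index, north index);
    the pole beads sit mid-sequence so that the inter-block bridge pair is
    never a sequence-neighbour residue pair.
    """
    if m < 3:
        raise ValueError("block size must be >= 3")
    south = np.array([0.0, 0.0, -_BLOCK_RADIUS])
    north = np.array([0.0, 0.0, _BLOCK_RADIUS])
    ring = []
    n_ring = m - 2
    for k in range(n_ring):
        phi = 2.0 * np.pi * k / n_ring
        ring.append(
            np.array(
                [_BLOCK_RADIUS * np.cos(phi), _BLOCK_RADIUS * np.sin(phi), 0.0]
            )
        )
    first = n_ring // 2
    pts = ring[:first] + [south, north] + ring[first:]
    return np.stack(pts), first, first + 1


def build_dimer_model(
    n_beads_per_chain: int = 40,
    community_layout: list[int] | None = None,
    doublewell_spec: dict | None = None,
    anticorrelated_pairs: list[tuple[int, int]] | None = None,
    seed: int = 0,
) -> DimerModel:
    """Build the two-chain bead dimer.

    ``community_layout`` lists the block sizes of one chain (mirrored to
    the other); every block must have >= 3 beads so that no planted
    community falls under the smallest reportable community size.
    ``doublewell_spec`` may override d1, d2, barrier and tilt of the
    double well acting on the centroid distance between the two
    recognition blocks (block 0 of each chain).
    """
    if community_layout is None:
        community_layout = [10, 10, 10, 10]
    if sum(community_layout) != n_beads_per_chain:
        raise ValueError(
            f"community layout {community_layout} does not sum to "
            f"{n_beads_per_chain}"
        )
    for size in community_layout:
        if size < 3:
            raise ValueError(
                "planted communities need >= 3 beads each; got a block of "
                f"{size}"
            )
    dw_spec = {"d1": 20.0, "d2": 28.0, "barrier": 1.2, "tilt": 0.0}
    if doublewell_spec:
        dw_spec.update(doublewell_spec)

    block_spacing = 2.0 * _BLOCK_RADIUS + _BRIDGE_GAP  # pole-to-pole gap 4.0 A
    chain_offsets = {
        "A": np.zeros(3),
        "B": np.array([float(dw_spec["d1"]), 0.0, 0.0]),
    }

    chain_ids: list[str] = []
    residue_ids: list[int] = []
    coords: list[np.ndarray] = []
    edges: list[tuple[int, int, float, float]] = []
    partition: list[int] = []
    block_ranges: list[tuple[str, int, int]] = []
    rec_groups: dict[str, list[int]] = {}

    label = 0
    for chain in ("A", "B"):
        offset = chain_offsets[chain]
        resid = 0
        prev_poles: tuple[int, int] | None = None  # (south, north) of block b-1
        for b, size in enumerate(community_layout):
            template, i_south, i_north = _block_template(size)
            center = offset + np.array([0.0, 0.0, block_spacing * b])
            start = len(coords)
            for p in template:
                chain_ids.append(chain)
                resid += 1
                residue_ids.append(resid)
                coords.append(center + p)
            members = list(range(start, len(coords)))
            partition.extend([label] * size)
            block_ranges.append((chain, residue_ids[start], resid))
            # stiff springs on every intra-block pair
            for ii in range(len(members)):
                for jj in range(ii + 1, len(members)):
                    i, j = members[ii], members[jj]
                    rest = float(np.linalg.norm(coords[i] - coords[j]))
                    edges.append((i, j, _K_INTRA, rest))
            south, north = start + i_south, start + i_north
            if prev_poles is not None:
                # bridge: facing pole beads at the contact-range rest gap,
                # plus diagonal springs so the hinge does not flop
                i_pole = prev_poles[1]
                edges.append(
                    (
                        i_pole,
                        south,
                        _K_INTRA,
                        float(np.linalg.norm(coords[i_pole] - coords[south])),
                    )
                )
                for i_d, j_d in (
                    (i_pole, members[0]),
                    (prev_poles[0], south),
                    (members[0] - size, members[0]),
                ):
                    rest = float(np.linalg.norm(coords[i_d] - coords[j_d]))
                    edges.append((i_d, j_d, _K_HINGE, rest))
            if b == 0:
                rec_groups[chain] = members
            prev_poles = (south, north)
            label += 1

    dw = DoubleWell(
        group_a=tuple(rec_groups["A"]),
        group_b=tuple(rec_groups["B"]),
        d1=float(dw_spec["d1"]),
        d2=float(dw_spec["d2"]),
        barrier=float(dw_spec["barrier"]),
        tilt=float(dw_spec["tilt"]),
    )

    n = len(coords)
    sign_pairs: list[tuple[int, int, int]] = []
    if anticorrelated_pairs is None:
        k = min(3, len(rec_groups["A"]))
        anticorrelated_pairs = [
            (rec_groups["A"][t], rec_groups["B"][t]) for t in range(k)
        ]
    for i, j in anticorrelated_pairs:
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"anticorrelated pair ({i}, {j}) out of range")
        if chain_ids[i] == chain_ids[j]:
            raise ValueError(
                "anticorrelated pairs must straddle the two chains; "
                f"({i}, {j}) are both on chain {chain_ids[i]}"
            )
        sign_pairs.append((i, j, -1))
    # co-moving pairs: beads sharing a rigid block
    first_block_a = rec_groups["A"]
    first_block_b = rec_groups["B"]
    sign_pairs.append((first_block_a[0], first_block_a[1], +1))
    sign_pairs.append((first_block_b[0], first_block_b[1], +1))

    return DimerModel(
        chain_ids=chain_ids,
        residue_ids=np.array(residue_ids),
        rest_coordinates=np.array(coords),
        elastic_edges=edges,
        doublewell=dw,
        planted_partition=np.array(partition),
        planted_sign_pairs=sign_pairs,
        block_ranges=block_ranges,
    )


def centroid_distance(x: np.ndarray, dw: DoubleWell):
    """Inter-group centroid distance for one frame (N,3) or many (F,N,3)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 2
    if single:
        x = x[None]
    ga = x[:, list(dw.group_a)].mean(axis=1)
    gb = x[:, list(dw.group_b)].mean(axis=1)
    s = np.linalg.norm(gb - ga, axis=1)
    return float(s[0]) if single else s


def simulate(model: DimerModel, params: SimulationParams) -> Trajectory:
    """Overdamped Langevin trajectory of the dimer; deterministic per seed.

    Frames are stored every ``params.stride`` steps (the initial
    configuration is not stored).  When ``params.boost`` is set, the
    double-well term contributes the boosted force
    -dU/ds * (alpha / (E_thresh - U + alpha))^2 below the threshold.
    """
    rng = np.random.default_rng(params.seed)
    x = model.rest_coordinates.copy()
    n = model.n_beads

    ei = np.array([e[0] for e in model.elastic_edges], dtype=int)
    ej = np.array([e[1] for e in model.elastic_edges], dtype=int)
    ek = np.array([e[2] for e in model.elastic_edges], dtype=float)
    el = np.array([e[3] for e in model.elastic_edges], dtype=float)

    dw = model.doublewell
    ga_idx = np.array(dw.group_a, dtype=int)
    gb_idx = np.array(dw.group_b, dtype=int)
    na, nb = ga_idx.size, gb_idx.size

    kt = KB * params.temperature
    zeta = params.friction
    mob = params.dt / zeta
    noise_amp = np.sqrt(2.0 * kt * params.dt / zeta)

    n_frames = params.n_steps // params.stride
    frames = np.empty((max(n_frames, 1), n, 3))
    stored = 0

    for step in range(1, params.n_steps + 1):
        forces = np.zeros_like(x)
        # elastic network
        dvec = x[ei] - x[ej]
        dist = np.linalg.norm(dvec, axis=1)
        np.maximum(dist, 1e-12, out=dist)
        fmag = -ek * (dist - el) / dist  # force on i along dvec
        fvec = fmag[:, None] * dvec
        np.add.at(forces, ei, fvec)
        np.add.at(forces, ej, -fvec)
        # double well on the centroid distance (optionally boosted)
        delta = x[gb_idx].mean(axis=0) - x[ga_idx].mean(axis=0)
        s = float(np.linalg.norm(delta))
        if s > 1e-9:
            duds = dw.gradient(s)
            if params.boost is not None:
                e_thr, alpha = params.boost
                duds *= boost_force_scale(dw.energy(s), e_thr, alpha)
            unit = delta / s
            forces[ga_idx] += (duds / na) * unit
            forces[gb_idx] -= (duds / nb) * unit

        x = x + mob * forces + noise_amp * rng.standard_normal((n, 3))

        if step % params.stride == 0:
            if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > 1e6:
                raise RuntimeError(
                    "simulation blew up (|coordinate| > 1e6 A); "
                    "use a smaller dt"
                )
            if stored < frames.shape[0]:
                frames[stored] = x
                stored += 1
    if stored == 0:  # n_steps < stride: store the final configuration
        frames[0] = x
        stored = 1
    return Trajectory(
        topology=model.to_structure(),
        frames=frames[:stored],
        frame_spacing=params.dt * params.stride,
    )


def boost_series(
    model: DimerModel, traj: Trajectory, boost: tuple[float, float]
) -> np.ndarray:
    """Per-frame boost energy dV of the double-well term (for reweighting)."""
    s = centroid_distance(traj.frames, model.doublewell)
    u = model.doublewell.energy(s)
    return np.asarray(boost_potential(u, boost[0], boost[1]))


# ---------------------------------------------------------------------------
# Analytic references for the planted double well.
# ---------------------------------------------------------------------------


def distance_density(dw: DoubleWell, temperature: float = 300.0):
    """Unnormalized stationary density of the centroid distance.

    p(s) ~ s^2 exp(-U(s)/kBT); exact for this model because intra-chain
    elastic energies are independent of the inter-group vector.
    """
    kt = KB * temperature

    def p(s):
        return s**2 * np.exp(-dw.energy(s) / kt)

    return p


def well_populations(
    dw: DoubleWell, temperature: float = 300.0
) -> tuple[float, float]:
    """Analytic Boltzmann populations of the two wells (split at the barrier).

    Returns (P(well at d1), P(well at d2)), normalized to 1.
    """
    p = distance_density(dw, temperature)
    lo = max(1e-6, dw.center - 6.0 * dw.half_width)
    hi = dw.center + 6.0 * dw.half_width
    z1, _ = quad(p, lo, dw.center, limit=400, epsabs=1e-13, epsrel=1e-11)
    z2, _ = quad(p, dw.center, hi, limit=400, epsabs=1e-13, epsrel=1e-11)
    total = z1 + z2
    pops = (z1 / total, z2 / total)
    if dw.d1 > dw.d2:
        pops = (pops[1], pops[0])
    return pops


def marginal_well_minima(
    dw: DoubleWell, temperature: float = 300.0
) -> tuple[float, float, float]:
    """Analytic minima and barrier of the distance free energy.

    Returns (s at the low-distance minimum, s at the high-distance
    minimum, s at the barrier top) of -kBT ln p(s) with
    p(s) ~ s^2 exp(-U(s)/kBT).  The radial Jacobian (and any tilt) shifts
    these slightly away from the bare well centers d1/d2.
    """
    from scipy.optimize import minimize_scalar

    kt = KB * temperature

    def free_energy(s):
        return dw.energy(s) - 2.0 * kt * np.log(s)

    lo_c, hi_c = sorted((dw.d1, dw.d2))
    w = dw.half_width
    m1 = minimize_scalar(
        free_energy, bounds=(lo_c - w, dw.center), method="bounded"
    ).x
    m2 = minimize_scalar(
        free_energy, bounds=(dw.center, hi_c + w), method="bounded"
    ).x
    barrier = minimize_scalar(
        lambda s: -free_energy(s), bounds=(m1, m2), method="bounded"
    ).x
    return float(m1), float(m2), float(barrier)


def analytic_bin_gap(
    dw: DoubleWell,
    edges: np.ndarray,
    bin1: int,
    bin2: int,
    temperature: float = 300.0,
) -> float:
    """Analytic free-energy difference dG(bin2) - dG(bin1) (kcal/mol)
    between two bins of a distance histogram with the given edges."""
    p = distance_density(dw, temperature)
    m1, _ = quad(p, edges[bin1], edges[bin1 + 1], limit=200)
    m2, _ = quad(p, edges[bin2], edges[bin2 + 1], limit=200)
    return -KB * temperature * np.log(m2 / m1)


def well_gap_bootstrap(
    distances: np.ndarray,
    split: float,
    temperature: float = 300.0,
    n_boot: int = 200,
    block_len: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Free-energy gap between the two well catchments and its block-
    bootstrap standard error.

    The gap is -kBT ln(N_above / N_below) with frames split at the
    barrier position; resampling contiguous frame blocks respects the
    time correlation of the series.  Returns (gap, standard error), both
    kcal/mol.
    """
    s = np.asarray(distances, dtype=float)
    n = s.size
    kt = KB * temperature
    n_above = int(np.sum(s > split))
    n_below = n - n_above
    if n_above == 0 or n_below == 0:
        raise ValueError("one well catchment is empty; cannot form a gap")
    gap = -kt * np.log(n_above / n_below)
    rng = np.random.default_rng(seed)
    block_len = min(block_len, n)
    n_blocks = int(np.ceil(n / block_len))
    samples = []
    for _ in range(n_boot):
        starts = rng.integers(0, n - block_len + 1, size=n_blocks)
        idx = (starts[:, None] + np.arange(block_len)[None, :]).ravel()[:n]
        k_above = int(np.sum(s[idx] > split))
        k_below = n - k_above
        if k_above and k_below:
            samples.append(-kt * np.log(k_above / k_below))
    return gap, float(np.std(samples))


def count_well_crossings(
    series: np.ndarray, dw: DoubleWell, hysteresis: float = 0.5
) -> int:
    """Number of well-to-well transitions of a distance series.

    A frame is assigned to a well only when it is within
    ``hysteresis * half_width`` of that well's center (hysteresis avoids
    counting barrier-top jitter); a crossing is a change of assigned well.
    """
    s = np.asarray(series, dtype=float)
    lo_center, hi_center = sorted((dw.d1, dw.d2))
    band = hysteresis * dw.half_width
    state = 0
    crossings = 0
    for v in s:
        if v <= lo_center + band:
            new = 1
        elif v >= hi_center - band:
            new = 2
        else:
            continue
        if state and new != state:
            crossings += 1
        state = new
    return crossings


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------


def write_fixture(
    model: DimerModel,
    trajectory: Trajectory,
    out_dir: str | os.PathLike,
    temperature: float = 300.0,
) -> dict[str, str]:
    """Write topology PDB, trajectory DCD, region YAML and ground-truth JSON.

    Returns a mapping of artifact name to path.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "topology": os.path.join(out_dir, "topology.pdb"),
        "trajectory": os.path.join(out_dir, "trajectory.dcd"),
        "regions": os.path.join(out_dir, "regions.yaml"),
        "ground_truth": os.path.join(out_dir, "ground_truth.json"),
    }
    write_structure(model.to_structure(), paths["topology"])
    write_trajectory(trajectory, paths["trajectory"], format="dcd")
    model.region_config(temperature).to_yaml(paths["regions"])
    p1, p2 = well_populations(model.doublewell, temperature)
    truth = {
        "schema_version": GROUND_TRUTH_SCHEMA_VERSION,
        "well_centers": [model.doublewell.d1, model.doublewell.d2],
        "barrier_kcal_mol": model.doublewell.barrier,
        "tilt_kcal_mol_per_A": model.doublewell.tilt,
        "expected_populations": [p1, p2],
        "planted_partition": model.planted_partition.tolist(),
        "planted_sign_pairs": [list(t) for t in model.planted_sign_pairs],
        "bead_labels": [
            [model.chain_ids[i], int(model.residue_ids[i])]
            for i in range(model.n_beads)
        ],
    }
    with open(paths["ground_truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return paths


# ---------------------------------------------------------------------------
# Synthetic protein-DNA interface with planted interaction counts
# ---------------------------------------------------------------------------


def build_protein_dna_complex(
    n_hbonds: int = 5, n_ionic: int = 3, n_hydrophobic: int = 4
) -> tuple[Structure, dict[str, int]]:
    """A synthetic protein-DNA complex with exactly planted contact counts.

    Each planted interaction occupies its own site on a 12 A grid so no
    unintended cross-site contact exists:

    * hydrogen bonds: SER OG donors 3.0 A from thymine OP1 acceptors;
    * ionic pairs: LYS NZ 3.8 A from adenine OP2 (outside the 3.5 A
      hydrogen-bond cutoff so the categories stay disjoint here);
    * hydrophobic contacts: VAL CG1 4.0 A from thymine C7 methyl carbons.

    Returns the Structure and the expected counts by kind.
    """
    atoms: list[Atom] = []
    serial = 0

    def add(name, element, res_name, res_id, chain, xyz):
        nonlocal serial
        serial += 1
        atoms.append(
            Atom(
                serial=serial,
                name=name,
                element=element,
                residue_name=res_name,
                residue_id=res_id,
                chain_id=chain,
                coordinates=np.asarray(xyz, dtype=float),
            )
        )

    spacing = 12.0
    site = 0
    prot_res = 0
    dna_res = 0
    for _ in range(n_hbonds):
        base = np.array([site * spacing, 0.0, 0.0])
        prot_res += 1
        dna_res += 1
        add("CB", "C", "SER", prot_res, "A", base + [0.0, 0.0, 1.4])
        add("OG", "O", "SER", prot_res, "A", base)
        add("P", "P", "DT", dna_res, "C", base + [3.0, 0.0, -1.5])
        add("OP1", "O", "DT", dna_res, "C", base + [3.0, 0.0, 0.0])
        site += 1
    for _ in range(n_ionic):
        base = np.array([site * spacing, 0.0, 0.0])
        prot_res += 1
        dna_res += 1
        add("CE", "C", "LYS", prot_res, "A", base + [0.0, 0.0, 1.5])
        add("NZ", "N", "LYS", prot_res, "A", base)
        add("P", "P", "DA", dna_res, "C", base + [3.8, 0.0, -1.5])
        add("OP2", "O", "DA", dna_res, "C", base + [3.8, 0.0, 0.0])
        site += 1
    for _ in range(n_hydrophobic):
        base = np.array([site * spacing, 0.0, 0.0])
        prot_res += 1
        dna_res += 1
        add("CB", "C", "VAL", prot_res, "A", base + [0.0, 0.0, 1.5])
        add("CG1", "C", "VAL", prot_res, "A", base)
        add("C7", "C", "DT", dna_res, "C", base + [4.0, 0.0, 0.0])
        site += 1
    structure = Structure(atoms=atoms, metadata="synthetic protein-DNA complex")
    expected = {
        "hbond": n_hbonds,
        "ionic": n_ionic,
        "hydrophobic": n_hydrophobic,
    }
    return structure, expected
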