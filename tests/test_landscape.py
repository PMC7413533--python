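"""Reaction coordinates, PMF, basin detection, representatives."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from allodyn.core import KB, Atom, RegionConfig, Structure, Trajectory
from allodyn.landscape import (
    FreeEnergySurface,
    ReactionCoordinateSeries,
    domain_rmsd,
    find_basins,
    helix_centroid_distance,
    interhelix_distance,
    kabsch_superpose,
    pmf_2d,
    representative_frame,
)
from allodyn.studies import landscape_model

KT300 = KB * 300.0


def _random_points(rng, n=8):
    return rng.normal(size=(n, 3)) * 5.0


class TestKabsch:
    def test_identity(self, rng):
        pts = _random_points(rng)
        rot, trans, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-9)

    def test_rigid_transform_recovered(self, rng):
        pts = _random_points(rng)
        r = Rotation.from_euler("xyz", [0.3, -1.1, 2.0])
        moved = pts @ r.as_matrix().T + np.array([1.0, -2.0, 3.0])
        _, _, rmsd = kabsch_superpose(moved, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_matches_independent_solver(self, rng):
        """Post-fit RMSD equals scipy's independent alignment solver on a
        perturbed square (and on random clouds)."""
        square = np.array(
            [[0, 0, 0], [2, 0, 0], [2, 2, 0], [0, 2, 0]], dtype=float
        )
        bent = square.copy()
        bent[2] += [0.0, 0.0, 1.0]
        for mobile, reference in [
            (bent, square),
            (_random_points(rng, 6), _random_points(rng, 6)),
        ]:
            _, _, rmsd = kabsch_superpose(mobile, reference)
            mob_c = mobile - mobile.mean(axis=0)
            ref_c = reference - reference.mean(axis=0)
            est, ssd = Rotation.align_vectors(ref_c, mob_c)
            oracle = np.sqrt(
                np.mean(
                    np.sum((mob_c @ est.as_matrix().T - ref_c) ** 2, axis=1)
                )
            )
            assert rmsd == pytest.approx(oracle, abs=1e-9)

    def test_proper_rotation_even_for_reflected_input(self, rng):
        pts = _random_points(rng)
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        rot, _, _ = kabsch_superpose(mirrored, pts)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.stack([[i, 0.0, 0.0] for i in range(5)])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)


def _probe_structure(d):
    """Two 4-bead protein chains whose probe C-alphas are d apart."""
    atoms = []
    serial = 0
    for chain, offset in (("A", 0.0), ("B", d)):
        for resid in range(1, 5):
            serial += 1
            atoms.append(
                Atom(
                    serial, "CA", "C", "ALA", resid, chain,
                    np.array([offset, float(resid), 0.0]),
                )
            )
    return Structure(atoms=atoms)


def _probe_region():
    return RegionConfig(
        protein_chains=("A", "B"),
        dna_binding_domain=(1, 4),
        elements={"alpha4": (1, 4)},
        probe_residue=2,
    )


class TestReactionCoordinates:
    def test_interhelix_distance_structure_and_trajectory(self):
        s = _probe_structure(30.0)
        region = _probe_region()
        assert interhelix_distance(s, region) == pytest.approx(30.0)
        traj = Trajectory(topology=s, frames=s.coordinates[None])
        np.testing.assert_allclose(interhelix_distance(traj, region), [30.0])

    def test_interhelix_translation_invariance(self):
        s = _probe_structure(30.0)
        region = _probe_region()
        shifted = s.with_coordinates(s.coordinates + np.array([5.0, -3.0, 9.0]))
        assert interhelix_distance(shifted, region) == pytest.approx(30.0)

    def test_missing_probe_rejected(self):
        region = RegionConfig(
            protein_chains=("A", "B"),
            dna_binding_domain=(1, 4),
            probe_residue=99,
        )
        with pytest.raises(ValueError, match="probe residue 99"):
            interhelix_distance(_probe_structure(30.0), region)

    def test_helix_centroid_distance(self):
        s = _probe_structure(30.0)
        assert helix_centroid_distance(s, _probe_region()) == pytest.approx(30.0)

    def test_domain_rmsd_zero_for_reference_and_rigid_motion(self):
        s = _probe_structure(30.0)
        region = _probe_region()
        rot = Rotation.from_euler("xyz", [0.4, 0.2, -0.9]).as_matrix()
        frames = np.stack(
            [s.coordinates, s.coordinates @ rot.T + np.array([3.0, 2, 1])]
        )
        traj = Trajectory(topology=s, frames=frames)
        r = domain_rmsd(traj, s, region)
        np.testing.assert_allclose(r, [0.0, 0.0], atol=1e-9)

    def test_domain_rmsd_single_displacement_against_oracle(self):
        s = _probe_structure(30.0)
        region = _probe_region()
        delta = 1.0
        moved = s.coordinates.copy()
        moved[0] += [0.0, 0.0, delta]
        traj = Trajectory(topology=s, frames=moved[None])
        r = domain_rmsd(traj, s, region)[0]
        _, _, oracle = kabsch_superpose(moved, s.coordinates)
        assert r == pytest.approx(oracle, abs=1e-12)
        # after fitting, one displaced bead among n gives ~ delta/sqrt(n)
        n = len(s)
        assert r <= delta / np.sqrt(n) + 1e-9
        assert r >= 0.5 * delta / np.sqrt(n)

    def test_domain_mismatch_reported(self):
        s = _probe_structure(30.0)
        region = _probe_region()
        smaller = Structure(atoms=s.atoms[:7])  # chain B residue 4 missing
        traj = Trajectory(topology=s, frames=s.coordinates[None])
        with pytest.raises(ValueError, match=r"\('B', 4\)"):
            domain_rmsd(traj, smaller, region)


class TestPmf2d:
    def test_all_frames_in_one_bin(self):
        series = ReactionCoordinateSeries(
            rmsd=np.full(50, 1.0), distance=np.full(50, 20.0)
        )
        surf = pmf_2d(series, n_bins=5, x_range=(0, 5), y_range=(15, 25))
        defined = np.isfinite(surf.deltaG)
        assert defined.sum() == 1
        assert surf.deltaG[defined][0] == 0.0
        assert surf.counts.sum() == 50

    def test_two_bin_closed_form(self):
        rmsd = np.concatenate([np.full(100, 1.0), np.full(10, 3.0)])
        dist = np.full(110, 20.0)
        series = ReactionCoordinateSeries(rmsd=rmsd, distance=dist)
        surf = pmf_2d(series, n_bins=2, temperature=300.0, y_range=(19, 21))
        vals = np.sort(surf.deltaG[np.isfinite(surf.deltaG)])
        assert vals[0] == 0.0
        assert vals[1] == pytest.approx(KT300 * np.log(10.0), rel=1e-12)

    def test_uniform_occupancy_is_flat(self):
        x = np.repeat(np.arange(4) + 0.5, 4).astype(float)
        y = np.tile(np.arange(4) + 0.5, 4).astype(float)
        series = ReactionCoordinateSeries(rmsd=x, distance=y)
        surf = pmf_2d(series, n_bins=4, x_range=(0, 4), y_range=(0, 4))
        np.testing.assert_allclose(surf.deltaG, 0.0, atol=1e-12)

    def test_degenerate_axis_rejected(self):
        series = ReactionCoordinateSeries(
            rmsd=np.full(10, 1.0), distance=np.arange(10.0)
        )
        with pytest.raises(ValueError, match="zero variance"):
            pmf_2d(series)

    def test_histogram_exact_differences(self, rng):
        """dG(b1) - dG(b2) = -kBT ln(n1/n2) for any two defined bins."""
        series = ReactionCoordinateSeries(
            rmsd=rng.uniform(0, 3, 4000), distance=rng.uniform(18, 30, 4000)
        )
        surf = pmf_2d(series, n_bins=6, temperature=300.0)
        finite = np.argwhere(np.isfinite(surf.deltaG))
        (i1, j1), (i2, j2) = finite[0], finite[-1]
        n1, n2 = surf.counts[i1, j1], surf.counts[i2, j2]
        lhs = surf.deltaG[i1, j1] - surf.deltaG[i2, j2]
        assert lhs == pytest.approx(-KT300 * np.log(n1 / n2), rel=1e-10)

    def test_weights_override_counts(self):
        series = ReactionCoordinateSeries(
            rmsd=np.array([1.0, 3.0]), distance=np.array([20.0, 20.0])
        )
        w = np.array([0.8, 0.2])
        surf = pmf_2d(series, n_bins=2, weights=w, y_range=(19, 21))
        vals = np.sort(surf.deltaG[np.isfinite(surf.deltaG)])
        assert vals[1] == pytest.approx(-KT300 * np.log(0.2 / 0.8), rel=1e-10)


def _surface_from_grid(dg):
    dg = np.asarray(dg, dtype=float)
    n = dg.shape[0]
    return FreeEnergySurface(
        x_edges=np.arange(n + 1.0),
        y_edges=np.arange(dg.shape[1] + 1.0),
        counts=np.zeros_like(dg, dtype=int),
        deltaG=dg,
        temperature=300.0,
        frame_bins=np.empty((0, 2), dtype=int),
    )


def _brute_force_basins(dg):
    """Exhaustive neighbour comparison, independent of find_basins."""
    dg = np.asarray(dg, dtype=float)
    out = []
    nx, ny = dg.shape
    for i in range(nx):
        for j in range(ny):
            if not np.isfinite(dg[i, j]):
                continue
            neigh = [
                dg[a, b]
                for a in range(max(0, i - 1), min(nx, i + 2))
                for b in range(max(0, j - 1), min(ny, j + 2))
                if (a, b) != (i, j) and np.isfinite(dg[a, b])
            ]
            if all(dg[i, j] < v for v in neigh):
                out.append((i, j))
    return sorted(out)


class TestFindBasins:
    def test_single_minimum_paraboloid(self):
        x, y = np.meshgrid(np.arange(7), np.arange(7), indexing="ij")
        dg = (x - 3.0) ** 2 + (y - 3.0) ** 2
        basins = find_basins(_surface_from_grid(dg))
        assert [(b.i, b.j) for b in basins] == [(3, 3)]

    def test_two_wells_match_brute_force(self, rng):
        x, y = np.meshgrid(np.arange(10), np.arange(10), indexing="ij")
        dg = np.minimum((x - 2.0) ** 2 + (y - 2.0) ** 2,
                        1.0 + (x - 7.0) ** 2 + (y - 7.0) ** 2)
        basins = find_basins(_surface_from_grid(dg))
        assert sorted((b.i, b.j) for b in basins) == _brute_force_basins(dg)
        assert len(basins) == 2
        assert basins[0].deltaG <= basins[1].deltaG

    def test_monotone_ramp_single_corner_basin(self):
        x, y = np.meshgrid(np.arange(5), np.arange(5), indexing="ij")
        dg = x + 2.0 * y
        basins = find_basins(_surface_from_grid(dg))
        assert [(b.i, b.j) for b in basins] == _brute_force_basins(dg) == [(0, 0)]

    def test_random_surfaces_match_brute_force(self, rng):
        for _ in range(20):
            dg = rng.normal(size=(8, 8))
            dg[rng.random(size=(8, 8)) < 0.2] = np.nan
            if not np.any(np.isfinite(dg)):
                continue
            basins = find_basins(_surface_from_grid(dg))
            assert sorted((b.i, b.j) for b in basins) == _brute_force_basins(dg)

    def test_invariant_to_constant_shift(self, rng):
        dg = rng.normal(size=(8, 8))
        a = find_basins(_surface_from_grid(dg))
        b = find_basins(_surface_from_grid(dg + 7.3))
        assert [(x.i, x.j) for x in a] == [(x.i, x.j) for x in b]

    def test_ties_disqualify(self):
        dg = np.ones((3, 3))
        assert find_basins(_surface_from_grid(dg)) == []


class TestRepresentativeFrame:
    def _traj_from_frames(self, frames):
        model = landscape_model()
        return Trajectory(topology=model.to_structure(), frames=np.asarray(frames))

    def _basin(self, members):
        from allodyn.landscape import Basin

        return Basin(
            i=0, j=0, deltaG=0.0,
            member_frames=np.asarray(members, dtype=int),
            x_center=0.0, y_center=0.0,
        )

    def test_singleton_basin(self):
        model = landscape_model()
        traj = self._traj_from_frames([model.rest_coordinates])
        region = model.region_config()
        assert representative_frame(traj, self._basin([0]), region) == 0

    def test_dominant_cluster_medoid(self, rng):
        model = landscape_model()
        base = model.rest_coordinates
        frames = [base + rng.normal(scale=0.01, size=base.shape) for _ in range(10)]
        outlier = base.copy()
        outlier[:5] += 8.0
        frames.append(outlier)
        traj = self._traj_from_frames(frames)
        region = model.region_config()
        rep = representative_frame(traj, self._basin(range(11)), region)
        assert rep != 10  # the outlier frame is never representative

    def test_larger_planted_cluster_wins(self, rng):
        model = landscape_model()
        base = model.rest_coordinates
        shifted = base.copy()
        shifted[:5] += np.array([6.0, 0.0, 0.0])
        frames = [base + rng.normal(scale=0.01, size=base.shape) for _ in range(12)]
        frames += [shifted + rng.normal(scale=0.01, size=base.shape) for _ in range(8)]
        traj = self._traj_from_frames(frames)
        region = model.region_config()
        rep = representative_frame(traj, self._basin(range(20)), region)
        assert rep < 12  # medoid comes from the 12-frame cluster
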