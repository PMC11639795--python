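"""Trajectory analytics: superposition, RMSD/RMSF, Rg, series, PCA, FEL."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation
from sklearn.metrics import silhouette_score

from pepforge import synth
from pepforge.errors import DataError
from pepforge.sasa import SASAParams
from pepforge.traj import (KB_KCAL, Trajectory, free_energy_landscape,
                           hbond_series, kabsch_superpose, pca,
                           radius_of_gyration, rg_series, rmsd_series, rmsf,
                           sasa_series)
from pepforge.structure import Residue, ResidueKey, Structure

from conftest import make_atom


def _ca_topology(n=6, spacing=3.8):
    """Non-collinear CA chain (zig-zag in y/z) so superposition is
    well-conditioned."""
    residues = []
    for i in range(n):
        coords = (spacing * i, 2.0 * math.sin(1.7 * i), 2.0 * math.cos(1.7 * i))
        residues.append(Residue(ResidueKey("A", i + 1), "ALA",
                                [make_atom(coords=coords, serial=i + 1)]))
    return Structure([(1, {"A": residues})])


def _static_traj(n_frames=5, n_res=6):
    topo = _ca_topology(n_res)
    ref = topo.coordinates()
    frames = np.repeat(ref[None], n_frames, axis=0)
    return Trajectory(topo, frames, np.arange(n_frames) * 0.01)


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(8, 3))
        sup = kabsch_superpose(pts, pts)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-10)

    def test_rigid_motion_recovered(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 3))
        R = Rotation.from_euler("z", 37, degrees=True).as_matrix()
        moved = pts @ R.T + np.array([1.0, -2.0, 3.0])
        sup = kabsch_superpose(pts, moved)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-8)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0)

    def test_four_point_matches_rotation_search_oracle(self):
        """Optimal RMSD vs an independent search over rotations."""
        ref = np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0], [0, 0, 2]], float)
        mobile = ref.copy()
        mobile[3] += np.array([1.0, 0.0, 0.0])  # displace one point
        mobile = mobile @ Rotation.from_euler(
            "xyz", [20, -35, 50], degrees=True).as_matrix().T + 4.0

        def rmsd_for(angles):
            R = Rotation.from_euler("xyz", angles, degrees=True).as_matrix()
            a = (mobile - mobile.mean(0)) @ R.T
            b = ref - ref.mean(0)
            return math.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))

        # coarse exhaustive grid, then local refinement
        grid = np.arange(-180.0, 180.0, 20.0)
        best = min(((rmsd_for((x, y, z)), (x, y, z))
                    for x in grid for y in grid for z in grid))
        refined = minimize(rmsd_for, best[1], method="Nelder-Mead",
                           options={"xatol": 1e-6, "fatol": 1e-12})
        oracle = refined.fun
        sup = kabsch_superpose(ref, mobile)
        assert sup.rmsd == pytest.approx(oracle, abs=1e-3)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(2, 7, 3))
        assert kabsch_superpose(a, b).rmsd == pytest.approx(
            kabsch_superpose(b, a).rmsd, abs=1e-9)

    def test_invariant_to_rigid_pretransform(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(2, 7, 3))
        base = kabsch_superpose(a, b).rmsd
        R = Rotation.from_euler("y", 75, degrees=True).as_matrix()
        assert kabsch_superpose(a @ R.T + 2.0, b).rmsd == pytest.approx(
            base, abs=1e-9)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


class TestRmsdSeries:
    def test_static_all_zero(self):
        t = _static_traj()
        _, values = rmsd_series(t, selection=None)
        np.testing.assert_allclose(values, 0.0, atol=1e-12)

    def test_ref_frame_zero_at_itself(self):
        topo = _ca_topology()
        rng = np.random.default_rng(0)
        frames = topo.coordinates()[None] + rng.normal(
            0, 0.5, size=(5, topo.n_atoms, 3))
        frames[3] = frames[0]
        t = Trajectory(topo, frames, np.arange(5) * 0.01)
        _, values = rmsd_series(t, selection=None, ref_frame=0)
        assert values[0] == pytest.approx(0.0, abs=1e-12)
        assert values[3] == pytest.approx(0.0, abs=1e-12)

    def test_harmonic_amplitude_expectation(self):
        """Isotropic Gaussian displacement sigma -> RMSD ~ sqrt(3)*sigma."""
        topo = _ca_topology(40)
        sigma = 0.5
        spec = synth.TrajectorySpec(n_frames=200,
                                    per_residue_amplitudes=(sigma,) * 40,
                                    seed=5)
        t = synth.make_trajectory(topo, spec)
        ref = topo.coordinates()
        t = Trajectory(topo, np.concatenate([ref[None], t.frames]),
                       np.arange(201) * 0.01)
        _, values = rmsd_series(t, selection=None, ref_frame=0)
        expected_nm = math.sqrt(3) * sigma / 10.0
        assert np.mean(values[1:]) == pytest.approx(expected_nm, rel=0.10)

    def test_bad_ref_raises(self):
        with pytest.raises(ValueError):
            rmsd_series(_static_traj(), ref_frame=99)


class TestRmsf:
    def test_static_zero(self):
        values = rmsf(_static_traj())
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in values.values())

    def test_high_amplitude_residue_is_argmax(self):
        topo = _ca_topology(8)
        amps = [0.2] * 8
        amps[3] = 0.9
        t = synth.make_trajectory(topo, synth.TrajectorySpec(
            n_frames=300, per_residue_amplitudes=tuple(amps), seed=7))
        values = rmsf(t)
        assert max(values, key=values.get) == ResidueKey("A", 4)

    def test_amplitude_ratio_three_to_one(self):
        topo = _ca_topology(20)
        amps = [0.2] * 20
        amps[5] = 0.6
        t = synth.make_trajectory(topo, synth.TrajectorySpec(
            n_frames=500, per_residue_amplitudes=tuple(amps), seed=11))
        values = rmsf(t)
        ratio = values[ResidueKey("A", 6)] / values[ResidueKey("A", 15)]
        assert ratio == pytest.approx(3.0, rel=0.15)

    def test_rank_order_recovered(self):
        """Residues carrying a >=1.5x amplitude ladder keep their exact rank
        order; background residues stabilize the superposition."""
        topo = _ca_topology(24)
        ladder = {3: 0.3, 7: 0.45, 11: 0.7, 15: 1.05, 19: 1.6}
        amps = tuple(ladder.get(i, 0.15) for i in range(24))
        t = synth.make_trajectory(topo, synth.TrajectorySpec(
            n_frames=500, per_residue_amplitudes=amps, seed=13))
        values = rmsf(t)
        ranked = sorted(ladder, key=lambda i: values[ResidueKey("A", i + 1)])
        assert ranked == sorted(ladder)

    def test_single_frame_raises(self):
        t = _static_traj(n_frames=1)
        with pytest.raises(DataError):
            rmsf(t)


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        assert radius_of_gyration(np.zeros((1, 3))) == 0.0

    def test_two_unit_masses_2A_apart(self):
        coords = np.array([[0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(coords) == pytest.approx(0.1)  # 1 A = 0.1 nm

    def test_random_cloud_matches_direct_sum(self):
        rng = np.random.default_rng(17)
        coords = rng.normal(size=(50, 3)) * 5
        masses = rng.uniform(1, 16, size=50)
        com = (masses[:, None] * coords).sum(0) / masses.sum()
        direct = math.sqrt((masses * ((coords - com) ** 2).sum(1)).sum()
                           / masses.sum()) / 10.0
        assert radius_of_gyration(coords, masses) == pytest.approx(
            direct, abs=1e-12)

    def test_zero_mass_raises(self):
        with pytest.raises(ValueError):
            radius_of_gyration(np.zeros((2, 3)), np.zeros(2))

    def test_series_constant_for_static(self):
        _, values = rg_series(_static_traj())
        assert np.ptp(values) == pytest.approx(0.0, abs=1e-12)


class TestSasaSeries:
    def test_static_constant(self):
        t = _static_traj()
        _, values = sasa_series(t, SASAParams(n_test_points=100))
        assert np.ptp(values) == pytest.approx(0.0, abs=1e-9)

    def test_isolated_atom_analytic(self):
        topo = Structure([(1, {"A": [Residue(ResidueKey("A", 1), "ALA",
                                             [make_atom(radius=1.7)])]})])
        frames = np.zeros((3, 1, 3))
        t = Trajectory(topo, frames, np.arange(3) * 0.1)
        _, values = sasa_series(t, SASAParams(n_test_points=960))
        expected = 4 * math.pi * 3.1**2 / 100.0
        np.testing.assert_allclose(values, expected, rtol=0.01)

    def test_breathing_dimer_matches_per_frame_oracle(self):
        topo = Structure([(1, {"A": [
            Residue(ResidueKey("A", 1), "ALA", [make_atom(serial=1)]),
            Residue(ResidueKey("A", 2), "ALA",
                    [make_atom(coords=(2.0, 0, 0), serial=2)])]})])
        distances = [2.0, 3.0, 4.0, 6.0, 8.0]
        frames = np.array([[[0, 0, 0], [d, 0, 0]] for d in distances], float)
        t = Trajectory(topo, frames, np.arange(5) * 0.1)
        _, values = sasa_series(t, SASAParams(n_test_points=960))
        from pepforge.sasa import sasa_shrake_rupley
        from conftest import atoms_structure
        oracle = []
        for d in distances:
            s = atoms_structure([((0, 0, 0), 1.7), ((d, 0, 0), 1.7)])
            oracle.append(sasa_shrake_rupley(
                s, SASAParams(n_test_points=960)).total / 100.0)
        np.testing.assert_allclose(values, oracle, rtol=1e-9)
        assert np.all(np.diff(values[:4]) > 0)  # separation exposes surface


class TestHbondSeries:
    def _pair_topology(self):
        donor = Residue(ResidueKey("A", 1), "ALA",
                        [make_atom("N", "N", (0, 0, 0), serial=1)])
        acceptor = Residue(ResidueKey("B", 1), "ALA",
                           [make_atom("O", "O", (2.9, 0, 0), serial=2)])
        return Structure([(1, {"A": [donor], "B": [acceptor]})])

    def test_constructed_pair_counted(self):
        topo = self._pair_topology()
        frames = np.repeat(topo.coordinates()[None], 3, axis=0)
        t = Trajectory(topo, frames, np.arange(3) * 0.1)
        _, counts = hbond_series(t, ["A"], ["B"])
        np.testing.assert_array_equal(counts, [1, 1, 1])

    def test_pair_pulled_apart(self):
        topo = self._pair_topology()
        frames = np.array([[[0, 0, 0], [2.9, 0, 0]],
                           [[0, 0, 0], [6.0, 0, 0]]])
        t = Trajectory(topo, frames, np.arange(2) * 0.1)
        _, counts = hbond_series(t, ["A"], ["B"])
        np.testing.assert_array_equal(counts, [1, 0])

    def test_oscillation_matches_per_frame_scan(self):
        topo = self._pair_topology()
        distances = [2.9, 6.0, 3.2, 5.5, 2.5, 4.0]
        frames = np.array([[[0, 0, 0], [d, 0, 0]] for d in distances])
        t = Trajectory(topo, frames, np.arange(6) * 0.1)
        _, counts = hbond_series(t, ["A"], ["B"])
        expected = [1 if d <= 3.5 else 0 for d in distances]
        np.testing.assert_array_equal(counts, expected)


class TestPca:
    def test_one_axis_motion(self):
        topo = _ca_topology(4)
        ref = topo.coordinates()
        frames = np.repeat(ref[None], 20, axis=0)
        # all atoms breathe along x together (not a rigid motion)
        amplitude = np.linspace(-1, 1, 20)
        frames[:, :, 0] += amplitude[:, None] * np.array([1, -1, 1, -1])
        t = Trajectory(topo, frames, np.arange(20) * 0.1)
        evals, proj = pca(t, selection=None)
        assert evals[0] / evals.sum() >= 0.99

    def test_static_zero_eigenvalues(self):
        evals, _ = pca(_static_traj(), selection=None)
        np.testing.assert_allclose(evals, 0.0, atol=1e-12)

    def test_trace_identity(self):
        topo = _ca_topology(5)
        t = synth.make_trajectory(topo, synth.TrajectorySpec(
            n_frames=50, per_residue_amplitudes=(0.5,) * 5, seed=23))
        evals, _ = pca(t, selection=None)
        from pepforge.traj import _superpose_to_mean
        coords = _superpose_to_mean(t.frames)
        X = coords.reshape(50, -1)
        X = X - X.mean(axis=0)
        total_var = np.sum(X**2) / (50 - 1)
        assert evals.sum() == pytest.approx(total_var, rel=1e-8)

    def test_three_state_hopping_clusters(self):
        topo = _ca_topology(10)
        t = synth.make_trajectory(topo, synth.TrajectorySpec(
            n_frames=150, n_states=3, seed=29))
        _, proj = pca(t, selection=None)
        labels = np.repeat(np.arange(3), 50)
        assert silhouette_score(proj, labels) > 0.5


class TestFel:
    def test_single_bin(self):
        proj = np.zeros((10, 2))
        grid = free_energy_landscape(proj, bins=4)
        assert grid.free_energy.min() == 0.0
        occupied = grid.free_energy == 0.0
        assert occupied.sum() == 1
        assert np.all(grid.free_energy[~occupied] == grid.cap)

    def test_uniform_occupancy(self):
        n = 8
        xs, ys = np.meshgrid(np.arange(n) + 0.5, np.arange(n) + 0.5)
        proj = np.column_stack([xs.ravel(), ys.ravel()])
        grid = free_energy_landscape(proj, bins=n)
        np.testing.assert_allclose(grid.free_energy, 0.0, atol=1e-12)

    def test_minimum_in_modal_bin(self):
        rng = np.random.default_rng(31)
        proj = rng.normal(size=(2000, 2))
        grid = free_energy_landscape(proj, bins=16)
        assert grid.free_energy.min() == 0.0
        H, _, _ = np.histogram2d(proj[:, 0], proj[:, 1], bins=16)
        assert grid.free_energy[np.unravel_index(H.argmax(), H.shape)] == 0.0

    def test_gaussian_cloud_quadratic_profile(self):
        """Boltzmann inversion of an isotropic Gaussian: F = kT r^2/(2 sigma^2)."""
        rng = np.random.default_rng(37)
        sigma, T = 1.0, 300.0
        proj = rng.normal(scale=sigma, size=(200_000, 2))
        grid = free_energy_landscape(proj, temperature=T, bins=41)
        xc = 0.5 * (grid.pc1_edges[:-1] + grid.pc1_edges[1:])
        yc = 0.5 * (grid.pc2_edges[:-1] + grid.pc2_edges[1:])
        X, Y = np.meshgrid(xc, yc, indexing="ij")
        r2 = X**2 + Y**2
        H, _, _ = np.histogram2d(proj[:, 0], proj[:, 1],
                                 bins=[grid.pc1_edges, grid.pc2_edges])
        mask = (H > 200) & (r2 > 0.05)  # well-sampled, off-center bins
        slope = np.polyfit(r2[mask], grid.free_energy[mask], 1)[0]
        expected = KB_KCAL * T / (2 * sigma**2)
        assert slope == pytest.approx(expected, rel=0.1)
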