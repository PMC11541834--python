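import numpy as np
import pytest

from scaffdeco.synthetic import CorrelatedBlock, TrajectorySpec, gen_trajectory
from scaffdeco.trajectory import (
    CorrelationMatrix,
    Trajectory,
    dccm,
    fel,
    hbond_count,
    kabsch,
    radius_of_gyration,
    read_pdb,
    rmsf,
    sasa,
    superpose_rmsd,
    write_pdb,
)
from scaffdeco.energetics import R_KCAL


def single_frame(coords, names=None, masses=None):
    coords = np.asarray(coords, float)[None, :, :]
    n = coords.shape[1]
    return Trajectory(
        coords,
        np.ones(n) if masses is None else np.asarray(masses, float),
        np.arange(n),
        names or ["CA"] * n,
    )


def rotation_matrix(axis, angle):
    axis = np.asarray(axis, float)
    axis /= np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K


class TestSuperposeRmsd:
    def test_identical_frames_zero(self):
        traj = gen_trajectory(TrajectorySpec(n_residues=8, n_frames=3, sigma_profile=0.0))
        assert np.allclose(superpose_rmsd(traj, selection="all"), 0.0)

    def test_rigid_transform_zero_after_fitting(self):
        ref = gen_trajectory(TrajectorySpec(n_residues=10, n_frames=1, sigma_profile=0.0)).coords[0]
        R = rotation_matrix([1, 2, 3], 1.1)
        moved = ref @ R.T + np.array([4.0, -2.0, 7.0])
        traj = single_frame(moved)
        values = superpose_rmsd(traj, reference=ref, selection="all")
        assert values[0] == pytest.approx(0.0, abs=1e-10)

    def test_matches_rotation_grid_oracle_on_four_points(self):
        """Kabsch optimum vs brute-force search over a dense rotation grid."""
        rng = np.random.default_rng(1)
        a = rng.normal(size=(4, 3))
        b = rng.normal(size=(4, 3))
        traj = single_frame(a)
        kabsch_rmsd = superpose_rmsd(traj, reference=b, selection="all")[0]
        ac = a - a.mean(0)
        bc = b - b.mean(0)

        def grid_min(ax_range, az_range, th_range, steps):
            best = (np.inf, None)
            for ax in np.linspace(*ax_range, steps):
                for az in np.linspace(*az_range, steps):
                    for theta in np.linspace(*th_range, steps):
                        R = rotation_matrix(
                            [np.sin(ax) * np.cos(az), np.sin(ax) * np.sin(az), np.cos(ax)],
                            theta)
                        r = np.sqrt(((ac @ R.T - bc) ** 2).sum(1).mean())
                        if r < best[0]:
                            best = (r, (ax, az, theta))
            return best

        best, (ax, az, th) = grid_min((0, np.pi), (0, 2 * np.pi), (0, 2 * np.pi), 25)
        w = np.pi / 24
        for _ in range(3):
            best, (ax, az, th) = grid_min((ax - w, ax + w), (az - w, az + w), (th - w, th + w), 11)
            w /= 5
        assert kabsch_rmsd <= best + 1e-9
        assert abs(kabsch_rmsd - best) < 1e-3

    def test_agrees_with_mdanalysis(self):
        from MDAnalysis.analysis.rms import rmsd as mda_rmsd

        rng = np.random.default_rng(2)
        a = rng.normal(size=(12, 3))
        b = a + rng.normal(scale=0.4, size=(12, 3))
        ours = superpose_rmsd(single_frame(b), reference=a, selection="all")[0]
        theirs = mda_rmsd(b, a, center=True, superposition=True)
        assert ours == pytest.approx(theirs, abs=1e-8)

    def test_atom_count_mismatch_rejected(self):
        traj = gen_trajectory(TrajectorySpec(n_residues=4, n_frames=2))
        with pytest.raises(ValueError):
            superpose_rmsd(traj, reference=np.zeros((3, 3)))


class TestRmsf:
    def test_zero_noise_zero_rmsf(self):
        traj = gen_trajectory(TrajectorySpec(n_residues=6, n_frames=5, sigma_profile=0.0))
        assert np.allclose(rmsf(traj), 0.0)

    def test_doubling_sigma_doubles_rmsf(self):
        kw = dict(n_residues=40, n_frames=3000, seed=6)
        r1 = rmsf(gen_trajectory(TrajectorySpec(sigma_profile=0.5, **kw)), fit=False)
        r2 = rmsf(gen_trajectory(TrajectorySpec(sigma_profile=1.0, **kw)), fit=False)
        assert np.allclose(r2 / r1, 2.0, rtol=1e-12)


class TestRadiusOfGyration:
    def test_symmetric_pair(self):
        traj = single_frame([[0, 0, 0], [2, 0, 0]])
        assert radius_of_gyration(traj)[0] == pytest.approx(0.1)  # 1 Å in nm

    def test_single_atom_zero(self):
        assert radius_of_gyration(single_frame([[3, 4, 5]]))[0] == 0.0

    def test_uniform_ring_equals_radius(self):
        R = 7.0
        theta = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        ring = np.stack([R * np.cos(theta), R * np.sin(theta), np.zeros_like(theta)], 1)
        assert radius_of_gyration(single_frame(ring))[0] == pytest.approx(R * 0.1)

    def test_invariant_under_rigid_motion(self):
        traj = gen_trajectory(TrajectorySpec(n_residues=10, n_frames=3, seed=1))
        rg0 = radius_of_gyration(traj)
        R = rotation_matrix([0, 1, 1], 0.8)
        moved = Trajectory(traj.coords @ R.T + 11.0, traj.masses, traj.atom_residues, traj.atom_names)
        assert np.allclose(radius_of_gyration(moved), rg0)


class TestHbond:
    def _traj(self, coords):
        coords = np.asarray(coords, float)
        if coords.ndim == 2:
            coords = coords[None]
        n = coords.shape[1]
        return Trajectory(coords, np.ones(n), np.arange(n), ["O"] * n)

    def test_ideal_linear_bond_counted(self):
        traj = self._traj([[0, 0, 0], [1, 0, 0], [2.8, 0, 0]])
        assert hbond_count(traj, [(0, 1)], [2])[0] == 1

    def test_long_distance_not_counted(self):
        traj = self._traj([[0, 0, 0], [1, 0, 0], [4.0, 0, 0]])
        assert hbond_count(traj, [(0, 1)], [2])[0] == 0

    def test_bent_geometry_not_counted(self):
        # H at 90° from the D->A axis: angle H-D-A = 90° > 30°
        traj = self._traj([[0, 0, 0], [0, 1, 0], [2.8, 0, 0]])
        assert hbond_count(traj, [(0, 1)], [2])[0] == 0

    def test_matches_brute_force_oracle_on_random_frames(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 8, size=(100, 12, 3))
        traj = self._traj(coords)
        donors = [(0, 1), (4, 5), (8, 9)]
        acceptors = [2, 3, 6, 7, 10, 11]
        ours = hbond_count(traj, donors, acceptors)
        for f in range(coords.shape[0]):
            n = 0
            for d, h in donors:
                for a in acceptors:
                    v_da = coords[f, a] - coords[f, d]
                    v_dh = coords[f, h] - coords[f, d]
                    dist = np.linalg.norm(v_da)
                    cosang = v_dh @ v_da / (np.linalg.norm(v_dh) * dist)
                    if dist <= 3.5 and np.degrees(np.arccos(np.clip(cosang, -1, 1))) <= 30:
                        n += 1
            assert ours[f] == n

    def test_invalid_hydrogen_index_rejected(self):
        traj = self._traj([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError):
            hbond_count(traj, [(0, 99)], [1])


class TestSasa:
    def test_isolated_atom_closed_form(self):
        traj = single_frame([[0, 0, 0]])
        area = sasa(traj, np.array([1.7]))[0]
        exact = 4 * np.pi * (1.7 + 1.4) ** 2 * 0.01  # nm²
        assert abs(area - exact) / exact < 0.01

    def test_fully_overlapping_atoms_count_once(self):
        one = sasa(single_frame([[0, 0, 0]]), np.array([1.7]))[0]
        two = sasa(single_frame([[0, 0, 0], [0, 0, 0]]), np.array([1.7, 1.7]))[0]
        assert two == pytest.approx(one, rel=1e-6)

    def test_monotone_decrease_on_approach(self):
        areas = []
        for d in (8.0, 5.0, 3.0, 1.5, 0.5):
            traj = single_frame([[0, 0, 0], [d, 0, 0]])
            areas.append(sasa(traj, np.array([1.7, 1.7]))[0])
        assert all(a >= b for a, b in zip(areas, areas[1:]))
        assert areas[0] > areas[-1]

    def test_missing_radius_rejected(self):
        with pytest.raises(ValueError):
            sasa(single_frame([[0, 0, 0]]), np.array([np.nan]))


class TestDccm:
    def test_unit_diagonal_symmetry_and_range(self):
        traj = gen_trajectory(TrajectorySpec(n_residues=15, n_frames=400, seed=2))
        C = dccm(traj)
        assert np.allclose(np.diag(C.values), 1.0)
        assert np.allclose(C.values, C.values.T)
        assert np.nanmax(np.abs(C.values)) <= 1.0 + 1e-12

    def test_identical_displacements_fully_correlated(self):
        rng = np.random.default_rng(4)
        disp = rng.normal(size=(200, 1, 3))
        base = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        coords = base[None] + np.concatenate([disp, disp], axis=1)
        traj = Trajectory(coords, np.ones(2), np.array([0, 1]), ["CA", "CA"])
        C = dccm(traj, fit=False)
        assert C.values[0, 1] == pytest.approx(1.0)

    def test_immobile_atom_masked(self):
        rng = np.random.default_rng(5)
        coords = np.zeros((50, 2, 3))
        coords[:, 1] = rng.normal(size=(50, 3))
        traj = Trajectory(coords, np.ones(2), np.array([0, 1]), ["CA", "CA"])
        C = dccm(traj, fit=False)
        assert C.mask[0] and not C.mask[1]
        assert np.isnan(C.values[0, 1]) and np.isnan(C.values[0, 0])


class TestFel:
    def test_single_conformation_single_zero_bin(self):
        surface = fel(np.ones(50), np.full(50, 2.0), bins=5)
        finite = np.isfinite(surface.G)
        assert finite.sum() == 1
        assert np.nanmin(surface.G) == 0.0

    def test_equally_populated_bins_both_zero(self):
        rmsd = np.array([0.5] * 10 + [4.5] * 10)
        rg = np.array([0.5] * 10 + [4.5] * 10)
        surface = fel(rmsd, rg, bins=2)
        finite = surface.G[np.isfinite(surface.G)]
        assert np.allclose(finite, 0.0)

    def test_population_ratio_gives_rt(self):
        t = 298.15
        # N_max = e * N for the rarer bin -> G = RT (use counts 271 and 100 ~ e ratio is inexact; use exact ratio)
        n_max, n = 1000, int(round(1000 / np.e))
        rmsd = np.array([0.5] * n_max + [4.5] * n)
        rg = np.ones_like(rmsd)
        surface = fel(rmsd, rg, temperature=t, bins=2)
        finite = np.sort(surface.G[np.isfinite(surface.G)])
        assert finite[0] == 0.0
        assert finite[-1] == pytest.approx(R_KCAL * t * np.log(n_max / n), rel=1e-9)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            fel(np.array([]), np.array([]))


class TestPdbIO:
    def test_round_trip_and_mdanalysis_compatibility(self, tmp_path):
        import MDAnalysis as mda

        traj = gen_trajectory(TrajectorySpec(n_residues=6, atoms_per_residue=3, n_frames=4, seed=7))
        path = tmp_path / "traj.pdb"
        write_pdb(traj, path)
        back = read_pdb(path)
        assert back.n_frames == traj.n_frames
        assert back.atom_names == traj.atom_names
        assert np.array_equal(back.atom_residues, traj.atom_residues)
        assert np.abs(back.coords - traj.coords).max() < 1e-3  # PDB precision
        u = mda.Universe(str(path))
        assert len(u.trajectory) == traj.n_frames
        assert len(u.atoms) == traj.n_atoms
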