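"""Ensemble container, PDB/XYZ I/O, selections, and Kabsch superposition."""

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from loopgate import (
    DegenerateFitError,
    ParseError,
    SelectionError,
    TopologyError,
    TrajectoryEnsemble,
    ValidationError,
    iterative_mean_fit,
    kabsch_superpose,
    make_calpha_topology,
    read_multimodel_pdb,
    read_xyz_trajectory,
    rmsd,
    select_atoms,
    write_multimodel_pdb,
    write_xyz_trajectory,
)
from loopgate.synthetic_data import GaussianEnsembleSpec, generate_gaussian_ensemble, helical_mean_structure

from conftest import pdb_atom_line, straight_chain


class TestEnsembleInvariants:
    def test_rejects_nonfinite_coordinates(self):
        coords = np.zeros((2, 3, 3))
        coords[1, 2, 0] = np.nan
        with pytest.raises(ValidationError):
            TrajectoryEnsemble(atoms=make_calpha_topology(3), coordinates=coords)

    def test_rejects_atom_count_mismatch(self):
        with pytest.raises(TopologyError):
            TrajectoryEnsemble(atoms=make_calpha_topology(4), coordinates=np.zeros((1, 3, 3)))

    def test_rejects_zero_frames(self):
        with pytest.raises(ValidationError):
            TrajectoryEnsemble(atoms=make_calpha_topology(3), coordinates=np.zeros((0, 3, 3)))


class TestPdbIO:
    def test_two_models_three_atoms(self, two_model_pdb):
        traj = read_multimodel_pdb(str(two_model_pdb))
        assert traj.n_frames == 2
        assert traj.n_atoms == 3
        # ligand het atom retained under its het-code
        assert traj.atoms[2].residue_name == "TH2"
        assert traj.atoms[2].name == "N4"
        np.testing.assert_allclose(traj.coordinates[1, 0] - traj.coordinates[0, 0], [1.5, 0, 0])

    def test_inconsistent_model_raises_topology_error(self, tmp_path):
        lines = ["MODEL        1",
                 pdb_atom_line(1, "CA", "GLY", "A", 1, 0, 0, 0),
                 pdb_atom_line(2, "CA", "GLY", "A", 2, 3.8, 0, 0),
                 "ENDMDL",
                 "MODEL        2",
                 pdb_atom_line(1, "CA", "GLY", "A", 1, 0, 0, 0),
                 "ENDMDL", "END"]
        path = tmp_path / "bad.pdb"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(TopologyError):
            read_multimodel_pdb(str(path))

    def test_malformed_coordinate_names_line(self, tmp_path):
        good = pdb_atom_line(1, "CA", "GLY", "A", 1, 1.0, 2.0, 3.0)
        path = tmp_path / "mangled.pdb"
        path.write_text(good.replace("1.000", "1.0x0") + "\n")
        with pytest.raises(ParseError, match="line"):
            read_multimodel_pdb(str(path))

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        lines = [
            pdb_atom_line(1, "N", "ASN", "A", 33, 0, 0, 0),
            pdb_atom_line(2, "CA", "ASN", "A", 33, 1.0, 0, 0, altloc="A", occupancy=0.4),
            pdb_atom_line(3, "CA", "ASN", "A", 33, 2.0, 0, 0, altloc="B", occupancy=0.6),
            pdb_atom_line(4, "C", "ASN", "A", 33, 3.0, 0, 0),
            "END",
        ]
        path = tmp_path / "altloc.pdb"
        path.write_text("\n".join(lines) + "\n")
        traj = read_multimodel_pdb(str(path))
        assert traj.n_atoms == 3
        ca = [i for i, a in enumerate(traj.atoms) if a.name == "CA"]
        assert traj.coordinates[0, ca[0], 0] == pytest.approx(2.0)

    def test_write_read_roundtrip(self, random_ensemble, tmp_path):
        path = tmp_path / "rt.pdb"
        write_multimodel_pdb(random_ensemble, str(path))
        back = read_multimodel_pdb(str(path))
        assert back.n_frames == random_ensemble.n_frames
        np.testing.assert_allclose(back.coordinates, random_ensemble.coordinates, atol=1e-3)


class TestXyzIO:
    def test_roundtrip_within_precision(self, random_ensemble, tmp_path):
        path = tmp_path / "t.xyz"
        write_xyz_trajectory(random_ensemble, str(path))
        back = read_xyz_trajectory(str(path), random_ensemble.atoms)
        np.testing.assert_allclose(back.coordinates, random_ensemble.coordinates, atol=1e-4)

    def test_empty_file_is_parse_error(self, tmp_path):
        path = tmp_path / "empty.xyz"
        path.write_text("")
        with pytest.raises(ParseError):
            read_xyz_trajectory(str(path), make_calpha_topology(3))

    def test_nan_token_is_validation_error(self, tmp_path):
        path = tmp_path / "nan.xyz"
        path.write_text("1\nframe 0\nCA nan 0.0 0.0\n")
        with pytest.raises(ValidationError):
            read_xyz_trajectory(str(path), make_calpha_topology(1))

    def test_atom_count_mismatch_is_topology_error(self, tmp_path):
        path = tmp_path / "mismatch.xyz"
        path.write_text("2\nframe 0\nCA 0 0 0\nCA 1 0 0\n")
        with pytest.raises(TopologyError):
            read_xyz_trajectory(str(path), make_calpha_topology(3))


class TestSelectAtoms:
    @pytest.mark.parametrize(
        "query, expected",
        [
            ("resid 23-29 and name CA", 7),
            ("resid 139-143 and name CA", 5),
            ("resid 33 and name CA", 1),
            ("name CA", 155),
            ("resid 1,3,5 and name CA", 3),
        ],
    )
    def test_residue_range_counts(self, query, expected):
        traj = straight_chain(155)
        assert len(select_atoms(traj, query)) == expected

    def test_empty_selection_warns(self):
        traj = straight_chain(5)
        with pytest.warns(UserWarning, match="matched no atoms"):
            sel = select_atoms(traj, "name OD1")
        assert len(sel) == 0

    @pytest.mark.parametrize("query", ["", "bogus CA", "resid 5-3", "name", "resid x"])
    def test_bad_query_raises(self, query):
        with pytest.raises(SelectionError):
            select_atoms(straight_chain(5), query)

    def test_idempotent_and_stable_under_xyz_roundtrip(self, random_ensemble, tmp_path):
        sel1 = select_atoms(random_ensemble, "resid 2-5 and name CA")
        path = tmp_path / "sel.xyz"
        write_xyz_trajectory(random_ensemble, str(path))
        back = read_xyz_trajectory(str(path), random_ensemble.atoms)
        sel2 = select_atoms(back, "resid 2-5 and name CA")
        assert sel1.indices == sel2.indices


def brute_force_min_rmsd(p, q, n_grid=24):
    """Oracle: minimize RMSD over SO(3) by Euler-angle grid + local polish."""
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)

    def cost(angles):
        r = Rotation.from_euler("zyx", angles).as_matrix()
        return np.sqrt(np.mean(np.sum((pc @ r.T - qc) ** 2, axis=1)))

    grid = np.linspace(-np.pi, np.pi, n_grid, endpoint=False)
    best = min(
        (cost(a) for a in itertools.product(grid, grid, grid)),
    )
    # polish from the best grid point
    best_angles = min(itertools.product(grid, grid, grid), key=cost)
    res = minimize(cost, best_angles, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-14})
    return min(best, res.fun)


class TestKabsch:
    def test_frame_vs_itself_is_zero(self, random_ensemble):
        sel = select_atoms(random_ensemble, "name CA")
        res = kabsch_superpose(random_ensemble, sel, reference=0)
        assert res.per_frame_rmsd[0] == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy_rmsd_vanishes(self):
        ref = helical_mean_structure(8)
        rot = Rotation.from_euler("zyx", [0.4, -1.1, 2.0]).as_matrix()
        moved = ref @ rot.T + np.array([5.0, -3.0, 11.0])
        traj = TrajectoryEnsemble(
            atoms=make_calpha_topology(8), coordinates=np.stack([ref, moved])
        )
        res = kabsch_superpose(traj, select_atoms(traj, "name CA"), reference=0)
        assert res.per_frame_rmsd[1] < 1e-8
        np.testing.assert_allclose(res.rotated_trajectory.coordinates[1], ref, atol=1e-8)

    def test_matches_brute_force_minimum(self):
        # two hand-written 4-atom frames; oracle = grid+polish over rotations
        p = np.array([[0.0, 0, 0], [3, 0, 0], [0, 2, 0], [1, 1, 2.5]])
        q = np.array([[0.2, 0.1, 0], [2.7, 0.4, 0.3], [-0.1, 2.2, -0.2], [1.4, 0.8, 2.3]])
        traj = TrajectoryEnsemble(atoms=make_calpha_topology(4), coordinates=np.stack([q, p]))
        res = kabsch_superpose(traj, select_atoms(traj, "name CA"), reference=0)
        oracle = brute_force_min_rmsd(p, q)
        assert res.per_frame_rmsd[1] == pytest.approx(oracle, abs=1e-3)

    def test_collinear_fit_raises(self):
        traj = straight_chain(5, n_frames=2)
        with pytest.raises(DegenerateFitError):
            kabsch_superpose(traj, select_atoms(traj, "name CA"), reference=0)

    def test_preserves_internal_distances(self, random_ensemble):
        sel = select_atoms(random_ensemble, "name CA")
        res = kabsch_superpose(random_ensemble, sel, reference=0)
        for f in (0, random_ensemble.n_frames - 1):
            before = np.linalg.norm(
                random_ensemble.coordinates[f][:, None] - random_ensemble.coordinates[f][None], axis=2
            )
            after = np.linalg.norm(
                res.rotated_trajectory.coordinates[f][:, None]
                - res.rotated_trajectory.coordinates[f][None],
                axis=2,
            )
            np.testing.assert_allclose(after, before, atol=1e-8)

    def test_rmsd_symmetric_and_rigid_invariant(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(6, 3)) * 4
        b = rng.normal(size=(6, 3)) * 4
        assert rmsd(a, b) == pytest.approx(rmsd(b, a))
        rot = Rotation.from_euler("zyx", [1.0, 0.2, -0.7]).as_matrix()
        traj = TrajectoryEnsemble(
            atoms=make_calpha_topology(6),
            coordinates=np.stack([a, b, a @ rot.T + 2.0, b @ rot.T + 2.0]),
        )
        sel = select_atoms(traj, "name CA")
        r1 = kabsch_superpose(traj, sel, reference=0).per_frame_rmsd[1]
        r2 = kabsch_superpose(traj, sel, reference=2).per_frame_rmsd[3]
        assert r1 == pytest.approx(r2, abs=1e-9)


class TestIterativeMeanFit:
    def test_identical_frames_converge_immediately(self):
        coords = np.tile(helical_mean_structure(6), (5, 1, 1))
        traj = TrajectoryEnsemble(atoms=make_calpha_topology(6), coordinates=coords)
        res = iterative_mean_fit(traj, select_atoms(traj, "name CA"))
        assert res.converged
        np.testing.assert_allclose(res.per_frame_rmsd, 0.0, atol=1e-12)

    def test_fixed_point_of_prefit_ensemble(self, random_ensemble):
        sel = select_atoms(random_ensemble, "name CA")
        first = iterative_mean_fit(random_ensemble, sel)
        second = iterative_mean_fit(first.rotated_trajectory, sel)
        assert second.n_iterations <= first.n_iterations
        assert rmsd(second.mean_structure, first.mean_structure) < 1e-3

    def test_recovers_known_mean(self):
        mean = helical_mean_structure(12)
        sigma, n = 0.4, 4000
        spec = GaussianEnsembleSpec(
            mean_structure=mean, isotropic_noise_sigma=sigma, n_frames=n, seed=11
        )
        traj = generate_gaussian_ensemble(spec)
        res = iterative_mean_fit(traj, select_atoms(traj, "name CA"))
        se = sigma / np.sqrt(n)
        # fitted mean matches the planted mean up to a rigid transform
        two = TrajectoryEnsemble(
            atoms=make_calpha_topology(12), coordinates=np.stack([mean, res.mean_structure])
        )
        aligned = kabsch_superpose(two, select_atoms(two, "name CA"), reference=0)
        assert aligned.per_frame_rmsd[1] < 3 * se * np.sqrt(3)
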