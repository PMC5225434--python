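"""Covariance construction, diagonalization, projections, FEL, mode motion."""

import numpy as np
import numpy.ma as ma
import pytest

from loopgate import (
    BOLTZMANN_KCAL,
    CovarianceModel,
    GaussianEnsembleSpec,
    ProjectionSeries,
    TrajectoryEnsemble,
    ValidationError,
    build_covariance,
    build_landscape,
    count_basins,
    diagonalize,
    extreme_frame,
    generate_gaussian_ensemble,
    helical_mean_structure,
    make_calpha_topology,
    mode_motion,
    project,
    select_atoms,
)


def naive_covariance(coords):
    """Brute-force double-loop covariance oracle (divisor = frame count)."""
    f, n, _ = coords.shape
    flat = coords.reshape(f, 3 * n)
    mean = flat.mean(axis=0)
    c = np.zeros((3 * n, 3 * n))
    for i in range(3 * n):
        for j in range(3 * n):
            c[i, j] = np.mean((flat[:, i] - mean[i]) * (flat[:, j] - mean[j]))
    return c


def ensemble_from(coords):
    return TrajectoryEnsemble(atoms=make_calpha_topology(coords.shape[1]), coordinates=coords)


class TestBuildCovariance:
    def test_two_atom_hand_computation(self):
        # frames: atom1 at (0,0,0) then (2,0,0); atom2 fixed at (1,0,0)
        coords = np.array([[[0.0, 0, 0], [1, 0, 0]], [[2.0, 0, 0], [1, 0, 0]]])
        traj = ensemble_from(coords)
        model = build_covariance(traj, select_atoms(traj, "name CA"), prefit=False)
        assert model.matrix_c[0, 0] == pytest.approx(1.0)  # mean 1, deviations ±1, divisor 2
        np.testing.assert_allclose(model.matrix_c[3:, :], 0.0, atol=1e-14)
        np.testing.assert_allclose(model.matrix_c[:, 3:], 0.0, atol=1e-14)

    def test_identical_frames_zero_covariance(self):
        coords = np.tile(helical_mean_structure(4), (6, 1, 1))
        traj = ensemble_from(coords)
        model = build_covariance(traj, select_atoms(traj, "name CA"), prefit=False)
        np.testing.assert_allclose(model.matrix_c, 0.0, atol=1e-14)
        np.testing.assert_allclose(model.eigenvalues, 0.0, atol=1e-14)

    def test_single_frame_rejected(self):
        traj = ensemble_from(helical_mean_structure(4)[None])
        with pytest.raises(ValidationError):
            build_covariance(traj, select_atoms(traj, "name CA"))

    def test_matches_naive_oracle_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            f = int(rng.integers(2, 51))
            n = int(rng.integers(2, 6))
            coords = rng.normal(size=(f, n, 3)) * 2.0
            traj = ensemble_from(coords)
            model = build_covariance(traj, select_atoms(traj, "name CA"), prefit=False)
            np.testing.assert_allclose(model.matrix_c, naive_covariance(coords), atol=1e-12)

    def test_planted_mode_recovery(self):
        mean = helical_mean_structure(10)
        mode = np.random.default_rng(4).normal(size=30)
        mode /= np.linalg.norm(mode)
        amplitude, sigma = 2.0, 0.2
        spec = GaussianEnsembleSpec(
            mean_structure=mean, mode_vectors=[mode], mode_amplitudes=[amplitude],
            isotropic_noise_sigma=sigma, n_frames=20_000, seed=6,
        )
        traj = generate_gaussian_ensemble(spec)
        model = build_covariance(traj, select_atoms(traj, "name CA"), prefit=False)
        assert model.eigenvalues[0] == pytest.approx(amplitude**2 + sigma**2, rel=0.05)
        assert abs(model.eigenvectors[0] @ mode) > 0.99


class TestDiagonalize:
    def test_diagonal_matrix_spectrum(self):
        c = np.diag([4.0, 1.0, 0.0, 0.0, 0.0, 0.0])
        model = CovarianceModel(
            selection=select_atoms(ensemble_from(np.zeros((1, 2, 3))), "name CA"),
            mean=np.zeros((2, 3)),
            matrix_c=c,
        )
        model = diagonalize(model)
        np.testing.assert_allclose(model.eigenvalues, [4.0, 1.0, 0, 0, 0, 0], atol=1e-14)
        assert abs(model.eigenvectors[0] @ np.eye(6)[0]) == pytest.approx(1.0)

    def test_trace_identity_and_known_spectrum_recovery(self):
        rng = np.random.default_rng(8)
        q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        lam = np.array([5.0, 3.0, 1.5, 0.7, 0.2, 0.0])
        c = q @ np.diag(lam) @ q.T
        c = 0.5 * (c + c.T)
        model = CovarianceModel(
            selection=select_atoms(ensemble_from(np.zeros((1, 2, 3))), "name CA"),
            mean=np.zeros((2, 3)),
            matrix_c=c,
        )
        model = diagonalize(model)
        np.testing.assert_allclose(model.eigenvalues, lam, atol=1e-10)
        assert np.sum(model.eigenvalues) == pytest.approx(np.trace(c), abs=1e-8)
        # orthonormal eigenvectors
        np.testing.assert_allclose(model.eigenvectors @ model.eigenvectors.T, np.eye(6), atol=1e-8)

    def test_asymmetric_matrix_rejected(self):
        c = np.eye(6)
        c[0, 1] = 1e-3
        model = CovarianceModel(
            selection=select_atoms(ensemble_from(np.zeros((1, 2, 3))), "name CA"),
            mean=np.zeros((2, 3)),
            matrix_c=c,
        )
        with pytest.raises(ValidationError, match="asymmetric"):
            diagonalize(model)

    def test_sign_convention_largest_component_positive(self, random_ensemble):
        model = build_covariance(random_ensemble, select_atoms(random_ensemble, "name CA"))
        for k in range(5):
            v = model.eigenvectors[k]
            assert v[np.argmax(np.abs(v))] > 0


class TestProject:
    @pytest.fixture
    def model_and_traj(self, random_ensemble):
        sel = select_atoms(random_ensemble, "name CA")
        from loopgate import iterative_mean_fit

        fitted = iterative_mean_fit(random_ensemble, sel).rotated_trajectory
        return build_covariance(fitted, sel, prefit=False), fitted

    def test_projection_mean_is_zero(self, model_and_traj):
        model, traj = model_and_traj
        proj = project(traj, model)
        assert abs(proj.pc1.mean()) < 1e-8
        assert abs(proj.pc2.mean()) < 1e-8

    def test_projection_variance_equals_eigenvalue(self, model_and_traj):
        model, traj = model_and_traj
        proj = project(traj, model)
        assert np.var(proj.pc1) == pytest.approx(model.eigenvalues[0], abs=1e-8)
        assert np.var(proj.pc2) == pytest.approx(model.eigenvalues[1], abs=1e-8)

    def test_displaced_mean_projects_to_displacement(self, model_and_traj):
        model, _ = model_and_traj
        c = 1.7
        frame = (model.mean.reshape(-1) + c * model.eigenvectors[0]).reshape(1, -1, 3)
        traj = ensemble_from(frame)
        proj = project(traj, model)
        assert proj.pc1[0] == pytest.approx(c, abs=1e-10)
        assert proj.pc2[0] == pytest.approx(0.0, abs=1e-10)


class TestExtremeFrame:
    def test_max_and_min(self):
        proj = ProjectionSeries(pc1=np.array([0.1, 5.2, -3.0]), pc2=np.zeros(3))
        assert extreme_frame(proj, mode=1, side="max") == 1
        assert extreme_frame(proj, mode=1, side="min") == 2

    def test_tie_goes_to_earliest(self):
        proj = ProjectionSeries(pc1=np.ones(5), pc2=np.ones(5))
        assert extreme_frame(proj, mode=1, side="max") == 0
        assert extreme_frame(proj, mode=2, side="min") == 0


class TestLandscape:
    def test_two_bin_closed_form(self):
        # 80 frames in one spot, 20 in another, 2x2 grid
        pc1 = np.concatenate([np.zeros(80), np.ones(20) * 10.0])
        proj = ProjectionSeries(pc1=pc1, pc2=np.zeros(100))
        surface = build_landscape(proj, temperature=300.0, n_bins=2)
        dg = surface.delta_g.compressed()
        expected = -BOLTZMANN_KCAL * 300.0 * np.log(20 / 80)
        assert sorted(np.round(dg, 6)) == pytest.approx([0.0, round(expected, 6)])
        assert expected == pytest.approx(0.826, abs=0.001)

    def test_uniform_occupancy_is_flat(self):
        # exactly one sample per bin center on a 4x4 grid
        g = np.linspace(0, 3, 4)
        xx, yy = np.meshgrid(g, g)
        proj = ProjectionSeries(pc1=xx.ravel(), pc2=yy.ravel())
        surface = build_landscape(proj, n_bins=4)
        np.testing.assert_allclose(surface.delta_g.compressed(), 0.0, atol=1e-12)

    def test_single_occupied_bin(self):
        proj = ProjectionSeries(pc1=np.zeros(50), pc2=np.zeros(50))
        surface = build_landscape(proj, n_bins=3)
        assert surface.counts.sum() == 50
        unmasked = ~ma.getmaskarray(surface.delta_g)
        assert unmasked.sum() == 1
        assert float(surface.delta_g.compressed()[0]) == 0.0
        assert len(count_basins(surface)) == 1

    def test_counts_sum_to_frames_and_min_is_zero(self, random_ensemble):
        sel = select_atoms(random_ensemble, "name CA")
        model = build_covariance(random_ensemble, sel)
        from loopgate import iterative_mean_fit

        fitted = iterative_mean_fit(random_ensemble, sel).rotated_trajectory
        surface = build_landscape(project(fitted, model), n_bins=6)
        assert surface.counts.sum() == random_ensemble.n_frames
        assert surface.delta_g.min() == 0.0
        assert (surface.delta_g.compressed() >= 0).all()

    def test_nonpositive_temperature_rejected(self):
        proj = ProjectionSeries(pc1=np.zeros(5), pc2=np.zeros(5))
        with pytest.raises(ValidationError):
            build_landscape(proj, temperature=0.0)


class TestModeMotion:
    def test_zero_amplitude_zero_vectors(self, random_ensemble):
        model = build_covariance(random_ensemble, select_atoms(random_ensemble, "name CA"))
        motion = mode_motion(model, mode=1, amplitude=0.0)
        np.testing.assert_array_equal(motion.displacements, 0.0)

    def test_norm_scales_linearly_with_amplitude(self, random_ensemble):
        model = build_covariance(random_ensemble, select_atoms(random_ensemble, "name CA"))
        m1 = mode_motion(model, mode=1, amplitude=1.0)
        m3 = mode_motion(model, mode=1, amplitude=3.0)
        np.testing.assert_allclose(m3.displacements, 3.0 * m1.displacements, atol=1e-12)

    def test_planted_mode_direction_recovered(self):
        mean = helical_mean_structure(8)
        mode = np.random.default_rng(9).normal(size=24)
        mode /= np.linalg.norm(mode)
        spec = GaussianEnsembleSpec(
            mean_structure=mean, mode_vectors=[mode], mode_amplitudes=[2.0],
            isotropic_noise_sigma=0.1, n_frames=20_000, seed=10,
        )
        traj = generate_gaussian_ensemble(spec)
        model = build_covariance(traj, select_atoms(traj, "name CA"), prefit=False)
        motion = mode_motion(model, mode=1, amplitude=1.0)
        cos = motion.displacements.reshape(-1) @ mode
        assert abs(cos) > 0.99

    def test_mode_out_of_range(self, random_ensemble):
        model = build_covariance(random_ensemble, select_atoms(random_ensemble, "name CA"))
        with pytest.raises(ValidationError):
            mode_motion(model, mode=0, amplitude=1.0)
        with pytest.raises(ValidationError):
            mode_motion(model, mode=31, amplitude=1.0)
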