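import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import dockmap as dm
from dockmap.trajectory import ModeSet, project


@pytest.fixture(scope="module")
def ref_coords(toy=None):
    return dm.make_toy_complex(0).coords(heavy_only=False)[:30]


def rigid_copies(ref, n, seed):
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n):
        rot = Rotation.random(rng=rng).as_matrix()
        frames.append((ref - ref.mean(0)) @ rot.T + rng.normal(size=3) * 10)
    return np.array(frames)


class TestTrajRmsd:
    def test_constant_trajectory_is_zero(self, ref_coords):
        t = dm.Trajectory(np.repeat(ref_coords[None], 5, axis=0))
        np.testing.assert_allclose(dm.traj_rmsd(t, ref_coords), 0.0, atol=1e-9)

    def test_rigid_motion_removed_by_fitting(self, ref_coords):
        t = dm.Trajectory(rigid_copies(ref_coords, 8, seed=1))
        assert dm.traj_rmsd(t, ref_coords).max() < 1e-6

    def test_gaussian_noise_matches_direct_oracle(self, ref_coords):
        rng = np.random.default_rng(2)
        sigma = 0.5
        noise = rng.normal(0, sigma, size=(40, *ref_coords.shape))
        t = dm.Trajectory(ref_coords[None] + noise)
        series = dm.traj_rmsd(t, ref_coords)
        direct = np.sqrt(np.mean(np.sum(noise**2, axis=2), axis=1))
        # fitting can only lower each frame's RMSD, and only slightly here
        assert np.all(series <= direct + 1e-12)
        assert series.mean() == pytest.approx(direct.mean(), rel=0.05)

    def test_shape_mismatch_rejected(self, ref_coords):
        t = dm.Trajectory(ref_coords[None])
        with pytest.raises(ValueError):
            dm.traj_rmsd(t, ref_coords[:-1])


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        t = dm.Trajectory(np.zeros((3, 1, 3)))
        np.testing.assert_allclose(
            dm.radius_of_gyration(t, mass_weighted=False), 0.0
        )

    def test_two_unit_mass_points_half_separation(self):
        frames = np.array([[[0.0, 0, 0], [2.0, 0, 0]]])
        t = dm.Trajectory(frames)
        assert dm.radius_of_gyration(t, mass_weighted=False)[0] == pytest.approx(1.0)

    def test_uniform_ring_equals_radius(self):
        ang = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        ring = 7.5 * np.stack([np.cos(ang), np.sin(ang), np.zeros_like(ang)], axis=1)
        t = dm.Trajectory(ring[None])
        assert dm.radius_of_gyration(t, mass_weighted=False)[0] == pytest.approx(
            7.5, abs=1e-9
        )

    def test_mass_weighting_follows_the_formula(self):
        frames = np.array([[[0.0, 0, 0], [4.0, 0, 0]]])
        masses = np.array([3.0, 1.0])
        t = dm.Trajectory(frames, masses=masses)
        com = 1.0  # (3*0 + 1*4)/4
        expected = np.sqrt((3 * com**2 + 1 * (4 - com) ** 2) / 4)
        assert dm.radius_of_gyration(t)[0] == pytest.approx(expected)

    def test_constant_under_rigid_motion_and_nm_unit(self, ref_coords):
        t = dm.Trajectory(rigid_copies(ref_coords, 6, seed=3))
        rg = dm.radius_of_gyration(t, mass_weighted=False)
        assert rg.std() < 1e-9
        rg_nm = dm.radius_of_gyration(t, mass_weighted=False, unit="nm")
        np.testing.assert_allclose(rg_nm, rg / 10.0)


class TestPcaModes:
    def test_single_direction_oscillation_rank_one(self, ref_coords):
        # breathing mode (radial expansion): orthogonal to every rigid-body
        # motion, so the internal fitting leaves it untouched
        v = (ref_coords - ref_coords.mean(0)).reshape(-1)
        v /= np.linalg.norm(v)
        amp = np.linspace(-2, 2, 9)
        frames = ref_coords[None] + (amp[:, None] * v[None]).reshape(9, -1, 3)
        modes = dm.pca_modes(dm.Trajectory(frames))
        overlap = abs(float(modes.eigenvectors[:, 0] @ v))
        assert overlap == pytest.approx(1.0, abs=1e-6)
        assert modes.eigenvalues[1:] == pytest.approx(0.0, abs=1e-9)

    def test_eigenvalue_sum_equals_total_variance(self, ref_coords):
        rng = np.random.default_rng(4)
        frames = ref_coords[None] + rng.normal(0, 0.3, size=(25, *ref_coords.shape))
        t = dm.Trajectory(frames)
        modes = dm.pca_modes(t)
        # recompute the fitted ensemble the same way an independent script would
        from dockmap.superpose import kabsch
        fitted = np.array([kabsch(t.frames[0], f).apply(f) for f in t.frames])
        mean = fitted.mean(0)
        fitted = np.array([kabsch(mean, f).apply(f) for f in fitted])
        mean = fitted.mean(0)
        x = (fitted - mean).reshape(25, -1)
        total_var = np.sum(np.var(x, axis=0, ddof=1))
        assert modes.eigenvalues.sum() == pytest.approx(total_var, rel=1e-9)

    def test_matches_dense_covariance_oracle(self, ref_coords):
        """Eigenvalues agree with an explicit 3n x 3n covariance eigensolve."""
        rng = np.random.default_rng(5)
        small = ref_coords[:6]
        frames = small[None] + rng.normal(0, 0.4, size=(30, *small.shape))
        t = dm.Trajectory(frames)
        modes = dm.pca_modes(t)
        from scipy.spatial.transform import Rotation as R

        def fit(ref, mobile):
            rot, _ = R.align_vectors(ref - ref.mean(0), mobile - mobile.mean(0))
            return (mobile - mobile.mean(0)) @ rot.as_matrix().T + ref.mean(0)

        fitted = np.array([fit(t.frames[0], f) for f in t.frames])
        mean = fitted.mean(0)
        fitted = np.array([fit(mean, f) for f in fitted])
        mean = fitted.mean(0)
        x = (fitted - mean).reshape(30, -1)
        cov = np.cov(x.T, ddof=1)
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(modes.eigenvalues, evals[: modes.n_modes], atol=1e-8)

    def test_orthonormal_modes(self, ref_coords):
        rng = np.random.default_rng(6)
        frames = ref_coords[None] + rng.normal(0, 0.3, size=(12, *ref_coords.shape))
        modes = dm.pca_modes(dm.Trajectory(frames))
        gram = modes.eigenvectors.T @ modes.eigenvectors
        np.testing.assert_allclose(gram, np.eye(modes.n_modes), atol=1e-8)

    def test_needs_two_frames(self, ref_coords):
        with pytest.raises(ValueError):
            dm.pca_modes(dm.Trajectory(ref_coords[None]))


class TestRmsip:
    def _modeset(self, basis):
        d, k = basis.shape
        return ModeSet(basis, np.ones(k), np.zeros((d // 3, 3)))

    def test_identical_sets_give_one(self, ref_coords):
        rng = np.random.default_rng(7)
        frames = ref_coords[None] + rng.normal(0, 0.3, size=(30, *ref_coords.shape))
        modes = dm.pca_modes(dm.Trajectory(frames))
        assert dm.rmsip(modes, modes, k=10) == pytest.approx(1.0)

    def test_orthogonal_subspaces_give_zero(self):
        eye = np.eye(12)
        a = self._modeset(eye[:, :3])
        b = self._modeset(eye[:, 3:6])
        assert dm.rmsip(a, b, k=3) == 0.0

    def test_random_subspace_mean_matches_monte_carlo_oracle(self):
        """Seeded MC expectation for random k-subspaces of R^d (~0.309 at k=3, d=30)."""
        rng = np.random.default_rng(8)
        d, k = 30, 3
        values = []
        for _ in range(300):
            qa, _ = np.linalg.qr(rng.normal(size=(d, k)))
            qb, _ = np.linalg.qr(rng.normal(size=(d, k)))
            values.append(dm.rmsip(self._modeset(qa), self._modeset(qb), k=k))
        assert np.mean(values) == pytest.approx(0.309, abs=0.02)

    def test_k_validation(self):
        a = self._modeset(np.eye(9)[:, :2])
        with pytest.raises(ValueError):
            dm.rmsip(a, a, k=5)
        b = self._modeset(np.eye(12)[:, :2])
        with pytest.raises(ValueError):
            dm.rmsip(a, b, k=2)


class TestCosineContent:
    def test_planted_half_period_cosine_near_one(self):
        T = 200
        t = np.arange(T)
        assert dm.cosine_content(np.cos(np.pi * t / T), 1) > 0.99

    def test_full_period_cosine_orthogonal_to_first_mode(self):
        T = 200
        t = np.arange(T)
        assert dm.cosine_content(np.cos(2 * np.pi * t / T), 1) < 0.01

    def test_white_noise_mean_matches_monte_carlo_oracle(self):
        # expectation ~ 1/T for an i.i.d. series (seeded MC value)
        rng = np.random.default_rng(9)
        T = 100
        vals = [dm.cosine_content(rng.normal(size=T), 1) for _ in range(500)]
        assert np.mean(vals) == pytest.approx(1.0 / T, rel=0.35)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(10)
        for i in (1, 2, 5):
            for _ in range(50):
                c = dm.cosine_content(rng.normal(size=64), i)
                assert 0.0 <= c <= 1.0

    def test_degenerate_series_rejected(self):
        with pytest.raises(ValueError):
            dm.cosine_content(np.ones(50), 1)
        with pytest.raises(ValueError):
            dm.cosine_content(np.arange(3.0), 1)


class TestSplitHalfConvergence:
    def test_duplicated_half_gives_rmsip_one(self, ref_coords):
        rng = np.random.default_rng(11)
        half = ref_coords[None] + rng.normal(0, 0.3, size=(20, *ref_coords.shape))
        t = dm.Trajectory(np.concatenate([half, half]))
        value, _ = dm.split_half_convergence(t, k=5)
        assert value == pytest.approx(1.0, abs=1e-6)

    def test_low_rank_fluctuations_converge(self, ref_coords):
        """Strong planted low-rank covariance: halves share the essential subspace."""
        rng = np.random.default_rng(12)
        d = ref_coords.size
        basis, _ = np.linalg.qr(rng.normal(size=(d, 3)))
        sigmas = np.array([10.0, 8.0, 6.0])
        T = 200
        coeff = rng.normal(size=(T, 3)) * sigmas
        frames = (ref_coords.reshape(-1)[None]
                  + coeff @ basis.T
                  + rng.normal(0, 0.05, size=(T, d))).reshape(T, -1, 3)
        value, _ = dm.split_half_convergence(dm.Trajectory(frames), k=3)
        assert value > 0.95

    def test_pure_drift_has_cosine_content_near_one(self):
        ref = dm.make_toy_complex(0)
        spec = dm.TrajectorySpec(100, noise_sigma=0.05, drift_amplitude=3.0, seed=13)
        t = dm.generate_trajectory(ref, spec)
        _, cosines = dm.split_half_convergence(t, k=3)
        assert cosines[0] > 0.9


class TestTrajectoryIO:
    def test_xyz_roundtrip(self, tmp_path, ref_coords):
        rng = np.random.default_rng(14)
        t = dm.Trajectory(ref_coords[None] + rng.normal(0, 0.3, size=(5, *ref_coords.shape)))
        path = tmp_path / "frames.txt"
        dm.write_xyz_frames(t, str(path))
        t2 = dm.read_xyz_frames(str(path))
        assert t2.n_frames == 5 and t2.n_atoms == t.n_atoms
        np.testing.assert_allclose(t.frames, t2.frames, atol=1e-4)

    def test_multi_model_pdb_roundtrip(self, tmp_path):
        ref = dm.make_toy_complex(0)
        rng = np.random.default_rng(15)
        models = [ref]
        for _ in range(3):
            m = ref.copy()
            for res in m.residues():
                for atom in res.atoms:
                    atom.coord = atom.coord + rng.normal(0, 0.2, 3)
            models.append(m)
        path = tmp_path / "traj.pdb"
        dm.write_pdb_models(models, str(path))
        t = dm.trajectory_from_pdb(str(path), atom_class="calpha")
        assert t.n_frames == 4
        assert t.n_atoms == len(ref.residues())

    def test_projection_of_first_mode_recovers_drift(self):
        ref = dm.make_toy_complex(0)
        spec = dm.TrajectorySpec(80, noise_sigma=0.02, drift_amplitude=2.0, seed=16)
        t = dm.generate_trajectory(ref, spec)
        modes = dm.pca_modes(t)
        proj = project(t, modes, k=1)[:, 0]
        # half-period cosine: monotone-ish sweep from one extreme to the other
        assert dm.cosine_content(proj, 1) > 0.95
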