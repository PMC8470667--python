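"""Superposition, RMSF, MSD and gate-distance descriptors."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

import cypflex as cf
from cypflex.errors import AlignmentError, NotAlignedError, SelectionError


def quaternion_rmsd_oracle(mobile, reference):
    """Independent minimum-RMSD oracle: numeric minimisation over unit
    quaternions (rotation) with optimal translation folded in."""
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)

    def cost(qvec):
        q = qvec / np.linalg.norm(qvec)
        rot = Rotation.from_quat(q).as_matrix()
        return np.sqrt(np.mean(np.sum((mob_c @ rot.T - ref_c) ** 2, axis=1)))

    best = np.inf
    for s in range(8):  # multistart over quaternion space
        q0 = np.random.default_rng(s).normal(size=4)
        res = minimize(cost, q0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        best = min(best, res.fun)
    return best


class TestKabsch:
    def test_identical_sets(self):
        pts = np.random.default_rng(0).normal(size=(20, 3))
        res = cf.kabsch_superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-10)

    def test_recovers_applied_transform(self):
        pts = np.random.default_rng(1).normal(size=(30, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        mobile = pts @ rot.T + np.array([1.0, 2.0, 3.0])
        res = cf.kabsch_superpose(mobile, pts)
        assert res.rmsd <= 1e-8
        np.testing.assert_allclose(res.apply(mobile), pts, atol=1e-8)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_matches_quaternion_minimisation_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(50, 3))
        b = rng.normal(size=(50, 3))
        res = cf.kabsch_superpose(a, b)
        assert res.rmsd == pytest.approx(quaternion_rmsd_oracle(a, b), abs=1e-6)

    def test_rmsd_never_exceeds_unaligned(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.normal(size=(10, 3))
            b = rng.normal(size=(10, 3))
            raw = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
            assert cf.kabsch_superpose(a, b).rmsd <= raw + 1e-12

    def test_too_few_points(self):
        with pytest.raises(AlignmentError):
            cf.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_reference(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(AlignmentError):
            cf.kabsch_superpose(line + 0.1, line)


class TestAlignTrajectory:
    def test_frozen_is_fixed_point(self, frozen_trajectory):
        aligned = cf.align_trajectory(frozen_trajectory)
        np.testing.assert_allclose(aligned.frames, frozen_trajectory.frames,
                                   atol=1e-10)
        assert aligned.aligned

    def test_rigid_tumbling_collapses_to_one_structure(self):
        structure = cf.make_toy_structure(cf.ToyProteinSpec(n_residues=15))
        # non-collinear template so rotations are recoverable
        rng = np.random.default_rng(4)
        base = structure.coords + rng.normal(0, 2.0, structure.coords.shape)
        frames = []
        for k in range(8):
            rot = Rotation.random(random_state=k).as_matrix()
            frames.append(base @ rot.T + rng.normal(0, 5.0, 3))
        traj = cf.Trajectory(topology=structure, frames=np.array(frames), dt=1.0)
        aligned = cf.align_trajectory(traj)
        spread = aligned.frames.max(axis=0) - aligned.frames.min(axis=0)
        assert spread.max() < 1e-6

    def test_second_pass_does_not_increase_mean_rmsd(self):
        structure = cf.make_toy_structure(cf.ToyProteinSpec(n_residues=30))
        traj = cf.make_gaussian_trajectory(structure, 0.5, 200, seed=5)
        sel = cf.ResidueSelector(mode="calpha")
        idx = sel.resolve(structure)
        aligned = cf.align_trajectory(traj, sel)

        def mean_rmsd_to_mean(frames):
            mean = frames[:, idx].mean(axis=0)
            return np.mean(np.sqrt(np.mean(
                np.sum((frames[:, idx] - mean) ** 2, axis=2), axis=1)))

        # one-pass alignment to frame 0 only
        from cypflex.flexibility import _kabsch_batch

        rot, trans, _ = _kabsch_batch(traj.frames[:, idx], traj.frames[0, idx])
        pass1 = np.einsum("fij,fnj->fni", rot, traj.frames) + trans[:, None]
        assert mean_rmsd_to_mean(aligned.frames) <= mean_rmsd_to_mean(pass1) + 1e-12


class TestRmsf:
    def test_frozen_trajectory_zero(self, frozen_trajectory):
        aligned = cf.align_trajectory(frozen_trajectory)
        profile = cf.rmsf(aligned)
        np.testing.assert_allclose(profile.rmsf, 0.0, atol=1e-10)

    def test_unaligned_input_rejected(self, frozen_trajectory):
        with pytest.raises(NotAlignedError):
            cf.rmsf(frozen_trajectory)

    def test_gaussian_recovery_sigma_sqrt3(self):
        structure = cf.make_toy_structure(cf.ToyProteinSpec(n_residues=100))
        traj = cf.make_gaussian_trajectory(structure, 0.5, 5000, seed=6)
        profile = cf.rmsf(cf.align_trajectory(traj))
        expected = 0.5 * np.sqrt(3.0)  # 0.866 A
        assert profile.mean_rmsf == pytest.approx(expected, rel=0.05)
        assert np.all(np.abs(profile.rmsf - expected) / expected < 0.15)

    def test_sigma_ramp_gives_monotone_profile(self):
        n = 60
        sigma = np.linspace(0.1, 1.0, n)
        structure = cf.make_toy_structure(cf.ToyProteinSpec(n_residues=n))
        traj = cf.make_gaussian_trajectory(structure, sigma, 3000, seed=7)
        profile = cf.rmsf(cf.align_trajectory(traj))
        # monotone within noise: rank correlation essentially 1
        from scipy.stats import spearmanr

        rho = spearmanr(np.arange(n), profile.rmsf).statistic
        assert rho > 0.95

    def test_invariant_under_global_rigid_transform(self):
        structure = cf.make_toy_structure(cf.ToyProteinSpec(n_residues=40))
        traj = cf.make_gaussian_trajectory(structure, 0.4, 400, seed=8)
        rot = Rotation.from_euler("xyz", [10, 60, -40], degrees=True).as_matrix()
        moved = cf.Trajectory(topology=structure,
                              frames=traj.frames @ rot.T + np.array([5, -3, 2]),
                              dt=traj.dt)
        a = cf.rmsf(cf.align_trajectory(traj))
        b = cf.rmsf(cf.align_trajectory(moved))
        np.testing.assert_allclose(a.rmsf, b.rmsf, atol=1e-8)


class TestRmsfBySse:
    def _uniform_profile(self, n=20, value=1.0):
        residues = [("A", i + 1, "") for i in range(n)]
        return cf.FlexibilityProfile(residues=residues,
                                     rmsf=np.full(n, value))

    def test_uniform_profile_uniform_means(self):
        table = cf.rmsf_by_sse(self._uniform_profile(),
                               {"F": (1, 10), "G": (11, 20)})
        assert list(table["mean_rmsf"]) == [1.0, 1.0]

    def test_disjoint_halves(self):
        residues = [("A", i + 1, "") for i in range(20)]
        values = np.array([1.0] * 10 + [2.0] * 10)
        profile = cf.FlexibilityProfile(residues=residues, rmsf=values)
        table = cf.rmsf_by_sse(profile, {"lo": (1, 10), "hi": (11, 20)})
        assert list(table["mean_rmsf"]) == [1.0, 2.0]

    def test_overlap_warns_but_computes(self):
        with pytest.warns(UserWarning, match="overlap"):
            table = cf.rmsf_by_sse(self._uniform_profile(),
                                   {"a": (1, 12), "b": (8, 20)})
        assert len(table) == 2

    def test_empty_sse_names_element(self):
        with pytest.raises(SelectionError, match="ghost"):
            cf.rmsf_by_sse(self._uniform_profile(), {"ghost": (400, 420)})


class TestMsdCurve:
    def test_frozen_trajectory_zero(self, frozen_trajectory):
        aligned = cf.align_trajectory(frozen_trajectory)
        curve = cf.msd_curve(aligned, cf.ResidueSelector(mode="all"),
                             lags_ps=[10.0, 50.0])
        np.testing.assert_allclose(curve.msd, 0.0, atol=1e-12)
        assert curve.msd[0] == 0.0  # lag 0 present and exactly 0

    def test_iid_gaussian_plateau_at_6_sigma_sq(self):
        sigma = 0.5
        structure = cf.make_toy_structure(cf.ToyProteinSpec(n_residues=100))
        traj = cf.make_gaussian_trajectory(structure, sigma, 3000, seed=9)
        aligned = cf.align_trajectory(traj)
        curve = cf.msd_curve(aligned, cf.ResidueSelector(mode="all"),
                             lags_ps=[100.0, 1000.0, 5000.0])
        plateau = 6.0 * sigma**2
        np.testing.assert_allclose(curve.msd[1:], plateau, rtol=0.05)

    def test_ar1_curve_monotone_nondecreasing(self):
        structure = cf.make_toy_structure(cf.ToyProteinSpec(n_residues=60))
        traj = cf.make_gaussian_trajectory(structure, 0.6, 4000, seed=10,
                                           ar1=0.98)
        aligned = cf.align_trajectory(traj)
        curve = cf.msd_curve(aligned, cf.ResidueSelector(mode="all"))
        diffs = np.diff(curve.msd)
        # monotone within noise: tolerate tiny negative wiggles
        assert np.all(diffs > -0.02 * curve.msd.max())

    def test_incommensurate_lag_warns(self, frozen_trajectory):
        aligned = cf.align_trajectory(frozen_trajectory)
        with pytest.warns(UserWarning, match="rounded"):
            cf.msd_curve(aligned, cf.ResidueSelector(mode="all"), lags_ps=[15.0])

    def test_plateau_consistent_with_rmsf(self):
        structure = cf.make_toy_structure(cf.ToyProteinSpec(n_residues=100))
        traj = cf.make_gaussian_trajectory(structure, 0.4, 2000, seed=11)
        aligned = cf.align_trajectory(traj)
        profile = cf.rmsf(aligned, cf.ResidueSelector(mode="all"))
        curve = cf.msd_curve(aligned, cf.ResidueSelector(mode="all"),
                             lags_ps=[500.0])
        assert curve.msd[-1] == pytest.approx(2 * np.mean(profile.rmsf**2),
                                              rel=0.10)


class TestGateDistance:
    def test_fixed_atoms(self):
        traj = cf.Trajectory(
            topology=cf.make_toy_structure(cf.ToyProteinSpec(n_residues=4)),
            frames=np.repeat(
                cf.make_toy_structure(cf.ToyProteinSpec(n_residues=4)).coords[None],
                6, axis=0),
            dt=1.0)
        series = cf.gate_distance_series(traj, ("A", 1), ("A", 3))
        assert series.mean == pytest.approx(2 * 3.8)
        assert series.rms_fluctuation == 0.0

    def test_alternating_distances(self):
        structure = cf.make_toy_structure(cf.ToyProteinSpec(n_residues=2))
        n = 2000
        frames = np.repeat(structure.coords[None], n, axis=0)
        # atom of residue 2 alternates between 9 and 11 A from residue 1
        frames[::2, 1, 0] = 9.0
        frames[1::2, 1, 0] = 11.0
        frames[:, 1, 1:] = 0.0
        frames[:, 0] = 0.0
        traj = cf.Trajectory(topology=structure, frames=frames, dt=1.0)
        series = cf.gate_distance_series(traj, ("A", 1), ("A", 2))
        assert series.mean == pytest.approx(10.0)
        assert series.rms_fluctuation == pytest.approx(1.0, rel=1e-3)

    def test_programmed_gate_sigma_recovered(self):
        structure = cf.make_toy_structure(cf.ToyProteinSpec(n_residues=30))
        sigma_gate = 0.8 / np.sqrt(2.0)  # distance sd = sigma * sqrt(2)
        sigma = np.zeros(30)
        sigma[[4, 24]] = sigma_gate
        traj = cf.make_gaussian_trajectory(structure, sigma, 5000, seed=12)
        series = cf.gate_distance_series(traj, ("A", 5), ("A", 25))
        assert series.rms_fluctuation == pytest.approx(0.8, rel=0.05)

    def test_missing_residue_named(self, frozen_trajectory):
        with pytest.raises(SelectionError, match="99"):
            cf.gate_distance_series(frozen_trajectory, ("A", 1), ("A", 99))
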