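"""Centers, CCDs, superposition, RMSD series/matrices, and helix tilt."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from trajcouple import (
    Selection,
    ccd_series,
    geometric_center,
    helix_tilt_series,
    kabsch_superpose,
    pairwise_rmsd_matrix,
    rmsd,
    rmsd_series,
)
from trajcouple.errors import DegenerateFitError, DimensionError

from conftest import all_atoms, bead_trajectory, random_rotation


class TestGeometricCenter:
    def test_midpoint(self):
        traj = bead_trajectory([[[0, 0, 0], [2, 0, 0]]])
        np.testing.assert_allclose(geometric_center(traj, 0, all_atoms(traj)), [1, 0, 0])

    def test_single_atom_identity(self):
        traj = bead_trajectory([[[1.5, -2.0, 3.0]]])
        np.testing.assert_allclose(geometric_center(traj, 0, all_atoms(traj)), [1.5, -2.0, 3.0])

    def test_unit_square(self):
        traj = bead_trajectory([[[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]]])
        np.testing.assert_allclose(geometric_center(traj, 0, all_atoms(traj)), [0.5, 0.5, 0])


class TestCcdSeries:
    def test_three_four_five(self):
        coords = np.array([[[0, 0, 0], [3, 4, 0]]] * 5, dtype=float)
        traj = bead_trajectory(coords)
        a = Selection("a", np.array([0]))
        b = Selection("b", np.array([1]))
        np.testing.assert_allclose(ccd_series(traj, a, b).values, 5.0)

    def test_self_distance_zero(self):
        traj = bead_trajectory(np.random.default_rng(0).normal(size=(3, 4, 3)))
        sel = all_atoms(traj)
        np.testing.assert_allclose(ccd_series(traj, sel, sel).values, 0.0)

    def test_planted_separation_schedule(self):
        # two single-bead "domains" at planted separations 60 then 30 Å
        coords = np.zeros((2, 2, 3))
        coords[0, 1, 0] = 60.0
        coords[1, 1, 0] = 30.0
        traj = bead_trajectory(coords)
        s = ccd_series(traj, Selection("a", np.array([0])), Selection("b", np.array([1])))
        np.testing.assert_allclose(s.values, [60.0, 30.0])

    def test_rigid_invariance(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(4, 6, 3))
        R = random_rotation(rng)
        shifted = coords @ R.T + np.array([3.0, -1.0, 2.0])
        a = Selection("a", np.arange(3))
        b = Selection("b", np.arange(3, 6))
        s1 = ccd_series(bead_trajectory(coords), a, b).values
        s2 = ccd_series(bead_trajectory(shifted), a, b).values
        np.testing.assert_allclose(s1, s2, atol=1e-10)


class TestKabsch:
    def test_identity(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(8, 3))
        R, t, fitted = kabsch_superpose(coords, coords)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(t, 0.0, atol=1e-10)
        assert rmsd(fitted, coords) < 1e-10

    def test_exact_rigid_recovery(self):
        rng = np.random.default_rng(4)
        ref = rng.normal(size=(10, 3))
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        mobile = ref @ Rz.T + np.array([1.0, 1.0, 1.0])
        _, _, fitted = kabsch_superpose(mobile, ref)
        assert rmsd(fitted, ref) <= 1e-8

    def test_optimality_vs_rotation_sampling(self):
        # our fit must beat (or match) the best of 20k random rotations
        rng = np.random.default_rng(5)
        ref = rng.normal(size=(10, 3))
        mobile = ref + rng.normal(scale=0.3, size=ref.shape)
        _, _, fitted = kabsch_superpose(mobile, ref)
        ours = rmsd(fitted, ref)
        mc = mobile - mobile.mean(axis=0)
        rc = ref - ref.mean(axis=0)
        best = np.inf
        for R in Rotation.random(20000, random_state=6).as_matrix():
            best = min(best, rmsd(mc @ R.T, rc))
        assert ours <= best + 1e-9

    def test_agrees_with_scipy_align_vectors(self):
        rng = np.random.default_rng(7)
        ref = rng.normal(size=(12, 3))
        mobile = ref @ random_rotation(rng).T + rng.normal(scale=0.2, size=ref.shape)
        R, _, _ = kabsch_superpose(mobile, ref)
        rot, _ = Rotation.align_vectors(ref - ref.mean(0), mobile - mobile.mean(0))
        np.testing.assert_allclose(R, rot.as_matrix(), atol=1e-8)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_collinear_and_tiny_fit_sets_fail(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(DegenerateFitError):
            kabsch_superpose(line, line)
        with pytest.raises(DegenerateFitError):
            kabsch_superpose(line[:2], line[:2])


class TestRmsd:
    def test_identical_zero(self):
        c = np.random.default_rng(8).normal(size=(5, 3))
        assert rmsd(c, c) == 0.0

    def test_uniform_shift(self):
        c = np.random.default_rng(9).normal(size=(7, 3))
        assert rmsd(c, c + [2.0, 0, 0]) == pytest.approx(2.0)

    def test_hand_arithmetic(self):
        a = np.zeros((2, 3))
        b = np.array([[1.0, 0, 0], [3.0, 0, 0]])
        assert rmsd(a, b) == pytest.approx(np.sqrt((1 + 9) / 2), abs=1e-4)
        assert rmsd(a, b) == pytest.approx(2.2361, abs=1e-4)

    def test_shape_mismatch(self):
        with pytest.raises(DimensionError):
            rmsd(np.zeros((2, 3)), np.zeros((3, 3)))


class TestRmsdSeries:
    def test_static_all_zero(self):
        coords = np.repeat(np.random.default_rng(10).normal(size=(1, 6, 3)), 4, axis=0)
        traj = bead_trajectory(coords)
        sel = all_atoms(traj)
        np.testing.assert_allclose(rmsd_series(traj, 0, sel, sel).values, 0.0, atol=1e-10)

    def test_rigid_motion_invisible_after_alignment(self):
        rng = np.random.default_rng(11)
        base = rng.normal(size=(6, 3))
        frames = []
        for _ in range(5):
            frames.append(base @ random_rotation(rng).T + rng.normal(size=3))
        traj = bead_trajectory(np.array(frames))
        sel = all_atoms(traj)
        np.testing.assert_allclose(rmsd_series(traj, 0, sel, sel).values, 0.0, atol=1e-8)

    def test_two_pose_alternation(self):
        rng = np.random.default_rng(12)
        pose0 = rng.normal(size=(5, 3))
        shift = rng.normal(size=(5, 3))
        shift -= shift.mean(axis=0)
        shift *= 3.0 / np.sqrt(np.mean(np.sum(shift**2, axis=1)))  # 3 Å apart, centered
        pose1 = pose0 + shift
        # receptor anchor stays fixed so the alignment is pinned
        anchor = rng.normal(size=(6, 3)) * 5
        frames = []
        for i in range(6):
            lig = pose0 if i % 2 == 0 else pose1
            frames.append(np.vstack([anchor, lig]))
        traj = bead_trajectory(np.array(frames))
        align = Selection("anchor", np.arange(6))
        lig_sel = Selection("lig", np.arange(6, 11))
        vals = rmsd_series(traj, 0, align, lig_sel).values
        np.testing.assert_allclose(vals, [0, 3, 0, 3, 0, 3], atol=1e-8)


class TestPairwiseMatrix:
    def test_identical_frames_zero_matrix(self):
        coords = np.repeat(np.random.default_rng(13).normal(size=(1, 5, 3)), 3, axis=0)
        traj = bead_trajectory(coords)
        sel = all_atoms(traj)
        np.testing.assert_allclose(pairwise_rmsd_matrix(traj, sel, sel), 0.0, atol=1e-10)

    def test_block_structure(self):
        rng = np.random.default_rng(14)
        A = rng.normal(size=(5, 3))
        shift = rng.normal(size=(5, 3))
        shift -= shift.mean(axis=0)
        d = 2.5
        shift *= d / np.sqrt(np.mean(np.sum(shift**2, axis=1)))
        anchor = rng.normal(size=(6, 3)) * 4
        frames = np.array([np.vstack([anchor, A]), np.vstack([anchor, A]), np.vstack([anchor, A + shift])])
        traj = bead_trajectory(frames)
        align = Selection("anchor", np.arange(6))
        meas = Selection("m", np.arange(6, 11))
        M = pairwise_rmsd_matrix(traj, align, meas)
        assert M[0, 1] == pytest.approx(0.0, abs=1e-9)
        assert M[0, 2] == pytest.approx(d, abs=1e-8)
        assert M[1, 2] == pytest.approx(d, abs=1e-8)

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(15)
        traj = bead_trajectory(rng.normal(size=(8, 6, 3)))
        sel = all_atoms(traj)
        M = pairwise_rmsd_matrix(traj, sel, sel)
        np.testing.assert_allclose(M, M.T, atol=1e-10)
        np.testing.assert_allclose(np.diag(M), 0.0)
        assert np.all(M >= 0)


class TestHelixTilt:
    @staticmethod
    def rod(n=10, axis=(0, 0, 1.0)):
        axis = np.asarray(axis, dtype=float)
        return np.outer(np.arange(n, dtype=float) * 1.5, axis / np.linalg.norm(axis))

    def test_static_zero(self):
        coords = np.repeat(self.rod()[None], 3, axis=0)
        traj = bead_trajectory(coords)
        np.testing.assert_allclose(helix_tilt_series(traj, all_atoms(traj), 0).angle_deg, 0.0, atol=1e-9)

    def test_orthogonal_axes(self):
        coords = np.stack([self.rod(axis=(0, 0, 1)), self.rod(axis=(1, 0, 0))])
        traj = bead_trajectory(coords)
        angles = helix_tilt_series(traj, all_atoms(traj), 0).angle_deg
        assert angles[1] == pytest.approx(90.0, abs=1e-8)

    @pytest.mark.parametrize("deg", [30.0, 120.0, 175.0])
    def test_constructed_rotation(self, deg):
        R = Rotation.from_euler("y", deg, degrees=True).as_matrix()
        coords = np.stack([self.rod(), self.rod() @ R.T])
        traj = bead_trajectory(coords)
        angles = helix_tilt_series(traj, all_atoms(traj), 0).angle_deg
        assert angles[1] == pytest.approx(deg, abs=1e-6)
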