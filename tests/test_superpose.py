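"""Kabsch superposition, RMSD series, and RMSF profiles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mdinteract import (
    Atom,
    Frame,
    GeometryError,
    Residue,
    Trajectory,
    kabsch_superpose,
    rmsd_series,
    rmsf,
)

RNG = np.random.default_rng(2024)


def random_structure(n=12):
    return RNG.normal(0.0, 5.0, size=(n, 3))


def apply_rigid(coords, rotation, translation):
    return coords @ rotation.T + translation


def brute_force_rmsd(mobile, reference, depth=3):
    """Independent oracle: nested grid search over Euler-angle rotations.

    Coarse 15-degree sweep refined twice around the best cell; translation
    handled by centering.  No SVD anywhere.
    """
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)
    n = mob.shape[0]

    def rmsd_for(angles):
        rot = Rotation.from_euler("zyx", angles, degrees=True).as_matrix()
        return np.sqrt(np.sum((mob @ rot.T - ref) ** 2) / n)

    best_angles, best = np.zeros(3), np.inf
    span, step = 180.0, 15.0
    for _ in range(depth + 1):
        grid = [
            (a, b, c)
            for a in np.arange(best_angles[0] - span, best_angles[0] + span + 1e-9, step)
            for b in np.arange(best_angles[1] - span, best_angles[1] + span + 1e-9, step)
            for c in np.arange(best_angles[2] - span, best_angles[2] + span + 1e-9, step)
        ]
        for angles in grid:
            val = rmsd_for(angles)
            if val < best:
                best, best_angles = val, np.array(angles)
        span, step = step, step / 10.0
    return best


class TestKabsch:
    def test_self_superposition_is_zero(self):
        coords = random_structure()
        _, _, rmsd = kabsch_superpose(coords, coords)
        assert rmsd <= 1e-10

    @pytest.mark.parametrize("seed", range(5))
    def test_rigid_copies_superpose_exactly(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.normal(0.0, 4.0, size=(10, 3))
        rot = Rotation.random(rng=rng).as_matrix()
        moved = apply_rigid(coords, rot, rng.normal(0, 20, 3))
        rotation, translation, rmsd = kabsch_superpose(moved, coords)
        assert rmsd <= 1e-8
        assert np.isclose(np.linalg.det(rotation), 1.0)
        np.testing.assert_allclose(apply_rigid(moved, rotation, translation), coords, atol=1e-7)

    def test_matches_brute_force_grid_oracle(self):
        """4-point toy, one point displaced: optimum equals grid search."""
        reference = np.array(
            [[0.0, 0.0, 0.0], [3.0, 0.0, 0.0], [0.0, 3.0, 0.0], [0.0, 0.0, 3.0]]
        )
        mobile = reference.copy()
        mobile[3] += np.array([0.0, 0.0, 2.0])  # 2 Å displacement
        rot = Rotation.from_euler("zyx", [25, -40, 60], degrees=True).as_matrix()
        mobile = apply_rigid(mobile, rot, np.array([5.0, -3.0, 1.0]))
        _, _, rmsd = kabsch_superpose(mobile, reference)
        assert rmsd == pytest.approx(brute_force_rmsd(mobile, reference), abs=1e-3)

    def test_symmetry(self):
        a, b = random_structure(), random_structure()
        assert kabsch_superpose(a, b)[2] == pytest.approx(kabsch_superpose(b, a)[2], abs=1e-9)

    def test_invariance_under_rigid_transform_of_either_input(self):
        a, b = random_structure(), random_structure()
        base = kabsch_superpose(a, b)[2]
        rot = Rotation.random(rng=RNG).as_matrix()
        assert kabsch_superpose(apply_rigid(a, rot, [1, 2, 3]), b)[2] == pytest.approx(base, abs=1e-8)
        assert kabsch_superpose(a, apply_rigid(b, rot, [-4, 0, 9]))[2] == pytest.approx(base, abs=1e-8)

    def test_too_few_or_collinear_points_rejected(self):
        with pytest.raises(GeometryError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[float(i), 0.0, 0.0] for i in range(5)])
        with pytest.raises(GeometryError):
            kabsch_superpose(line, line)


def traj_from_coords(frames_coords, chain_id="A"):
    """Build a Cα trajectory from an (n_frames, n_res, 3) array."""
    frames = []
    for k, coords in enumerate(frames_coords):
        chain = [
            Residue(i + 1, "ALA", chain_id, [Atom("CA", "C", xyz)])
            for i, xyz in enumerate(coords)
        ]
        frames.append(Frame(chains=[chain], time=10.0 * k))
    return Trajectory(frames=frames)


@pytest.fixture()
def base_coords():
    rng = np.random.default_rng(7)
    return rng.normal(0.0, 5.0, size=(15, 3))


class TestRmsdSeries:
    def test_static_trajectory_is_all_zero(self, base_coords):
        traj = traj_from_coords([base_coords] * 4)
        series = rmsd_series(traj)
        np.testing.assert_allclose(series.values, 0.0, atol=1e-10)

    def test_translated_frame_scores_zero(self, base_coords):
        traj = traj_from_coords([base_coords, base_coords + np.array([3.0, -8.0, 1.0])])
        series = rmsd_series(traj, reference_frame=0)
        assert series.values[1] <= 1e-10

    def test_agrees_with_per_frame_superposition(self, base_coords):
        rng = np.random.default_rng(3)
        frames = [base_coords, base_coords + rng.normal(0, 1.0, base_coords.shape)]
        traj = traj_from_coords(frames)
        series = rmsd_series(traj, reference_frame=0)
        expected = kabsch_superpose(frames[1], frames[0])[2]
        assert series.values[1] == pytest.approx(expected, abs=1e-12)

    def test_bad_reference_index(self, base_coords):
        traj = traj_from_coords([base_coords] * 2)
        with pytest.raises(IndexError):
            rmsd_series(traj, reference_frame=5)


class TestRmsf:
    def test_static_trajectory_rmsf_zero(self, base_coords):
        # Quarter-unit coordinates keep frame averaging exact in binary.
        coords = np.round(base_coords * 4) / 4
        traj = traj_from_coords([coords] * 10)
        profile = rmsf(traj)
        assert np.all(profile.values == 0.0)

    def test_two_state_oscillation_closed_form(self):
        """Two residues oscillating ±d along the axis through them.

        Placed on the z-axis and moving along z in opposite directions, the
        oscillation induces no net translation or rotation, so the optimal
        superposition is the identity and each oscillating residue's RMSF is
        exactly d (two-state variance d²); all other residues stay at 0.
        """
        d = 0.3
        rng = np.random.default_rng(11)
        base = rng.normal(0.0, 5.0, size=(12, 3))
        base[0] = [0.0, 0.0, 6.0]
        base[1] = [0.0, 0.0, -6.0]
        up, down = base.copy(), base.copy()
        up[0, 2] += d
        up[1, 2] -= d
        down[0, 2] -= d
        down[1, 2] += d
        traj = traj_from_coords([up, down, up, down])
        profile = rmsf(traj)
        assert profile.values[0] == pytest.approx(d, abs=1e-9)
        assert profile.values[1] == pytest.approx(d, abs=1e-9)
        np.testing.assert_allclose(profile.values[2:], 0.0, atol=1e-9)

    def test_invariant_to_global_rigid_transform(self, base_coords):
        rng = np.random.default_rng(5)
        frames = [base_coords + rng.normal(0, 0.5, base_coords.shape) for _ in range(6)]
        rot = Rotation.random(rng=rng).as_matrix()
        moved = [apply_rigid(f, rot, np.array([10.0, -4.0, 2.0])) for f in frames]
        np.testing.assert_allclose(
            rmsf(traj_from_coords(frames)).values,
            rmsf(traj_from_coords(moved)).values,
            atol=1e-8,
        )

    def test_invariant_to_frame_reordering(self, base_coords):
        rng = np.random.default_rng(9)
        frames = [base_coords + rng.normal(0, 0.5, base_coords.shape) for _ in range(6)]
        np.testing.assert_allclose(
            rmsf(traj_from_coords(frames)).values,
            rmsf(traj_from_coords(frames[::-1])).values,
            atol=1e-6,
        )

    def test_needs_two_frames(self, base_coords):
        with pytest.raises(ValueError):
            rmsf(traj_from_coords([base_coords]))
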