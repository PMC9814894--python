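"""Guest motion: averaging, gyration shape, classification, torsions."""

import numpy as np
import pytest

from cagekit import (Conformation, GyrationTensorSummary, MotionClass,
                     ShapeClass, ShapeThresholds, average_guest_structure,
                     characterize_guest, classify_shape, dihedral,
                     infer_motion, max_dimension, orientation_angle)
from cagekit.geometry import relative_shape_anisotropy
from cagekit.guest import DegenerateLongAxisError, host_axial_axis
from cagekit.synthetic import (CANONICAL_GUESTS, FixtureConfig,
                               make_rotation_trajectory, random_rotation,
                               rod_guest)


def conf_of(coords, elements=None):
    coords = np.asarray(coords, float)
    n = len(coords)
    elements = elements or ["C"] * n
    return Conformation(coords, [f"G{i}" for i in range(n)], elements,
                        np.zeros(n, dtype=int))


class TestAverageGuestStructure:
    def test_static_guest_average_is_instantaneous(self):
        cfg = FixtureConfig(seed=0, n_frames=1, noise_sd=0.0)
        traj, truth = make_rotation_trajectory(cfg=cfg)
        avg = average_guest_structure(traj, truth.host_indices,
                                      truth.guest_indices)
        assert np.allclose(avg.coords, traj.coords[0][truth.guest_indices],
                           atol=1e-10)

    def test_axial_spin_collapses_to_rod(self):
        cfg = FixtureConfig(seed=1, n_frames=720, rotation_mode="axial",
                            noise_sd=0.0)
        traj, truth = make_rotation_trajectory(rod_guest(7.2), cfg)
        avg = average_guest_structure(traj, truth.host_indices,
                                      truth.guest_indices)
        g = GyrationTensorSummary.from_coords(avg.coords)
        assert g.kappa2 > 0.7  # off-axis atoms collapse toward the axis

    def test_isotropic_rotation_collapses_to_ball(self):
        """10^4 uniform rotations average to an isotropic point cloud."""
        cfg = FixtureConfig(seed=2, n_frames=10000, rotation_mode="isotropic",
                            noise_sd=0.0)
        traj, truth = make_rotation_trajectory(rod_guest(5.0), cfg)
        avg = average_guest_structure(traj, truth.host_indices,
                                      truth.guest_indices)
        g = GyrationTensorSummary.from_coords(avg.coords)
        assert g.kappa2 < 0.1

    def test_commutes_with_global_rigid_motion(self):
        cfg = FixtureConfig(seed=3, n_frames=48, rotation_mode="axial")
        traj, truth = make_rotation_trajectory(cfg=cfg)
        rng = np.random.default_rng(5)
        r = random_rotation(rng)
        t = np.array([3.0, -2.0, 8.0])
        moved = traj.with_coords(traj.coords @ r.T + t)
        a = average_guest_structure(traj, truth.host_indices,
                                    truth.guest_indices)
        b = average_guest_structure(moved, truth.host_indices,
                                    truth.guest_indices)
        assert np.allclose(a.coords @ r.T + t, b.coords, atol=1e-8)

    def test_overlapping_selections_rejected(self):
        cfg = FixtureConfig(seed=4, n_frames=2)
        traj, truth = make_rotation_trajectory(cfg=cfg)
        with pytest.raises(ValueError, match="overlap"):
            average_guest_structure(traj, truth.host_indices,
                                    truth.host_indices[:3])


class TestShapeClassification:
    def test_low_kappa_is_ball(self):
        g = GyrationTensorSummary(np.array([1.0, 0.98, 0.96]),
                                  asphericity=0.03, kappa2=0.02)
        assert classify_shape(g, length=4.0) is ShapeClass.BALL

    def test_axial_averaging_gives_long_rod(self):
        cfg = FixtureConfig(seed=5, n_frames=1000, rotation_mode="axial")
        traj, truth = make_rotation_trajectory(cfg=cfg)
        s = characterize_guest(traj, truth.host_indices, truth.guest_indices)
        assert s.shape is ShapeClass.LONG_ROD
        assert s.motion is MotionClass.AXIAL_SPIN

    def test_mixed_averaging_gives_short_rod(self):
        """Dominant axial spin with ~1-in-10 equatorial flips shortens the
        averaged rod below the long-rod cut."""
        cfg = FixtureConfig(seed=6, n_frames=1000, rotation_mode="mixed",
                            mixed_ratio=0.1)
        traj, truth = make_rotation_trajectory(cfg=cfg)
        s = characterize_guest(traj, truth.host_indices, truth.guest_indices)
        assert s.shape is ShapeClass.SHORT_ROD
        assert s.motion is MotionClass.PARTIALLY_FREE_SPIN

    def test_motion_mapping_total_and_deterministic(self):
        assert infer_motion(ShapeClass.BALL) is MotionClass.FREE_SPIN
        assert infer_motion(ShapeClass.SHORT_ROD) is MotionClass.PARTIALLY_FREE_SPIN
        assert infer_motion(ShapeClass.LONG_ROD) is MotionClass.AXIAL_SPIN

    def test_kappa2_invariant_under_rigid_motion_and_scale(self):
        rng = np.random.default_rng(7)
        coords = rng.normal(size=(15, 3))
        g0 = GyrationTensorSummary.from_coords(coords)
        moved = 3.7 * (coords @ random_rotation(rng).T) + [1.0, 2.0, 3.0]
        g1 = GyrationTensorSummary.from_coords(moved)
        assert g1.kappa2 == pytest.approx(g0.kappa2, abs=1e-10)

    def test_kappa2_limits(self):
        line = np.stack([np.linspace(-3, 3, 10)] + [np.zeros(10)] * 2, axis=1)
        assert relative_shape_anisotropy(
            GyrationTensorSummary.from_coords(line).eigenvalues) == pytest.approx(1.0)


class TestMaxDimension:
    def test_two_atoms_with_and_without_vdw(self):
        conf = conf_of([[0, 0, 0], [3, 0, 0]], ["C", "O"])
        assert max_dimension(conf) == pytest.approx(3.0)
        from cagekit.elements import vdw_radius
        assert max_dimension(conf, include_vdw=True) == pytest.approx(
            3.0 + vdw_radius("C") + vdw_radius("O"))

    def test_equilateral_triangle(self):
        conf = conf_of([[0, 0, 0], [2, 0, 0], [1, np.sqrt(3), 0]])
        assert max_dimension(conf) == pytest.approx(2.0)

    def test_matches_double_loop_on_random_clouds(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            coords = rng.normal(scale=3.0, size=(50, 3))
            expected = max(np.linalg.norm(coords[i] - coords[j])
                           for i in range(50) for j in range(i + 1, 50))
            assert max_dimension(conf_of(coords)) == pytest.approx(expected)

    def test_single_atom_rejected(self):
        with pytest.raises(ValueError, match="2 atoms"):
            max_dimension(conf_of([[0, 0, 0]]))


class TestOrientation:
    def test_aligned_rod_zero_degrees(self):
        rod = rod_guest(6.0)
        assert orientation_angle(rod, [0, 0, 1]) == pytest.approx(0.0, abs=1.0)

    def test_perpendicular_rod_ninety_degrees(self):
        rod = rod_guest(6.0)
        assert orientation_angle(rod, [1, 0, 0]) == pytest.approx(90.0, abs=1.0)

    def test_thirty_degree_fixture(self):
        # a pure line tilted 30 degrees from z in the xz-plane
        t = np.linspace(-3, 3, 12)
        axis = np.array([np.sin(np.radians(30)), 0.0, np.cos(np.radians(30))])
        coords = t[:, None] * axis[None, :]
        assert orientation_angle(coords, [0, 0, 1]) == pytest.approx(
            30.0, abs=1e-6)

    def test_degenerate_long_axis_flagged(self):
        ring = np.stack([np.cos(np.linspace(0, 2 * np.pi, 8, endpoint=False)),
                         np.sin(np.linspace(0, 2 * np.pi, 8, endpoint=False)),
                         np.zeros(8)], axis=1)
        with pytest.raises(DegenerateLongAxisError):
            orientation_angle(ring, [0, 0, 1])

    def test_host_axis_of_synthetic_cage_is_z(self):
        from cagekit.synthetic import cavity_selection, make_cage
        conf, top = make_cage()
        axis = host_axial_axis(conf.coords[cavity_selection(top)])
        assert abs(abs(axis[2]) - 1.0) < 1e-6


class TestDihedral:
    def test_planar_trans_is_180(self):
        ang = dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0])
        assert abs(ang) == pytest.approx(180.0)

    def test_planar_cis_is_zero(self):
        ang = dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0])
        assert ang == pytest.approx(0.0, abs=1e-10)

    def test_constructed_sixty_degree_gauche(self):
        # rotate the far bond 60 degrees about the central x-axis bond
        theta = np.radians(60.0)
        p3 = np.array([1.0, np.cos(theta), np.sin(theta)])
        ang = dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], p3)
        assert abs(ang) == pytest.approx(60.0, abs=1e-8)

    def test_sign_flips_under_mirror(self):
        pts = [np.array([0.0, 1.0, 0.2]), np.zeros(3),
               np.array([1.0, 0.0, 0.0]), np.array([1.3, -0.8, 0.7])]
        a = dihedral(*pts)
        mirrored = [p * np.array([1.0, 1.0, -1.0]) for p in pts]
        assert dihedral(*mirrored) == pytest.approx(-a, abs=1e-10)

    def test_collinear_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])


class TestPipeline:
    @pytest.mark.parametrize("mode,shape,motion", [
        ("axial", ShapeClass.LONG_ROD, MotionClass.AXIAL_SPIN),
        ("isotropic", ShapeClass.BALL, MotionClass.FREE_SPIN),
        ("mixed", ShapeClass.SHORT_ROD, MotionClass.PARTIALLY_FREE_SPIN),
    ])
    @pytest.mark.parametrize("seed", [0, 7, 13])
    def test_canonical_modes_classified_correctly(self, mode, shape, motion,
                                                  seed):
        cfg = FixtureConfig(seed=seed, n_frames=1000, rotation_mode=mode)
        traj, truth = make_rotation_trajectory(cfg=cfg)
        s = characterize_guest(traj, truth.host_indices, truth.guest_indices)
        assert s.shape is shape
        assert s.motion is motion
        if shape is not ShapeClass.BALL:
            assert 0.0 <= s.orientation_deg <= 90.0
            assert s.orientation_deg < 10.0  # rod stays near the axial axis
        g = CANONICAL_GUESTS[mode]()
        assert s.mdg == pytest.approx(max_dimension(g), abs=0.3)
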