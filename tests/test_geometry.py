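"""Rotation conventions, cylinder fitting, tube frame, unrolling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

import coatlattice as cl
from coatlattice.errors import (
    FitDegenerateError,
    InvalidAngleError,
    InvalidRotationError,
    UnmappableParticleError,
)

from conftest import axis_angle_matrix, geodesic_angle, random_rotation_matrices

EZ = np.array([0.0, 0.0, 1.0])
EY = np.array([0.0, 1.0, 0.0])


class TestEulerMatrix:
    def test_identity(self):
        assert np.allclose(cl.euler_to_matrix((0, 0, 0)), np.eye(3))

    def test_tilt_zero_gimbal_degeneracy(self):
        # at tilt = 0 the rot and psi rotations share an axis
        assert np.allclose(
            cl.euler_to_matrix((90, 0, 0)), cl.euler_to_matrix((0, 0, 90))
        )

    def test_matches_axis_angle_oracle(self):
        g = np.random.default_rng(7)
        for _ in range(100):
            rot, tilt, psi = g.uniform(-180, 180), g.uniform(0, 180), g.uniform(-180, 180)
            expected = (
                axis_angle_matrix(EZ, np.deg2rad(rot))
                @ axis_angle_matrix(EY, np.deg2rad(tilt))
                @ axis_angle_matrix(EZ, np.deg2rad(psi))
            )
            R = cl.euler_to_matrix((rot, tilt, psi))
            assert np.max(np.abs(R - expected)) < 1e-12
            assert abs(np.linalg.det(R) - 1.0) < 1e-12

    def test_matches_scipy_convention(self):
        g = np.random.default_rng(8)
        e = np.column_stack(
            [g.uniform(-179, 179, 20), g.uniform(1, 179, 20), g.uniform(-179, 179, 20)]
        )
        ours = cl.eulers_to_matrices(e)
        ref = Rotation.from_euler("ZYZ", e, degrees=True).as_matrix()
        assert np.max(np.abs(ours - ref)) < 1e-12

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidAngleError):
            cl.euler_to_matrix((np.nan, 0, 0))


class TestMatrixEuler:
    def test_identity_tie_break(self):
        assert cl.matrix_to_euler(np.eye(3)) == (0.0, 0.0, 0.0)

    def test_tilt_180_tie_break(self):
        assert cl.matrix_to_euler(axis_angle_matrix(EY, np.pi)) == pytest.approx(
            (0.0, 180.0, 0.0)
        )

    def test_round_trip_geodesic(self):
        for R in random_rotation_matrices(1000, seed=3):
            back = cl.euler_to_matrix(cl.matrix_to_euler(R))
            assert geodesic_angle(R, back) < 1e-9

    def test_canonical_ranges(self):
        for R in random_rotation_matrices(200, seed=4):
            rot, tilt, psi = cl.matrix_to_euler(R)
            assert 0.0 <= tilt <= 180.0
            assert -180.0 < rot <= 180.0
            assert -180.0 < psi <= 180.0

    def test_near_gimbal_round_trip(self):
        for tilt in (1e-7, 180 - 1e-7):
            R = cl.euler_to_matrix((35.0, tilt, -120.0))
            back = cl.euler_to_matrix(cl.matrix_to_euler(R))
            assert geodesic_angle(R, back) < 1e-9

    def test_non_orthonormal_rejected(self):
        with pytest.raises(InvalidRotationError):
            cl.matrix_to_euler(np.eye(3) * 1.1)
        with pytest.raises(InvalidRotationError):
            cl.matrix_to_euler(np.diag([1.0, 1.0, -1.0]))  # improper


class TestRelativePose:
    @staticmethod
    def _pose(pid, pos, euler):
        return cl.Pose(particle_id=pid, position=np.asarray(pos, float), euler_deg=euler)

    def test_self_is_identity(self):
        a = self._pose(0, (10, -5, 3), (30, 40, 50))
        d, rel = cl.relative_pose(a, a)
        assert np.allclose(d, 0) and np.allclose(rel, np.eye(3))

    def test_translation_along_body_x(self):
        a = self._pose(0, (0, 0, 0), (30, 60, -45))
        b = self._pose(1, a.position + 10.0 * a.rotation[:, 0], (30, 60, -45))
        d, rel = cl.relative_pose(a, b)
        assert np.allclose(d, [10, 0, 0], atol=1e-12)
        assert np.allclose(rel, np.eye(3))

    def test_forward_apply_oracle(self):
        g = np.random.default_rng(11)
        for _ in range(50):
            a = self._pose(0, g.normal(size=3) * 100, tuple(g.uniform(-90, 90, 3)))
            b = self._pose(1, g.normal(size=3) * 100, tuple(g.uniform(-90, 90, 3)))
            d, rel = cl.relative_pose(a, b)
            # invert: recover b's position and orientation from a's pose
            pos_b = a.position + a.rotation @ d
            R_b = a.rotation @ rel
            assert np.linalg.norm(pos_b - b.position) < 1e-9
            assert np.max(np.abs(R_b - b.rotation)) < 1e-9


def _cylinder_points(radius=200.0, n=64, turns=3.0, length=400.0, seed=None):
    """Exact points on a +z cylinder, spread helically for axial coverage."""
    t = np.linspace(0, 2 * np.pi * turns, n)
    z = np.linspace(0, length, n)
    pts = np.stack([radius * np.cos(t), radius * np.sin(t), z], axis=1)
    if seed is not None:
        pts = pts + np.random.default_rng(seed).normal(0, 3.0, pts.shape)
    return pts


class TestFitCylinder:
    def test_exact_points(self):
        fit = cl.fit_cylinder(_cylinder_points())
        assert fit.radius == pytest.approx(200.0, abs=1e-6)
        assert fit.rms_residual < 1e-6
        assert abs(abs(fit.axis_direction[2]) - 1.0) < 1e-9

    @pytest.mark.parametrize("seed", range(5))
    def test_noisy_radius_recovery(self, seed):
        fit = cl.fit_cylinder(_cylinder_points(seed=seed))
        assert fit.radius == pytest.approx(200.0, abs=1.0)

    def test_rigid_motion_invariance(self):
        pts = _cylinder_points(seed=0)
        R = cl.euler_to_matrix((25, 70, -110))
        moved = pts @ R.T + np.array([500.0, -300.0, 120.0])
        f0, f1 = cl.fit_cylinder(pts), cl.fit_cylinder(moved)
        assert abs(f0.radius - f1.radius) < 1e-6
        assert abs(f0.rms_residual - f1.rms_residual) < 1e-6

    def test_flat_ring(self):
        # zero axial extent: axis is the *smallest* PCA direction
        t = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        pts = np.stack([150 * np.cos(t), 150 * np.sin(t), np.zeros_like(t)], axis=1)
        fit = cl.fit_cylinder(pts)
        assert fit.radius == pytest.approx(150.0, abs=1e-6)

    def test_collinear_rejected(self):
        pts = np.outer(np.linspace(0, 1, 10), [1.0, 2.0, 3.0])
        with pytest.raises(FitDegenerateError):
            cl.fit_cylinder(pts)

    def test_arc_deficient_rejected(self):
        t = np.linspace(0, np.pi / 4, 30)  # 45 degrees of arc only
        z = np.linspace(0, 300, 30)
        pts = np.stack([200 * np.cos(t), 200 * np.sin(t), z], axis=1)
        with pytest.raises(FitDegenerateError):
            cl.fit_cylinder(pts)

    def test_too_few_points(self):
        with pytest.raises(FitDegenerateError):
            cl.fit_cylinder(np.eye(3))


class TestTubeFrame:
    def test_axis_aligned_unchanged(self, noise_free):
        _, table, _ = noise_free
        fit = cl.fit_cylinder(cl.table_positions(table))
        framed = cl.to_tube_frame(table, fit)
        # generator frame is already canonical: axis +z, particle 0 at theta=0, z=0
        assert np.max(np.abs(cl.table_positions(framed) - cl.table_positions(table))) < 1e-6

    def test_rigid_motion_canonicalizes(self, noise_free):
        _, table, _ = noise_free
        R = cl.euler_to_matrix((40, 55, 170))
        moved = cl.apply_rigid(table, R, np.array([1000.0, -250.0, 80.0]))
        framed0 = cl.to_tube_frame(table, cl.fit_cylinder(cl.table_positions(table)))
        framed1 = cl.to_tube_frame(moved, cl.fit_cylinder(cl.table_positions(moved)))
        assert np.max(np.abs(cl.table_positions(framed0) - cl.table_positions(framed1))) < 1e-6

    def test_relative_pose_invariant(self, noise_free):
        _, table, _ = noise_free
        framed = cl.to_tube_frame(table, cl.fit_cylinder(cl.table_positions(table)))
        a0, b0 = cl.pose_from_row(table.iloc[3]), cl.pose_from_row(table.iloc[9])
        a1, b1 = cl.pose_from_row(framed.iloc[3]), cl.pose_from_row(framed.iloc[9])
        d0, rel0 = cl.relative_pose(a0, b0)
        d1, rel1 = cl.relative_pose(a1, b1)
        assert np.linalg.norm(d0 - d1) < 1e-9
        assert np.max(np.abs(rel0 - rel1)) < 1e-9


class TestUnroll:
    def test_reference_particle(self):
        table = cl.make_table(
            np.array([[200.0, 0.0, 0.0]]), np.array([[0.0, 90.0, 0.0]])
        )
        un = cl.unroll(table, 200.0)
        assert un["u_A"].iloc[0] == pytest.approx(0.0)
        assert un["z_A"].iloc[0] == pytest.approx(0.0)

    def test_arc_length_scaling(self):
        th = 1.0  # radian
        pos = np.array([[200.0, 0.0, 0.0], [200 * np.cos(th), 200 * np.sin(th), 0.0]])
        table = cl.make_table(pos, np.zeros((2, 3)))
        un = cl.unroll(table, 200.0)
        assert un["u_A"].iloc[1] - un["u_A"].iloc[0] == pytest.approx(200.0)

    def test_on_axis_rejected(self):
        table = cl.make_table(np.array([[0.0, 0.0, 50.0]]), np.zeros((1, 3)))
        with pytest.raises(UnmappableParticleError):
            cl.unroll(table, 200.0)

    def test_chord_vs_unrolled_small_angles(self):
        # unrolled neighbor distances track chords to < 1.5% below 30 deg
        r = 200.0
        for dtheta_deg in (2.98, 10.0, 20.0, 29.9):
            th = np.deg2rad(dtheta_deg)
            dz = 40.0
            chord = np.hypot(2 * r * np.sin(th / 2), dz)
            unrolled = np.hypot(r * th, dz)
            assert abs(unrolled - chord) / chord < 0.015

    def test_generator_vector_in_displacements(self, noise_free):
        # the one-start generator appears among unrolled nearest-neighbor steps
        _, table, _ = noise_free
        fit = cl.fit_cylinder(cl.table_positions(table))
        framed = cl.to_tube_frame(table, fit)
        pairs = cl.find_neighbors(framed, 250.0, fit.radius)
        vecs = np.array(
            [[p.du_A, p.dz_A] if p.dz_A >= 0 else [-p.du_A, -p.dz_A] for p in pairs]
        )
        target = np.array([207.71, 12.397])  # closed form: r*twist_rad, rise
        dists = np.linalg.norm(vecs - target, axis=1)
        assert dists.min() < 0.01


class TestWrapAngle:
    @pytest.mark.parametrize(
        "raw,expected",
        [(181.0, -179.0), (-180.0, 180.0), (180.0, 180.0), (540.0, 180.0), (0.0, 0.0)],
    )
    def test_wrap(self, raw, expected):
        assert cl.wrap_angle_deg(raw) == pytest.approx(expected)

    @given(st.floats(min_value=-1e6, max_value=1e6, allow_nan=False))
    @settings(deadline=None, derandomize=True)
    def test_wrap_range_and_congruence(self, angle):
        w = cl.wrap_angle_deg(angle)
        assert -180.0 < w <= 180.0
        # congruent to the input modulo 360 (tolerance scales with magnitude)
        assert abs((angle - w) / 360.0 - round((angle - w) / 360.0)) < 1e-9


class TestEulerPropertyBased:
    @given(
        st.floats(min_value=-360, max_value=360, allow_nan=False),
        st.floats(min_value=0, max_value=180, allow_nan=False),
        st.floats(min_value=-360, max_value=360, allow_nan=False),
    )
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_round_trip_any_triple(self, rot, tilt, psi):
        """Any ZYZ triple maps to a rotation whose canonical Euler form
        regenerates the same rotation."""
        R = cl.euler_to_matrix((rot, tilt, psi))
        assert abs(np.linalg.det(R) - 1.0) < 1e-12
        back = cl.euler_to_matrix(cl.matrix_to_euler(R))
        assert geodesic_angle(R, back) < 1e-9
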