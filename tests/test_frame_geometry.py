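"""Base-pair frame fitting, twist definitions and screw decomposition,
checked against independent oracles (Horn quaternion superposition,
matrix logarithm, Gram-Schmidt, explicit brute-force reconstruction)."""

import numpy as np
import pytest
from scipy.linalg import logm
from scipy.spatial.transform import Rotation, Slerp

from helixtemp import (
    BasePairFrame,
    GeometryError,
    end_to_end_twist,
    fit_base_frame,
    global_twist_series,
    local_helical_axis,
    make_helix_trajectory,
    mean_plane_twist,
    pair_midframe,
    project_frame_to_axis,
    step_screw_axis,
)
from helixtemp.templates import template_coords

from conftest import random_frame, rot_z


# ---------------------------------------------------------------------------
# independent oracles


def horn_rotation(ref: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """Closed-form quaternion superposition (Horn 1987): R minimizing
    |obs - R @ ref| for centered point sets."""
    M = ref.T @ obs
    N = np.array(
        [
            [M[0, 0] + M[1, 1] + M[2, 2], M[1, 2] - M[2, 1],
             M[2, 0] - M[0, 2], M[0, 1] - M[1, 0]],
            [M[1, 2] - M[2, 1], M[0, 0] - M[1, 1] - M[2, 2],
             M[0, 1] + M[1, 0], M[2, 0] + M[0, 2]],
            [M[2, 0] - M[0, 2], M[0, 1] + M[1, 0],
             -M[0, 0] + M[1, 1] - M[2, 2], M[1, 2] + M[2, 1]],
            [M[0, 1] - M[1, 0], M[2, 0] + M[0, 2],
             M[1, 2] + M[2, 1], -M[0, 0] - M[1, 1] + M[2, 2]],
        ]
    )
    w, v = np.linalg.eigh(N)
    q = v[:, -1]  # (w, x, y, z)
    return Rotation.from_quat([q[1], q[2], q[3], q[0]]).as_matrix()


def matrix_log_screw(r_rel: np.ndarray, t_rel: np.ndarray):
    """Axis-angle via the matrix logarithm plus translation projection."""
    W = np.real(logm(r_rel))
    w = np.array([W[2, 1] - W[1, 2], W[0, 2] - W[2, 0], W[1, 0] - W[0, 1]]) / 2.0
    angle = np.linalg.norm(w)
    axis = w / angle
    return np.degrees(angle), float(t_rel @ axis), axis


# ---------------------------------------------------------------------------
# fit_base_frame


class TestFitBaseFrame:
    def test_unmoved_template_gives_identity(self):
        names, xyz = template_coords("G")
        f = fit_base_frame(xyz, names, "G")
        np.testing.assert_allclose(f.triad, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(f.origin, 0.0, atol=1e-12)
        assert f.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_known_transform_recovered(self):
        names, xyz = template_coords("A")
        R = rot_z(30.0)
        t = np.array([1.0, 2.0, 3.0])
        f = fit_base_frame(xyz @ R.T + t, names, "A")
        np.testing.assert_allclose(f.triad, R, atol=1e-9)
        np.testing.assert_allclose(f.origin, t, atol=1e-9)

    @pytest.mark.parametrize("base", ["A", "C", "G", "T", "U"])
    def test_noisy_fit_matches_quaternion_oracle(self, base, rng):
        """Under 0.05 A isotropic noise the fit agrees with an independent
        Horn quaternion superposition draw by draw, and its angular error from
        the true rotation stays at the degree scale (planar templates make the
        out-of-plane component the softest direction)."""
        names, xyz = template_coords(base)
        errs = []
        for _ in range(20):
            R = Rotation.random(random_state=rng).as_matrix()
            t = rng.normal(0, 5, 3)
            obs = xyz @ R.T + t + rng.normal(0, 0.05, xyz.shape)
            f = fit_base_frame(obs, names, base)
            errs.append(np.degrees(
                Rotation.from_matrix(f.triad.T @ R).magnitude()
            ))
            oracle = horn_rotation(xyz - xyz.mean(0), obs - obs.mean(0))
            np.testing.assert_allclose(f.triad, oracle, atol=1e-8)
        assert np.mean(errs) < 1.3  # oracle-measured mean error is ~1.0 deg

    def test_unknown_base_and_collinear_atoms_rejected(self):
        names, xyz = template_coords("C")
        with pytest.raises(ValueError, match="unknown base"):
            fit_base_frame(xyz, names, "X")
        line = np.outer(np.arange(4.0), [1.0, 0.0, 0.0])
        with pytest.raises(GeometryError, match="collinear"):
            fit_base_frame(line, names[:4], "C")

    def test_too_few_matching_atoms(self):
        with pytest.raises(GeometryError, match=">=3"):
            fit_base_frame(np.zeros((2, 3)), ["N1", "C2"], "C")


# ---------------------------------------------------------------------------
# pair_midframe


class TestPairMidframe:
    def test_flipped_copy_returns_reference_frame(self, rng):
        fw = random_frame(rng)
        fc = BasePairFrame(fw.origin, fw.triad @ np.diag([1.0, -1.0, -1.0]))
        mid = pair_midframe(fw, fc)
        np.testing.assert_allclose(mid.triad, fw.triad, atol=1e-12)
        np.testing.assert_allclose(mid.origin, fw.origin, atol=1e-12)

    def test_half_rotation_matches_slerp_oracle(self, rng):
        fw = random_frame(rng)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        rot10 = Rotation.from_rotvec(np.radians(10.0) * axis)
        flipped = fw.triad @ rot10.as_matrix()  # W-convention partner frame
        fc = BasePairFrame(fw.origin, flipped @ np.diag([1.0, -1.0, -1.0]))
        mid = pair_midframe(fw, fc)
        ang = np.degrees(Rotation.from_matrix(fw.triad.T @ mid.triad).magnitude())
        assert ang == pytest.approx(5.0, abs=1e-9)
        slerp = Slerp([0, 1], Rotation.from_matrix([fw.triad, flipped]))
        np.testing.assert_allclose(mid.triad, slerp(0.5).as_matrix(), atol=1e-9)

    def test_swap_symmetry(self, rng):
        """Swapping the two bases (with the consistent flip) gives the same
        midframe."""
        flip = np.diag([1.0, -1.0, -1.0])
        fw = random_frame(rng)
        fc = BasePairFrame(fw.origin + rng.normal(0, 0.5, 3),
                           random_frame(rng).triad)
        m1 = pair_midframe(fw, fc)
        # re-express each base in the other strand's convention and swap:
        # the geodesic midpoint between the same two orientations is unchanged
        fw2 = BasePairFrame(fc.origin, fc.triad @ flip)
        fc2 = BasePairFrame(fw.origin, fw.triad @ flip)
        m2 = pair_midframe(fw2, fc2)
        np.testing.assert_allclose(m2.triad, m1.triad, atol=1e-9)
        np.testing.assert_allclose(m2.origin, m1.origin, atol=1e-12)


# ---------------------------------------------------------------------------
# mean_plane_twist


class TestMeanPlaneTwist:
    def test_identical_frames_zero(self, rng):
        f = random_frame(rng)
        assert mean_plane_twist(f, f) == pytest.approx(0.0, abs=1e-12)

    def test_shared_axis_is_analytic(self, rng):
        f = random_frame(rng)
        g = BasePairFrame(f.origin, f.triad @ rot_z(34.3))
        assert mean_plane_twist(f, g) == pytest.approx(34.3, abs=1e-9)

    def test_tilted_axes_match_explicit_construction(self, rng):
        """Brute-force oracle: carry each x-axis into the mean plane with an
        explicitly constructed hinge rotation matrix and measure the angle."""
        for _ in range(50):
            fa = random_frame(rng)
            tilt = Rotation.from_euler("x", 10, degrees=True).as_matrix()
            spin = Rotation.from_euler(
                "z", rng.uniform(-170, 170), degrees=True
            ).as_matrix()
            fb = BasePairFrame(fa.origin, fa.triad @ tilt @ spin)
            mz = fa.z + fb.z
            mz = mz / np.linalg.norm(mz)

            def hinge(z):
                ax = np.cross(z, mz)
                ang = np.arctan2(np.linalg.norm(ax), z @ mz)
                return Rotation.from_rotvec(
                    ang * ax / np.linalg.norm(ax)
                ).as_matrix()

            pa = hinge(fa.z) @ fa.x
            pb = hinge(fb.z) @ fb.x
            expected = np.degrees(np.arctan2(np.cross(pa, pb) @ mz, pa @ pb))
            assert mean_plane_twist(fa, fb) == pytest.approx(expected, abs=1e-10)

    def test_offset_rotation_additivity_is_exact(self, rng):
        """Rotating either frame about its own z-axis shifts the twist by
        exactly that offset — the property behind the experiment-mimicking
        invariance of end-to-end twist changes."""
        for _ in range(20):
            fa = random_frame(rng)
            fb = BasePairFrame(
                fa.origin,
                fa.triad
                @ Rotation.from_euler("x", 12, degrees=True).as_matrix()
                @ rot_z(rng.uniform(-150, 150)),
            )
            t0 = mean_plane_twist(fa, fb)
            a, b = 25.0, -40.0
            t1 = mean_plane_twist(
                BasePairFrame(fa.origin, fa.triad @ rot_z(a)),
                BasePairFrame(fb.origin, fb.triad @ rot_z(b)),
            )
            shift = (t1 - t0) - (b - a)
            shift -= 360.0 * round(shift / 360.0)
            assert shift == pytest.approx(0.0, abs=1e-9)

    def test_antisymmetry(self, rng):
        for _ in range(50):
            fa, fb = random_frame(rng), random_frame(rng)
            if fa.z @ fb.z < -0.99:
                continue
            assert mean_plane_twist(fa, fb) == pytest.approx(
                -mean_plane_twist(fb, fa), abs=1e-10
            )

    def test_antiparallel_axes_degenerate(self, rng):
        f = random_frame(rng)
        g = BasePairFrame(
            f.origin, f.triad @ Rotation.from_euler("x", 180, degrees=True).as_matrix()
        )
        with pytest.raises(GeometryError, match="antiparallel"):
            mean_plane_twist(f, g)


# ---------------------------------------------------------------------------
# step_screw_axis


class TestStepScrewAxis:
    def test_pure_z_screw(self):
        f = BasePairFrame(np.zeros(3), np.eye(3))
        g = BasePairFrame([0.0, 0.0, 2.8], rot_z(34.3))
        sp = step_screw_axis(f, g)
        assert sp.h_twist == pytest.approx(34.3, abs=1e-9)
        assert sp.h_rise == pytest.approx(2.8, abs=1e-9)
        np.testing.assert_allclose(sp.axis, [0, 0, 1], atol=1e-9)

    def test_pure_translation_limit(self, rng):
        f = random_frame(rng)
        t = rng.normal(size=3)
        g = BasePairFrame(f.origin + t, f.triad)
        sp = step_screw_axis(f, g)
        assert sp.h_twist == 0.0
        assert sp.h_rise == pytest.approx(np.linalg.norm(t), abs=1e-9)
        np.testing.assert_allclose(sp.axis, t / np.linalg.norm(t), atol=1e-9)

    def test_random_transform_matches_matrix_log_oracle(self, rng):
        for _ in range(200):
            f = random_frame(rng)
            g = random_frame(rng)
            sp = step_screw_axis(f, g)
            r_rel = f.triad.T @ g.triad
            t_rel = f.triad.T @ (g.origin - f.origin)
            ang, rise, axis = matrix_log_screw(r_rel, t_rel)
            assert sp.h_twist == pytest.approx(ang, abs=1e-7)
            assert sp.h_rise == pytest.approx(rise, abs=1e-7)
            np.testing.assert_allclose(sp.axis, f.triad @ axis, atol=1e-6)


# ---------------------------------------------------------------------------
# local axes and projection


class TestLocalAxisAndProjection:
    def test_straight_helix_axis_is_global_z(self, ideal_spec):
        traj, _, _ = make_helix_trajectory(ideal_spec, 27.0, with_atoms=False)
        frames = traj.snapshot_frames(0)
        for p in range(2, ideal_spec.n_bp):
            np.testing.assert_allclose(
                local_helical_axis(frames, p), [0, 0, 1], atol=1e-10
            )

    def test_kinked_helix_equals_direct_average(self, noisy_spec):
        traj, _, _ = make_helix_trajectory(noisy_spec, 27.0, with_atoms=False)
        frames = traj.snapshot_frames(0)
        p = 10
        a1 = step_screw_axis(frames[p - 2], frames[p - 1]).axis
        a2 = step_screw_axis(frames[p - 1], frames[p]).axis
        expected = (a1 + a2) / np.linalg.norm(a1 + a2)
        np.testing.assert_allclose(
            local_helical_axis(frames, p), expected, atol=1e-12
        )

    def test_axis_is_unit_norm_and_terminus_rejected(self, rng):
        frames = [random_frame(rng) for _ in range(5)]
        assert np.linalg.norm(local_helical_axis(frames, 3)) == pytest.approx(1.0)
        with pytest.raises(GeometryError, match="flanking"):
            local_helical_axis(frames, 1)

    def test_projection_identity_when_aligned(self, rng):
        f = random_frame(rng)
        out = project_frame_to_axis(f, f.z)
        np.testing.assert_allclose(out.triad, f.triad, atol=1e-12)
        np.testing.assert_allclose(out.origin, f.origin, atol=1e-12)

    def test_projection_matches_gram_schmidt_oracle(self, rng):
        for _ in range(20):
            f = random_frame(rng)
            tilt = Rotation.from_rotvec(
                np.radians(15) * np.array([1.0, 0, 0])
            ).as_matrix()
            axis = f.triad @ tilt @ np.array([0.0, 0.0, 1.0])
            out = project_frame_to_axis(f, axis)
            # Gram-Schmidt: orthogonalize x against the axis, then y = z cross x
            x = f.x - (f.x @ axis) * axis
            x /= np.linalg.norm(x)
            expected = np.stack([x, np.cross(axis, x), axis], axis=1)
            np.testing.assert_allclose(out.triad, expected, atol=1e-12)

    def test_projection_output_orthonormal(self, rng):
        for _ in range(20):
            f = random_frame(rng)
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            if f.z @ axis < -0.9 or abs(f.x @ axis) > 0.99:
                continue
            out = project_frame_to_axis(f, axis)
            np.testing.assert_allclose(
                out.triad.T @ out.triad, np.eye(3), atol=1e-12
            )
            assert np.linalg.det(out.triad) == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# end-to-end twist


def brute_force_e2e(frames, first, last, offsets=(0.0, 0.0)):
    """Independent reconstruction with an explicit unwrap search over
    k in {-2..2} and optional constant offset rotations of the end frames
    about their own z-axes."""
    axis_a = local_helical_axis(frames, first)
    axis_b = local_helical_axis(frames, last)
    ea = project_frame_to_axis(frames[first - 1], axis_a)
    eb = project_frame_to_axis(frames[last - 1], axis_b)
    ea = BasePairFrame(ea.origin, ea.triad @ rot_z(offsets[0]))
    eb = BasePairFrame(eb.origin, eb.triad @ rot_z(offsets[1]))
    raw = mean_plane_twist(ea, eb)
    local_sum = sum(
        mean_plane_twist(frames[i - 1], frames[i]) for i in range(first, last)
    )
    cands = [raw + 360.0 * k for k in range(-2, 3)]
    return min(cands, key=lambda v: abs(v - local_sum))


class TestEndToEndTwist:
    def test_ideal_helix_closure(self, ideal_spec):
        traj, _, _ = make_helix_trajectory(ideal_spec, 27.0, with_atoms=False)
        gt = end_to_end_twist(traj.snapshot_frames(0), 4, 24)
        assert gt.end_to_end_twist == pytest.approx(20 * 32.7, abs=1e-8)
        assert gt.htwist_sum == pytest.approx(20 * 32.7, abs=1e-8)
        assert gt.mean_hrise == pytest.approx(2.8, abs=1e-10)

    def test_perturbed_helix_matches_brute_force(self, noisy_spec):
        traj, _, _ = make_helix_trajectory(noisy_spec, 27.0, with_atoms=False)
        series = global_twist_series(traj, 4, 30)
        for s in range(5):
            frames = traj.snapshot_frames(s)
            expected = brute_force_e2e(frames, 4, 30)
            gt = end_to_end_twist(frames, 4, 30)
            assert gt.end_to_end_twist == pytest.approx(expected, abs=1e-9)
            assert series["end_to_end_twist_deg"].iloc[s] == pytest.approx(
                expected, abs=1e-9
            )

    def test_offset_rotation_invariance_of_changes(self, noisy_spec):
        """Rotating the end frames about their own z-axes by constant offsets
        shifts every snapshot's twist equally: snapshot-to-snapshot changes
        are untouched."""
        traj, _, _ = make_helix_trajectory(noisy_spec, 27.0, with_atoms=False)
        base = [
            brute_force_e2e(traj.snapshot_frames(s), 4, 30) for s in range(6)
        ]
        shifted = [
            brute_force_e2e(traj.snapshot_frames(s), 4, 30, offsets=(25.0, -40.0))
            for s in range(6)
        ]
        d_base = np.diff(base)
        d_shift = np.diff(shifted)
        np.testing.assert_allclose(d_shift, d_base, atol=1e-9)

    def test_rigid_body_invariance(self, noisy_spec, rng):
        traj, _, _ = make_helix_trajectory(noisy_spec, 27.0, with_atoms=False)
        ref = global_twist_series(traj, 4, 30)
        Q = Rotation.random(random_state=rng).as_matrix()
        t = rng.normal(0, 50, 3)
        moved = type(traj)(
            origins=traj.origins @ Q.T + t,
            triads=np.einsum("ij,snjk->snik", Q, traj.triads),
            sequence=traj.sequence,
            temperature=traj.temperature,
        )
        out = global_twist_series(moved, 4, 30)
        for col in ("end_to_end_twist_deg", "htwist_sum_deg", "mean_hrise_A"):
            np.testing.assert_allclose(out[col], ref[col], atol=1e-8)

    def test_range_must_be_interior(self, ideal_spec):
        traj, _, _ = make_helix_trajectory(ideal_spec, 27.0, with_atoms=False)
        with pytest.raises(GeometryError, match="interior"):
            end_to_end_twist(traj.snapshot_frames(0), 1, 27)
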