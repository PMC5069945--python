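import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from bivshape.errors import (
    GapError,
    IncompatiblePopulationError,
    InsufficientDataError,
    InvalidArgumentError,
)
from bivshape.mesh import mesh_volume
from bivshape.preprocess import (
    ContourSlice,
    ContourStack,
    RigidTransform,
    correct_slice_misalignment,
    detect_ed_es,
    loft_contours,
    loft_surface,
    resample_temporal,
    rigid_align_population,
)


def circle_loop(cx, cy, z, r=20.0, n=32):
    theta = np.arange(n) * 2 * np.pi / n
    return np.stack(
        [cx + r * np.cos(theta), cy + r * np.sin(theta), np.full(n, z)], axis=1
    )


def straight_stack(shifts=None, n_slices=6):
    zs = np.arange(n_slices, dtype=float) * 8.0
    shifts = np.zeros((n_slices, 2)) if shifts is None else shifts
    slices = tuple(
        ContourSlice(
            z,
            {
                "lv_endo": circle_loop(sx, sy, z, r=15.0),
                "lv_epi": circle_loop(sx, sy, z, r=25.0),
                "rv_endo": circle_loop(sx + 35.0, sy, z, r=18.0),
            },
        )
        for z, (sx, sy) in zip(zs, shifts)
    )
    return ContourStack(slices)


class TestSliceMisalignment:
    def test_collinear_centroids_unchanged(self):
        stack = straight_stack()
        out = correct_slice_misalignment(stack)
        for before, after in zip(stack.slices, out.slices):
            np.testing.assert_allclose(
                after.contours["lv_epi"], before.contours["lv_epi"], atol=1e-9
            )

    def test_planted_shifts_recovered(self, rng):
        # plant in-plane shifts orthogonal to the regression on z (zero mean,
        # zero covariance with z) so the fitted line is the original axis and
        # recovery is exact
        n = 6
        zs = np.arange(n, dtype=float) * 8.0
        sh = rng.uniform(-5, 5, (n, 2))
        sh -= sh.mean(axis=0)
        zc = zs - zs.mean()
        sh -= np.outer(zc, (zc @ sh) / (zc**2).sum())
        stack = straight_stack(shifts=sh)
        out = correct_slice_misalignment(stack)
        for sl, (sx, sy), z in zip(out.slices, sh, zs):
            np.testing.assert_allclose(
                sl.contours["lv_epi"], circle_loop(0, 0, z, r=25.0), atol=1e-6
            )

    def test_correction_reduces_deviation_from_line(self, rng):
        sh = rng.uniform(-5, 5, (6, 2))
        stack = straight_stack(shifts=sh)
        out = correct_slice_misalignment(stack)

        def deviation(s):
            c = np.array([sl.contours["lv_epi"].mean(0) for sl in s.slices])
            z = np.array([sl.z for sl in s.slices])
            design = np.column_stack([np.ones_like(z), z])
            coef, *_ = np.linalg.lstsq(design, c[:, :2], rcond=None)
            return np.linalg.norm(design @ coef - c[:, :2])

        assert deviation(out) <= deviation(stack) + 1e-12

    def test_z_positions_and_other_surfaces_shift_together(self, rng):
        sh = rng.uniform(-5, 5, (6, 2))
        stack = straight_stack(shifts=sh)
        out = correct_slice_misalignment(stack)
        for before, after in zip(stack.slices, out.slices):
            assert after.z == before.z
            d_epi = (after.contours["lv_epi"] - before.contours["lv_epi"])[0]
            d_rv = (after.contours["rv_endo"] - before.contours["rv_endo"])[0]
            np.testing.assert_allclose(d_epi, d_rv, atol=1e-12)

    def test_too_few_slices_rejected(self):
        stack = straight_stack(n_slices=2)
        with pytest.raises(InsufficientDataError):
            correct_slice_misalignment(stack)


class TestRigidAlignment:
    def test_recovers_planted_rigid_motions(self, small_template, rng):
        meshes = [
            small_template.transformed(
                Rotation.random(random_state=i).as_matrix(), rng.uniform(-30, 30, 3)
            )
            for i in range(6)
        ]
        aligned, transforms = rigid_align_population(meshes)
        flats = np.array([m.flatten() for m in aligned])
        spread = np.abs(flats - flats.mean(axis=0)).max()
        assert spread < 1e-6

    def test_identity_for_coregistered_population(self, small_template, basis):
        # identical copies: transforms reduce to the common centering shift
        meshes = [small_template] * 4
        aligned, transforms = rigid_align_population(meshes)
        for t in transforms:
            np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-9)
            np.testing.assert_allclose(
                t.translation, transforms[0].translation, atol=1e-9
            )

    def test_scale_is_preserved(self, small_template):
        scaled = small_template.with_flat(small_template.flatten() * 1.2)
        aligned, _ = rigid_align_population([small_template, scaled, small_template])
        flats = [m.flatten() for m in aligned]
        # the scaled copy cannot be superposed: residual stays large
        assert np.abs(flats[1] - flats[0]).max() > 1.0

    def test_alignment_preserves_volumes(self, small_template, rng):
        meshes = [
            small_template.transformed(
                Rotation.random(random_state=10 + i).as_matrix(),
                rng.uniform(-30, 30, 3),
            )
            for i in range(4)
        ]
        aligned, _ = rigid_align_population(meshes)
        for before, after in zip(meshes, aligned):
            for (_, sb), (_, sa) in zip(before.surfaces(), after.surfaces()):
                assert mesh_volume(sa) == pytest.approx(
                    mesh_volume(sb), rel=1e-9
                )

    def test_final_mean_centroid_at_origin(self, small_template, rng):
        meshes = [
            small_template.transformed(np.eye(3), rng.uniform(-30, 30, 3))
            for _ in range(5)
        ]
        aligned, _ = rigid_align_population(meshes)
        centroid = np.mean(
            [np.vstack([s.vertices for _, s in m.surfaces()]) for m in aligned],
            axis=(0, 1),
        )
        np.testing.assert_allclose(centroid, 0.0, atol=1e-6)

    def test_topology_mismatch_rejected(self, small_template, template):
        with pytest.raises(IncompatiblePopulationError):
            rigid_align_population([small_template, template])

    def test_improper_rotation_rejected(self):
        with pytest.raises(InvalidArgumentError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestTemporalResampling:
    def test_identity_when_counts_match(self, rng):
        frames = [rng.standard_normal((10, 3)) for _ in range(7)]
        out = resample_temporal(frames, 7)
        for a, b in zip(frames, out):
            np.testing.assert_allclose(a, b, atol=1e-12)

    def test_constant_sequence_stays_constant(self, rng):
        frame = rng.standard_normal((8, 3))
        out = resample_temporal([frame] * 4, 11)
        for f in out:
            np.testing.assert_allclose(f, frame, atol=1e-12)

    def test_midpoint_of_linear_motion_is_mean(self):
        a = np.zeros((5, 3))
        b = np.ones((5, 3)) * 4.0
        out = resample_temporal([a, b], 3)
        np.testing.assert_allclose(out[1], (a + b) / 2.0, atol=1e-12)

    def test_mismatched_point_counts_rejected(self, rng):
        with pytest.raises(IncompatiblePopulationError):
            resample_temporal(
                [rng.standard_normal((5, 3)), rng.standard_normal((6, 3))], 4
            )


class TestEdEsDetection:
    @pytest.mark.parametrize(
        "curve, expected",
        [
            ([120, 100, 80, 95, 110], (0, 2)),
            ([5.0, 5.0, 5.0], (0, 0)),  # constant: first-occurrence ties
        ],
    )
    def test_examples(self, curve, expected):
        assert detect_ed_es(curve) == expected

    def test_sampled_cosine_extrema(self):
        t = np.arange(30)
        v = 100 + 20 * np.cos(2 * np.pi * t / 30)
        assert detect_ed_es(v) == (0, 15)

    def test_invariant_to_uniform_rescaling(self, rng):
        v = rng.uniform(50, 150, 25)
        assert detect_ed_es(v) == detect_ed_es(7.3 * v)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(InvalidArgumentError):
            detect_ed_es([100.0, -5.0, 80.0])


class TestLofting:
    def test_cylinder_volume(self):
        h, r = 40.0, 10.0
        loops = [circle_loop(0, 0, z, r=r, n=48) for z in np.linspace(0, h, 9)]
        surf = loft_surface(loops, 24)
        assert surf.is_closed()
        assert mesh_volume(surf) == pytest.approx(np.pi * r**2 * h, rel=0.02)

    def test_topology_matches_template(self, small_template):
        # 8 slices lofted at circumferential resolution 12 reproduces the
        # 12 x 8 template face structure exactly
        stack = straight_stack(n_slices=8)
        mesh = loft_contours(stack, circumferential_resolution=12)
        assert mesh.same_topology(small_template) or all(
            np.array_equal(a.faces, b.faces)
            for (_, a), (_, b) in zip(mesh.surfaces(), small_template.surfaces())
        )

    def test_loop_start_rotation_leaves_volume_unchanged(self):
        loops = [circle_loop(0, 0, z, r=12.0, n=24) for z in np.linspace(0, 30, 6)]
        rolled = [np.roll(lp, 5, axis=0) for lp in loops]
        v1 = mesh_volume(loft_surface(loops, 24))
        v2 = mesh_volume(loft_surface(rolled, 24))
        assert v2 == pytest.approx(v1, abs=1e-9)

    def test_missing_interior_slice_is_gap_error(self):
        stack = straight_stack(n_slices=6)
        slices = list(stack.slices)
        broken = dict(slices[3].contours)
        del broken["rv_endo"]
        slices[3] = ContourSlice(slices[3].z, broken)
        with pytest.raises(GapError):
            loft_contours(ContourStack(tuple(slices)), 12)
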