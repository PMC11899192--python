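"""Skeletonization, centerline extraction, and the morphometric formulas."""

import math
import warnings

import numpy as np
import pytest

from fibmorph import (
    CenterlineLoop,
    MorphometryConfig,
    PhantomSpec,
    RoiMask,
    SliceImage,
    SubjectStack,
    bone_area,
    centerline_length,
    extract_centerline_loop,
    make_annulus_phantom,
    skeletonize_mask,
    slice_morphometry,
    subject_morphometry,
)
from fibmorph.errors import (
    AnisotropicSpacingError,
    EmptyMaskError,
    InsufficientSlicesError,
    TopologyError,
)

SP = (0.7, 0.7)


def annulus_mask(n=51, r_out=20, r_in=12, center=None):
    c = center or (n // 2, n // 2)
    yy, xx = np.mgrid[:n, :n]
    r = np.hypot(yy - c[0], xx - c[1])
    return (r >= r_in) & (r <= r_out)


class TestSkeletonize:
    def test_annulus_skeleton_is_the_mid_circle(self):
        """Medial axis of an annulus: one cycle within 1 px of mid radius."""
        mask = RoiMask(annulus_mask(), SP, "bone")
        sk = skeletonize_mask(mask)
        pts = np.argwhere(sk)
        radii = np.hypot(pts[:, 0] - 25, pts[:, 1] - 25)
        assert np.abs(radii - 16).max() <= 1.0
        # unit width: no 2x2 block fully set
        assert not (sk[:-1, :-1] & sk[1:, :-1] & sk[:-1, 1:] & sk[1:, 1:]).any()
        assert (sk & ~mask.values).sum() == 0  # subset of the mask

    def test_one_pixel_ring_is_its_own_skeleton(self):
        from skimage.draw import circle_perimeter

        ring = np.zeros((21, 21), bool)
        rr, cc = circle_perimeter(10, 10, 7)
        ring[rr, cc] = True
        sk = skeletonize_mask(RoiMask(ring, SP, "bone"))
        np.testing.assert_array_equal(sk, ring)

    def test_filled_disk_warns_about_missing_hole(self):
        disk = annulus_mask(r_in=0)
        with pytest.warns(UserWarning, match="no interior hole"):
            skeletonize_mask(RoiMask(disk, SP, "bone"))

    def test_two_components_raise_topology_error(self):
        two = annulus_mask(n=101, r_out=15, r_in=10, center=(25, 25)) | annulus_mask(
            n=101, r_out=15, r_in=10, center=(75, 75)
        )
        with pytest.raises(TopologyError, match="2"):
            skeletonize_mask(RoiMask(two, SP, "bone"))

    def test_stray_pixels_removed_before_thinning(self):
        mask = annulus_mask()
        mask[2, 2] = True  # 1-px speck, below the 5-px cleanup threshold
        sk = skeletonize_mask(RoiMask(mask, SP, "bone"))
        assert not sk[2, 2]


class TestCenterlineLoop:
    def test_clean_skeleton_loops_through_every_pixel(self):
        sk = skeletonize_mask(RoiMask(annulus_mask(), SP, "bone"))
        loop = extract_centerline_loop(sk)
        assert loop.is_closed
        assert len(loop.pixel_path) == int(sk.sum())
        assert len(set(loop.pixel_path)) == len(loop.pixel_path)  # simple
        steps = [
            max(abs(a[0] - b[0]), abs(a[1] - b[1]))
            for a, b in zip(loop.pixel_path, loop.pixel_path[1:] + loop.pixel_path[:1])
        ]
        assert set(steps) == {1}  # consecutive pixels are 8-neighbors

    def test_spur_pixels_excluded_from_loop(self):
        """A nub on the ring produces a skeleton spur that pruning removes."""
        mask = annulus_mask()
        mask[25, 45:49] = True  # 4-px radial nub on the outer boundary
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sk = skeletonize_mask(RoiMask(mask, SP, "bone"))
        loop = extract_centerline_loop(sk)
        clean = extract_centerline_loop(
            skeletonize_mask(RoiMask(annulus_mask(), SP, "bone"))
        )
        assert loop.is_closed
        assert abs(len(loop.pixel_path) - len(clean.pixel_path)) <= 2
        radii = [np.hypot(r - 25, c - 25) for r, c in loop.pixel_path]
        assert max(radii) < 18  # no spur pixel out near the nub

    def test_open_ring_falls_back_to_longest_path(self):
        mask = annulus_mask()
        mask[:25, 24:28] = False  # cut through the top of the ring -> C shape
        with pytest.warns(UserWarning):
            sk = skeletonize_mask(RoiMask(mask, SP, "bone"))
            loop = extract_centerline_loop(sk)
        assert not loop.is_closed
        assert len(loop.pixel_path) > 20

    def test_empty_skeleton_raises(self):
        with pytest.raises(EmptyMaskError):
            extract_centerline_loop(np.zeros((5, 5), bool))


class TestCenterlineLength:
    def test_unit_square_path(self):
        loop = CenterlineLoop([(0, 0), (0, 1), (1, 1), (1, 0)], is_closed=True)
        assert centerline_length(loop, 0.7) == pytest.approx(4 * 0.7)

    def test_open_path_omits_closure_step(self):
        loop = CenterlineLoop([(0, 0), (0, 1), (1, 2)], is_closed=False)
        assert centerline_length(loop, 1.0) == pytest.approx(1 + math.sqrt(2))

    def test_length_scales_linearly_with_spacing(self, average_annulus):
        _, _, bone, _, _ = average_annulus
        loop = extract_centerline_loop(skeletonize_mask(bone))
        assert centerline_length(loop, 1.4) == pytest.approx(
            2 * centerline_length(loop, 0.7)
        )

    def test_digital_circle_corrected_length_within_3_percent(self):
        """Kulpa weights debias the digital perimeter of a circle."""
        mask = annulus_mask(n=81, r_out=16.5, r_in=15.5, center=(40, 40))
        loop = extract_centerline_loop(skeletonize_mask(RoiMask(mask, SP, "bone")))
        cl = centerline_length(loop, 0.7, estimator="corrected")
        assert cl == pytest.approx(2 * math.pi * 16 * 0.7, rel=0.03)

    def test_unknown_estimator_rejected(self):
        loop = CenterlineLoop([(0, 0), (0, 1)], is_closed=False)
        with pytest.raises(ValueError):
            centerline_length(loop, 0.7, estimator="nope")


class TestBoneArea:
    def test_pixel_count_times_area(self):
        mask = np.zeros((20, 20), bool)
        mask[:10, :10] = True  # 100 px
        assert bone_area(RoiMask(mask, SP, "bone")) == pytest.approx(49.0)

    def test_additive_over_disjoint_masks(self):
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        a[:5, :5] = True
        b[10:, 10:] = True
        total = bone_area(RoiMask(a | b, SP, "bone"))
        assert total == pytest.approx(
            bone_area(RoiMask(a, SP, "bone")) + bone_area(RoiMask(b, SP, "bone"))
        )

    def test_fine_grid_annulus_within_one_percent(self):
        spec = PhantomSpec(outer_diameter=10.9, wall_thickness=2.7, pixel_spacing=0.175)
        _, bone, _, truth = make_annulus_phantom(spec)
        assert bone_area(bone) == pytest.approx(truth.true_BA, rel=0.01)

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            bone_area(RoiMask(np.zeros((4, 4)), SP, "bone"))


class TestSliceMorphometry:
    def test_ring_model_arithmetic(self, average_annulus):
        """BT = BA/CL and g = D_in/D_out reproduce the annulus geometry."""
        _, image, bone, marrow, truth = average_annulus
        sm = slice_morphometry(image, bone, marrow)
        assert sm.BT == pytest.approx(sm.BA / sm.CL)
        assert sm.centerline_diameter == pytest.approx(sm.CL / math.pi)
        assert sm.D_out == pytest.approx(sm.centerline_diameter + sm.BT)
        assert sm.D_in == pytest.approx(sm.centerline_diameter - sm.BT)
        assert sm.g == pytest.approx(sm.D_in / sm.D_out)
        assert sm.BT == pytest.approx(truth.true_BT, abs=0.35)
        assert sm.g == pytest.approx(truth.true_g, abs=0.08)
        assert sm.BMA == pytest.approx(truth.true_BMA, rel=0.15)

    def test_literal_convention_uses_loop_length_directly(self, average_annulus):
        _, image, bone, marrow, _ = average_annulus
        lit = slice_morphometry(image, bone, marrow,
                                MorphometryConfig(g_convention="literal"))
        assert lit.g == pytest.approx((lit.CL - lit.BT) / (lit.CL + lit.BT))
        assert lit.g > 0.8  # loop length >> wall: literal form saturates

    def test_mpi_invariant_to_global_intensity_rescaling(self, average_annulus):
        _, image, bone, marrow, _ = average_annulus
        sm1 = slice_morphometry(image, bone, marrow)
        scaled = SliceImage(image.values * 7.3, image.pixel_spacing,
                            image.slice_index)
        sm2 = slice_morphometry(scaled, bone, marrow)
        assert sm2.MPI == pytest.approx(sm1.MPI, rel=1e-6)

    def test_mpi_of_uniform_bone_equals_normalized_intensity(self):
        spec = PhantomSpec(intensity_bone=0.12, intensity_marrow=1.0,
                           supersample_factor=1)
        image, bone, marrow, _ = make_annulus_phantom(spec)
        sm = slice_morphometry(image, bone, marrow)
        assert sm.MPI == pytest.approx(0.12, abs=1e-6)

    def test_scale_equivariance(self):
        """Doubling the spacing doubles lengths, quadruples areas, fixes g."""
        results = {}
        for sp in (0.35, 0.7):
            spec = PhantomSpec(outer_diameter=10.9, wall_thickness=2.7,
                               pixel_spacing=sp, grid_size=61)
            image, bone, marrow, _ = make_annulus_phantom(spec)
            # identical pixel grid, relabelled spacing -> strict equivariance
            if sp == 0.35:
                base = (image.values, bone.values, marrow.values)
                results[sp] = slice_morphometry(image, bone, marrow)
            else:
                img = SliceImage(base[0], (0.7, 0.7))
                bn = RoiMask(base[1], (0.7, 0.7), "bone")
                mr = RoiMask(base[2], (0.7, 0.7), "marrow")
                results[sp] = slice_morphometry(img, bn, mr)
        a, b = results[0.35], results[0.7]
        assert b.CL == pytest.approx(2 * a.CL)
        assert b.BT == pytest.approx(2 * a.BT)
        assert b.BA == pytest.approx(4 * a.BA)
        assert b.BMA == pytest.approx(4 * a.BMA)
        assert b.g == pytest.approx(a.g)
        assert b.MPI == pytest.approx(a.MPI)

    @pytest.mark.parametrize("spacing,amp", [(0.35, 0.05), (0.175, 0.1)])
    def test_rotated_phantom_measures_within_2_percent(self, spacing, amp):
        """A 30-degree rotation of the triangular ring moves BT and g by
        < 2% once the wall spans a few pixels (area digitization dominates
        the orientation sensitivity at coarser grids)."""
        base = PhantomSpec(outer_diameter=10.9, wall_thickness=2.7,
                           deformation_harmonics=((3, amp, 1.0),),
                           pixel_spacing=spacing)
        rot = PhantomSpec(outer_diameter=10.9, wall_thickness=2.7,
                          deformation_harmonics=((3, amp, 1.0 + math.pi / 6),),
                          pixel_spacing=spacing)
        m1 = slice_morphometry(*make_annulus_phantom(base)[:3])
        m2 = slice_morphometry(*make_annulus_phantom(rot)[:3])
        assert m2.BT == pytest.approx(m1.BT, rel=0.02)
        assert m2.g == pytest.approx(m1.g, rel=0.02)

    def test_anisotropic_spacing_rejected(self):
        image = SliceImage(np.ones((10, 10)), (0.7, 0.5))
        mask = RoiMask(np.ones((10, 10)), (0.7, 0.5), "bone")
        with pytest.raises(AnisotropicSpacingError):
            slice_morphometry(image, mask, mask)


class TestSubjectMorphometry:
    def _stack_from_phantom(self, n=9, wall=2.7):
        spec = PhantomSpec(outer_diameter=10.9, wall_thickness=wall)
        slices = []
        for k in range(n):
            image, bone, marrow, _ = make_annulus_phantom(spec, rng=k)
            image.slice_index = bone.slice_index = marrow.slice_index = k
            slices.append((image, bone, marrow))
        return SubjectStack(subject_id="P1", slices=slices)

    def test_identical_slices_average_to_slice_values(self):
        stack = self._stack_from_phantom()
        res = subject_morphometry(stack)
        sm = slice_morphometry(*stack.slices[1])
        assert res.n_slices_used == 7
        assert res.BT == pytest.approx(sm.BT)
        assert res.g == pytest.approx(sm.g)

    def test_wall_thickness_is_mean_of_per_slice_ratios(self):
        stack = self._stack_from_phantom(n=7)
        res = subject_morphometry(stack)
        assert res.BT == pytest.approx(
            np.mean([s.BA / s.CL for s in res.per_slice])
        )

    def test_arithmetic_mean_example(self):
        # per-slice BA/CL of {2,2,2,3,3,3,6} mm must average to 3.0 mm
        assert np.mean([2, 2, 2, 3, 3, 3, 6]) == pytest.approx(3.0)

    def test_bad_slice_dropped_then_too_few_raises(self):
        stack = self._stack_from_phantom(n=7)
        image, bone, marrow = stack.slices[3]
        two = np.zeros_like(bone.values)
        two[2:10, 2:10] = True
        two[14:22, 14:22] = True  # two components -> topology failure
        bad = (image, RoiMask(two, bone.pixel_spacing, "bone", 3), marrow)
        broken = SubjectStack("P2", stack.slices[:3] + [bad] + stack.slices[4:])
        with pytest.warns(UserWarning, match="dropping slice"):
            with pytest.raises(InsufficientSlicesError):
                subject_morphometry(broken)

    def test_nine_slices_use_central_seven(self):
        stack = self._stack_from_phantom(n=9)
        res = subject_morphometry(stack)
        assert [s.slice_index for s in res.per_slice] == list(range(1, 8))
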