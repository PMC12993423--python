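"""Geometric operations against analytic ground truth.

Sphere volumes, lens overlaps, centre-of-mass shifts and margin
expansions all have closed forms, which the rasterized pipeline must
reproduce within discretisation tolerance.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from doseaccum.core import ImageGeometry, RegistrationMatrix, Roi
from doseaccum.errors import EmptyStructureError, UndefinedMetricError
from doseaccum.geometry import (
    BinaryMask,
    center_of_mass,
    cmd,
    dice,
    expand_margin,
    mask_volume,
    rasterize,
    transform_roi,
)

from conftest import circle_roi, sphere_mask


def square_roi(side, z_lo, z_hi, z_step=1.0, center=(0.0, 0.0)):
    h = side / 2.0
    cx, cy = center
    poly = np.array([(cx - h, cy - h), (cx + h, cy - h),
                     (cx + h, cy + h), (cx - h, cy + h)])
    zs = np.arange(z_lo, z_hi + 1e-9, z_step)
    return Roi(name="square", slices=[(float(z), [poly]) for z in zs])


class TestTransformRoi:
    def test_identity_leaves_vertices(self, sphere_roi):
        out = transform_roi(sphere_roi, RegistrationMatrix.identity())
        assert np.allclose(out.all_vertices(), sphere_roi.all_vertices())

    def test_pure_translation_shifts_every_vertex(self, sphere_roi):
        reg = RegistrationMatrix.from_translation((3.0, 0.0, 4.0))
        out = transform_roi(sphere_roi, reg)
        assert np.allclose(out.all_vertices(),
                           sphere_roi.all_vertices() + [3.0, 0.0, 4.0])

    def test_translation_then_inverse_restores(self, sphere_roi):
        reg = RegistrationMatrix.from_translation((2.5, -1.25, 3.75))
        there = transform_roi(sphere_roi, reg, "moving_to_fixed")
        back = transform_roi(there, reg, "fixed_to_moving")
        assert np.allclose(back.all_vertices(), sphere_roi.all_vertices(),
                           atol=1e-6)

    def test_rotation_preserves_volume_within_2pct(self, sphere_roi,
                                                   big_grid):
        from scipy.spatial.transform import Rotation

        m = np.eye(4)
        m[:3, :3] = Rotation.from_euler("z", 10, degrees=True).as_matrix()
        reg = RegistrationMatrix(m)
        out = transform_roi(sphere_roi, reg)
        v_in = mask_volume(rasterize(sphere_roi, big_grid, 2))
        v_out = mask_volume(rasterize(out, big_grid, 2))
        assert v_out == pytest.approx(v_in, rel=0.02)

    def test_empty_roi_rejected(self):
        with pytest.raises(EmptyStructureError):
            transform_roi(Roi("empty", []), RegistrationMatrix.identity())


class TestRasterize:
    def test_cube_volume(self, unit_grid):
        # 20 mm cube, edges between voxel centres, contoured every 1 mm
        # from -9.5 to 9.5 -> 20 slabs of exactly 400 mm^2
        roi = square_roi(20.0, -9.5, 9.5, center=(0.5, 0.5))
        vol_mm3 = mask_volume(rasterize(roi, unit_grid, 4)) * 1000
        assert vol_mm3 == pytest.approx(8000.0, rel=0.06)

    def test_nested_square_makes_hole(self, unit_grid):
        outer = square_roi(20.0, 0.0, 0.0, center=(0.5, 0.5)).slices[0][1][0]
        inner = square_roi(10.0, 0.0, 0.0, center=(0.5, 0.5)).slices[0][1][0]
        roi = Roi(name="ring", slices=[(0.0, [outer, inner])])
        mask = rasterize(roi, unit_grid, 4)
        area_mm2 = mask.n_set  # single 1 mm slice -> voxels = mm^2
        assert area_mm2 == pytest.approx(0.75 * 400.0, rel=0.05)

    def test_sphere_volume_within_1pct(self, big_grid):
        roi = circle_roi("s", 0, 0, 0, 25.0, z_spacing=1.0)
        vol_mm3 = mask_volume(rasterize(roi, big_grid, 4)) * 1000
        analytic = 4.0 / 3.0 * math.pi * 25.0 ** 3
        assert vol_mm3 == pytest.approx(analytic, rel=0.01)

    def test_halving_spacing_converges_to_analytic(self):
        roi = circle_roi("s", 0, 0, 0, 15.0, z_spacing=1.0)
        analytic = 4.0 / 3.0 * math.pi * 15.0 ** 3
        errs = []
        for sp in (2.0, 1.0):
            g = ImageGeometry(origin=(-20, -20, -20),
                              spacing=(sp, sp, sp),
                              dims=(int(40 / sp) + 1,) * 3)
            v = mask_volume(rasterize(roi, g, 2)) * 1000
            errs.append(abs(v - analytic))
        assert errs[1] < errs[0]

    def test_all_planes_out_of_range_warns_empty(self, unit_grid):
        roi = square_roi(10.0, 100.0, 105.0)
        with pytest.warns(UserWarning, match="outside grid"):
            mask = rasterize(roi, unit_grid, 2)
        assert mask.is_empty


class TestMaskMetrics:
    def test_volume_unit_arithmetic(self, unit_grid):
        vox = np.zeros(unit_grid.dims, dtype=bool)
        vox.ravel()[:1000] = True
        assert mask_volume(BinaryMask(unit_grid, vox)) == pytest.approx(1.0)
        assert mask_volume(
            BinaryMask(unit_grid, np.zeros(unit_grid.dims, bool))) == 0.0

    def test_com_single_and_pair(self, unit_grid):
        vox = np.zeros(unit_grid.dims, dtype=bool)
        vox[20, 20, 20] = True  # centre voxel -> (0,0,0)
        assert np.allclose(center_of_mass(BinaryMask(unit_grid, vox)),
                           (0, 0, 0))
        vox[20, 20, 24] = True
        assert np.allclose(center_of_mass(BinaryMask(unit_grid, vox)),
                           (0, 0, 2.0))

    def test_com_of_symmetric_sphere(self, big_grid):
        m = sphere_mask(big_grid, (10.0, -20.0, 5.0), 12.0)
        assert np.allclose(center_of_mass(m), (10.0, -20.0, 5.0), atol=0.5)

    def test_com_empty_raises(self, unit_grid):
        with pytest.raises(EmptyStructureError):
            center_of_mass(BinaryMask(unit_grid, np.zeros(unit_grid.dims,
                                                          bool)))

    def test_cmd_3_4_5(self, big_grid):
        a = sphere_mask(big_grid, (0, 0, 0), 10.0)
        b = sphere_mask(big_grid, (3.0, 4.0, 0.0), 10.0)
        assert cmd(a, a) == 0.0
        assert cmd(a, b) == pytest.approx(5.0, abs=0.5)

    def test_cmd_triangle_inequality(self, big_grid):
        a = sphere_mask(big_grid, (0, 0, 0), 8.0)
        b = sphere_mask(big_grid, (6, 0, 0), 8.0)
        c = sphere_mask(big_grid, (3, 5, 2), 8.0)
        assert cmd(a, b) <= cmd(a, c) + cmd(c, b) + 1e-9


class TestDice:
    def test_identical_and_disjoint(self, big_grid):
        a = sphere_mask(big_grid, (0, 0, 0), 10.0)
        b = sphere_mask(big_grid, (25, 25, 0), 5.0)
        assert dice(a, a) == 1.0
        assert dice(a, b) == 0.0

    def test_symmetry(self, big_grid):
        a = sphere_mask(big_grid, (0, 0, 0), 10.0)
        b = sphere_mask(big_grid, (5, 0, 0), 10.0)
        assert dice(a, b) == dice(b, a)

    def test_equal_spheres_lens_overlap(self, big_grid):
        # analytic: DSC = (4r+d)(2r-d)^2 / (16 r^3), r=10, d=10 -> 0.3125
        a = sphere_mask(big_grid, (0, 0, 0), 10.0)
        b = sphere_mask(big_grid, (10.0, 0, 0), 10.0)
        assert dice(a, b) == pytest.approx(0.3125, rel=0.02)

    def test_both_empty_is_undefined(self, unit_grid):
        empty = BinaryMask(unit_grid, np.zeros(unit_grid.dims, bool))
        with pytest.raises(UndefinedMetricError):
            dice(empty, empty)

    def test_one_empty_is_zero(self, big_grid):
        a = sphere_mask(big_grid, (0, 0, 0), 10.0)
        empty = BinaryMask(big_grid, np.zeros(big_grid.dims, bool))
        assert dice(a, empty) == 0.0


class TestExpandMargin:
    def test_point_grows_to_ball(self, big_grid):
        vox = np.zeros(big_grid.dims, dtype=bool)
        vox[40, 40, 40] = True
        grown = expand_margin(BinaryMask(big_grid, vox), 10.0)
        analytic = 4.0 / 3.0 * math.pi * 10.0 ** 3
        assert mask_volume(grown) * 1000 == pytest.approx(analytic, rel=0.05)

    def test_sub_voxel_margin_is_noop(self, big_grid):
        m = sphere_mask(big_grid, (0, 0, 0), 10.0)
        out = expand_margin(m, 0.4)
        assert np.array_equal(out.voxels, m.voxels)

    def test_sphere_expansion_matches_analytic(self, big_grid):
        m = sphere_mask(big_grid, (0, 0, 0), 20.0)
        grown = expand_margin(m, 10.0)
        analytic = 4.0 / 3.0 * math.pi * 30.0 ** 3
        assert mask_volume(grown) * 1000 == pytest.approx(analytic, rel=0.02)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(m1=st.floats(1.0, 8.0), extra=st.floats(0.5, 6.0))
    def test_monotone_in_margin(self, m1, extra):
        g = ImageGeometry(origin=(-25, -25, -25), spacing=(1, 1, 1),
                          dims=(51, 51, 51))
        m = sphere_mask(g, (0, 0, 0), 6.0)
        small = expand_margin(m, m1)
        large = expand_margin(m, m1 + extra)
        assert np.all(large.voxels[small.voxels])

    def test_empty_rejected(self, unit_grid):
        with pytest.raises(EmptyStructureError):
            expand_margin(BinaryMask(unit_grid,
                                     np.zeros(unit_grid.dims, bool)), 5.0)
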