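"""Voxel-grid geometry, ROI stacking, interpolation and boundary extraction."""

import numpy as np
import pytest

from lesionfit3d import (
    DimensionError,
    EmptyInputError,
    LesionMask,
    ValidationError,
    VoxelGrid,
    boundary_points,
    interpolate_z,
    stack_rois,
    surface_points,
)
from lesionfit3d.measure import planimetric_volume

from conftest import make_phantom


def disc(nx, ny, cx, cy, radius_px):
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    return (ii - cx) ** 2 + (jj - cy) ** 2 <= radius_px**2


class TestVoxelGrid:
    def test_slice_centres_are_thickness_plus_gap_apart(self):
        g = VoxelGrid(nx=4, ny=4, nz=5, dx=0.5, dy=0.5,
                      slice_thickness=3.0, slice_gap=3.0, origin=(1.0, 2.0, 10.0))
        assert g.dz == 6.0
        assert g.slice_z(0) == 10.0
        assert g.slice_z(3) == 10.0 + 3 * 6.0

    def test_voxel_centre_coordinates(self):
        g = VoxelGrid(nx=4, ny=4, nz=3, dx=0.5, dy=0.25,
                      slice_thickness=2.0, slice_gap=1.0, origin=(0.0, 0.0, -3.0))
        pt = g.index_to_mm([[2, 3, 1]])[0]
        assert np.allclose(pt, [1.0, 0.75, 0.0])

    @pytest.mark.parametrize("bad", [
        dict(nx=0), dict(dx=-1.0), dict(slice_thickness=0.0), dict(slice_gap=-0.1),
    ])
    def test_invalid_geometry_rejected(self, bad):
        kwargs = dict(nx=4, ny=4, nz=4, dx=1.0, dy=1.0, slice_thickness=3.0,
                      slice_gap=3.0)
        kwargs.update(bad)
        with pytest.raises(ValidationError):
            VoxelGrid(**kwargs)


class TestStackRois:
    def test_stacking_preserves_counts(self):
        g = VoxelGrid(nx=5, ny=5, nz=3, dx=1, dy=1, slice_thickness=3, slice_gap=3)
        roi = np.zeros((5, 5), bool)
        roi[2, 2] = roi[2, 3] = True
        mask = stack_rois([roi, roi, roi], g)
        assert mask.voxel_count == 6
        assert np.array_equal(mask.occupancy[:, :, 1], roi)

    def test_single_slice_single_voxel(self):
        g = VoxelGrid(nx=3, ny=3, nz=1, dx=1, dy=1, slice_thickness=3)
        roi = np.zeros((3, 3), bool)
        roi[1, 1] = True
        assert stack_rois([roi], g).voxel_count == 1

    def test_shape_mismatch_and_empty_input(self):
        g = VoxelGrid(nx=5, ny=5, nz=2, dx=1, dy=1, slice_thickness=3)
        with pytest.raises(DimensionError):
            stack_rois([np.zeros((5, 5), bool), np.zeros((4, 5), bool)], g)
        with pytest.raises(EmptyInputError):
            stack_rois([], g)
        with pytest.raises(DimensionError):
            stack_rois([np.zeros((5, 5), bool)], g)  # nz mismatch


class TestInterpolateZ:
    def test_constant_shape_between_equal_slices(self):
        g = VoxelGrid(nx=30, ny=30, nz=2, dx=1, dy=1, slice_thickness=3, slice_gap=3)
        roi = disc(30, 30, 15, 15, 6)
        mask = stack_rois([roi, roi], g)
        out = interpolate_z(mask, 1.0)
        # every slice between the original centres contains the same disc
        for k in out.occupied_slices():
            z = out.grid.slice_z(k)
            if g.slice_z(0) <= z <= g.slice_z(1):
                assert np.array_equal(out.occupancy[:, :, k], roi)

    def test_midpoint_between_concentric_circles_is_mean_radius(self):
        # signed-distance interpolation oracle: circles r=5 and r=3 (mm), the
        # midpoint slice must be a circle of radius 4 mm (+/- 1 pixel)
        g = VoxelGrid(nx=60, ny=60, nz=2, dx=0.5, dy=0.5,
                      slice_thickness=3, slice_gap=3)
        mask = stack_rois([disc(60, 60, 30, 30, 10), disc(60, 60, 30, 30, 6)], g)
        out = interpolate_z(mask, 1.0)
        k_mid = next(k for k in range(out.grid.nz)
                     if abs(out.grid.slice_z(k) - 3.0) < 1e-9)
        mid = out.occupancy[:, :, k_mid]
        expected = disc(60, 60, 30, 30, 8)  # 4 mm = 8 px
        # symmetric difference confined to a 1-pixel annulus
        ring = disc(60, 60, 30, 30, 9) & ~disc(60, 60, 30, 30, 7)
        assert not np.any((mid ^ expected) & ~ring)

    def test_single_slice_extends_half_profile_with_taper(self):
        # one occupied slice, 3+3 mm profile: output spans the centre +/- 3 mm
        # with the contour eroding 1 mm per mm beyond the slice
        g = VoxelGrid(nx=40, ny=40, nz=3, dx=0.5, dy=0.5,
                      slice_thickness=3, slice_gap=3)
        rois = [np.zeros((40, 40), bool), disc(40, 40, 20, 20, 12), np.zeros((40, 40), bool)]
        mask = stack_rois(rois, g)
        out = interpolate_z(mask, 1.0)
        zs = [out.grid.slice_z(k) for k in out.occupied_slices()]
        centre_z = g.slice_z(1)
        assert min(zs) == pytest.approx(centre_z - 3.0)
        assert max(zs) == pytest.approx(centre_z + 3.0)
        # the ROI at +/- 3 mm is the original eroded by 3 mm (12 px -> ~6 px)
        k_end = out.occupied_slices()[-1]
        end_area = out.occupancy[:, :, k_end].sum()
        assert end_area < rois[1].sum() / 2

    def test_original_slice_centres_reproduced_exactly(self, t2_paper_grid):
        mask, _ = make_phantom(t2_paper_grid, (12.0, 9.0, 8.0), zoff=1.0)
        out = interpolate_z(mask, 1.0)
        for k in mask.occupied_slices():
            z = mask.grid.slice_z(k)
            k_out = next(m for m in range(out.grid.nz)
                         if abs(out.grid.slice_z(m) - z) < 1e-9)
            assert np.array_equal(out.occupancy[:, :, k_out], mask.occupancy[:, :, k])

    def test_idempotent_on_fine_grid(self, rng):
        g = VoxelGrid(nx=20, ny=20, nz=9, dx=1, dy=1, slice_thickness=1.0)
        occ = np.zeros(g.shape, bool)
        for k in range(2, 7):  # random blob occupying slices 2..6
            occ[:, :, k] = disc(20, 20, 10, 10, int(rng.integers(3, 7)))
        mask = LesionMask(g, occ)
        out = interpolate_z(mask, 1.0)
        # output covers the occupied range and reproduces it exactly
        k0 = mask.occupied_slices()[0]
        assert out.grid.origin[2] == pytest.approx(g.slice_z(k0))
        assert out.grid.nz == mask.occupied_slices()[-1] - k0 + 1
        for m in range(out.grid.nz):
            assert np.array_equal(out.occupancy[:, :, m], occ[:, :, k0 + m])

    def test_interpolated_volume_consistent_with_planimetric(self, t2_paper_grid):
        mask, _ = make_phantom(t2_paper_grid, (12.0, 10.0, 9.0), zoff=1.5)
        assert len(mask.occupied_slices()) >= 3
        out = interpolate_z(mask, 1.0)
        vol_interp = out.voxel_count * np.prod(out.grid.spacing)
        vol_plan = planimetric_volume(mask) * 1000.0
        assert abs(vol_interp - vol_plan) / vol_plan <= 0.15

    def test_contract_violations(self):
        g = VoxelGrid(nx=5, ny=5, nz=2, dx=1, dy=1, slice_thickness=3, slice_gap=3)
        empty = LesionMask(g, np.zeros(g.shape, bool))
        with pytest.raises(EmptyInputError):
            interpolate_z(empty)
        occ = np.zeros(g.shape, bool)
        occ[2, 2, :] = True
        with pytest.raises(ValidationError):
            interpolate_z(LesionMask(g, occ), target_spacing=7.0)  # > centre spacing


class TestBoundaryPoints:
    def make_block(self, n):
        g = VoxelGrid(nx=n + 4, ny=n + 4, nz=n + 4, dx=1, dy=1, slice_thickness=1)
        occ = np.zeros(g.shape, bool)
        occ[2:2 + n, 2:2 + n, 2:2 + n] = True
        return LesionMask(g, occ)

    def test_single_voxel_is_its_own_boundary(self):
        g = VoxelGrid(nx=3, ny=3, nz=3, dx=1, dy=1, slice_thickness=1)
        occ = np.zeros(g.shape, bool)
        occ[1, 1, 1] = True
        pts = boundary_points(LesionMask(g, occ))
        assert len(pts) == 1
        assert np.allclose(pts.points[0], [1, 1, 1])

    @pytest.mark.parametrize("n,expected", [(3, 26), (5, 98)])
    def test_solid_block_boundary_counts(self, n, expected):
        assert len(boundary_points(self.make_block(n))) == expected

    def test_boundary_subset_and_strict_shrink(self, sphere_phantom_iso):
        mask, _ = sphere_phantom_iso
        pts = boundary_points(mask)
        centres = {tuple(p) for p in mask.grid.index_to_mm(np.argwhere(mask.occupancy))}
        assert all(tuple(p) in centres for p in pts.points)
        # removing the boundary layer strictly decreases the voxel count
        idx = np.round(
            (pts.points - np.asarray(mask.grid.origin)) / np.asarray(mask.grid.spacing)
        ).astype(int)
        occ2 = mask.occupancy.copy()
        occ2[idx[:, 0], idx[:, 1], idx[:, 2]] = False
        assert occ2.sum() < mask.voxel_count

    def test_empty_mask_rejected(self):
        g = VoxelGrid(nx=3, ny=3, nz=3, dx=1, dy=1, slice_thickness=1)
        with pytest.raises(EmptyInputError):
            boundary_points(LesionMask(g, np.zeros(g.shape, bool)))


class TestSurfacePoints:
    def test_vertices_straddle_the_true_surface(self, sphere_phantom_iso):
        mask, _ = sphere_phantom_iso
        pts = surface_points(mask).points
        centre = pts.mean(axis=0)
        radii = np.linalg.norm(pts - centre, axis=1)
        # sub-voxel sampling: mean radius within a quarter voxel of truth
        assert abs(radii.mean() - 10.0) < 0.25
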