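"""Volume rasterization, iso-surfacing and contour lofting."""

import math

import numpy as np
import pytest

from microgrind import morphometry as mor
from microgrind import reconstruction as rec
from microgrind import segmentation as seg
from microgrind.phantom import CLASS_INDEX, classify_points
from microgrind.registration import SlicePose
from microgrind.segmentation import ContourPolygon, ContourSet

SPHERE_V = 4.0 / 3.0 * math.pi * 500.0**3
BONE_V = SPHERE_V - math.pi * 25.0**2 * 1000.0


def _pose(run, c_um, gx=0.0, gy=0.0, px=5.0):
    return SlicePose(run=run, angle_deg=0.0, tx_um=0.0, ty_um=0.0, scale=1.0,
                     gx=gx, gy=gy, c_um=c_um, residual_px=0.0, pixel_size_um=px)


def _disk_map(run, radius_px=12.0, size=48, px=5.0):
    idx = np.arange(size) + 0.5
    X, Y = np.meshgrid(idx, idx)
    mask = (X - size / 2) ** 2 + (Y - size / 2) ** 2 <= radius_px**2
    return seg.TissueLabelMap(
        labels=np.where(mask, CLASS_INDEX["bone"], 0).astype(np.uint8),
        run=run, pixel_size_um=px,
    )


class TestRasterizeStack:
    def test_two_planes_give_one_gap_slab(self):
        maps = [_disk_map(1), _disk_map(2)]
        poses = [_pose(1, 35.0), _pose(2, 70.0)]
        vol = rec.rasterize_stack(maps, poses, voxel_um=5.0)
        zmask = vol.mask("bone").any(axis=(1, 2))
        zs = vol.origin_um[2] + np.arange(vol.data.shape[0]) * vol.voxel_um
        covered = zs[zmask]
        # nearest-plane fill spans exactly the interval between the two cuts
        assert covered.min() >= 35.0 and covered.max() <= 70.0
        assert covered.max() - covered.min() == pytest.approx(30.0, abs=vol.voxel_um)

    def test_single_slice_rejected(self):
        with pytest.raises(rec.ReconstructionError, match="two slices"):
            rec.rasterize_stack([_disk_map(1)], [_pose(1, 35.0)])

    def test_overlapping_planes_rejected(self):
        maps = [_disk_map(1), _disk_map(2)]
        poses = [_pose(1, 70.0), _pose(2, 35.0)]
        with pytest.raises(rec.ReconstructionError, match="negative gap"):
            rec.rasterize_stack(maps, poses, voxel_um=5.0)

    def test_tilt_aware_beats_flat_stacking(self, stain):
        from microgrind import phantom, registration as reg

        spec = phantom.make_ossicle_phantom("two_sphere_test", 0)
        t = 59.0 / (2 * (1400.0 - 130.0))
        sched = phantom.GrindingSchedule(n_runs=24, tilt=(t, t))
        res = phantom.simulate_grinding(spec, sched, stain=stain, seed=2)
        px = sched.pixel_size_um
        poses = reg.build_pose_stack(
            {p.run: im for p, im in zip(res.true_poses, res.images)},
            res.abrasion, np.asarray(spec.fiducial_columns), spec.block_size[2],
            px, expected_radius_px=spec.fiducial_radius / px, stain=stain,
        )
        maps = [seg.classify_pixels(im, stain, run=p.run, pixel_size_um=px)
                for p, im in zip(res.true_poses, res.images)]
        errs = {}
        for mode in (True, False):
            vol = rec.rasterize_stack(maps, poses, voxel_um=15.0, tilt_aware=mode)
            nz, ny, nx = vol.data.shape
            xs = vol.origin_um[0] + np.arange(nx) * vol.voxel_um
            ys = vol.origin_um[1] + np.arange(ny) * vol.voxel_um
            zs = vol.origin_um[2] + np.arange(nz) * vol.voxel_um
            Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
            truth = classify_points(
                spec, np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
            ).reshape(vol.data.shape)
            errs[mode] = (vol.data != truth).mean()
        assert errs[True] < errs[False]


class TestSurfaceFromVolume:
    @pytest.fixture(scope="class")
    def sphere_volume(self):
        vox = 10.0
        n = int(1100 / vox)
        idx = (np.arange(n) + 0.5) * vox - 550.0
        Z, Y, X = np.meshgrid(idx, idx, idx, indexing="ij")
        mask = X**2 + Y**2 + Z**2 <= 500.0**2
        return rec.LabelVolume(
            data=np.where(mask, CLASS_INDEX["bone"], 0).astype(np.uint8), voxel_um=vox
        )

    def test_sphere_topology_and_volume(self, sphere_volume):
        mesh = rec.surface_from_volume(sphere_volume, "bone", smoothing_iters=0)
        assert mesh.watertight
        assert mesh.euler_characteristic == 2
        assert mor.mesh_volume_tetra(mesh) == pytest.approx(SPHERE_V, rel=0.02)

    def test_smoothing_preserves_volume(self, sphere_volume):
        v0 = mor.mesh_volume_tetra(rec.surface_from_volume(sphere_volume, "bone", smoothing_iters=0))
        v20 = mor.mesh_volume_tetra(rec.surface_from_volume(sphere_volume, "bone", smoothing_iters=20))
        assert abs(v20 - v0) / v0 < 0.01

    def test_absent_class(self, sphere_volume):
        with pytest.raises(rec.ReconstructionError, match="absent"):
            rec.surface_from_volume(sphere_volume, "cartilage")

    def test_small_components_dropped(self, sphere_volume):
        data = sphere_volume.data.copy()
        data[2, 2, 2] = CLASS_INDEX["bone"]  # a single stray voxel
        vol = rec.LabelVolume(data=data, voxel_um=sphere_volume.voxel_um)
        mesh = rec.surface_from_volume(vol, "bone", smoothing_iters=0, min_component_voxels=8)
        assert mesh.watertight
        assert mesh.euler_characteristic == 2  # one ball, stray voxel gone


def _square_ring(side=1000.0):
    return np.array([[0.0, 0.0], [side, 0.0], [side, side], [0.0, side]])


def _circle_ring(cx, cy, r, n=48):
    t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    return np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)])


class TestLoftContours:
    def test_box_from_squares(self):
        css, poses = [], []
        for k in range(5):
            cs = ContourSet(run=k + 1)
            cs.add(ContourPolygon("bone", _square_ring()))
            css.append(cs)
            poses.append(_pose(k + 1, 35.0 * (k + 1)))
        mesh = rec.loft_contours(css, poses, "bone")
        assert mesh.watertight
        assert mor.mesh_volume_tetra(mesh) == pytest.approx(1000.0 * 1000.0 * 140.0, rel=1e-3)

    def test_single_slice_rejected(self):
        cs = ContourSet(run=1)
        cs.add(ContourPolygon("bone", _square_ring()))
        with pytest.raises(rec.ReconstructionError, match="two slices"):
            rec.loft_contours([cs], [_pose(1, 35.0)], "bone")

    def test_y_branch_watertight_genus_zero(self):
        css, poses = [], []
        for k in range(8):
            cs = ContourSet(run=k + 1)
            if k < 4:
                cs.add(ContourPolygon("vessel", _circle_ring(400, 400, 80)))
            else:
                cs.add(ContourPolygon("vessel", _circle_ring(320, 400, 50)))
                cs.add(ContourPolygon("vessel", _circle_ring(480, 400, 50)))
            css.append(cs)
            poses.append(_pose(k + 1, 35.0 * (k + 1)))
        mesh = rec.loft_contours(css, poses, "vessel")
        assert mesh.watertight
        assert mesh.genus == 0

    def test_cylinder_volume(self):
        css, poses = [], []
        for k in range(6):
            cs = ContourSet(run=k + 1)
            cs.add(ContourPolygon("vessel", _circle_ring(300, 300, 100, n=96)))
            css.append(cs)
            poses.append(_pose(k + 1, 35.0 * (k + 1)))
        mesh = rec.loft_contours(css, poses, "vessel")
        assert mesh.watertight
        # 96-gon prism, height 5 x 35
        poly_area = 0.5 * 96 * 100.0**2 * math.sin(2 * math.pi / 96)
        assert mor.mesh_volume_tetra(mesh) == pytest.approx(poly_area * 175.0, rel=1e-3)

    def test_loft_agrees_with_rasterized_surface(self, sphere_sim, sphere_poses, sphere_labelmaps):
        # volume-method agreement on the default phantom (bone structure)
        spec, sched, res = sphere_sim
        css = [
            seg.extract_contours(lm, "bone", pose=p)
            for lm, p in zip(sphere_labelmaps, sphere_poses)
        ]
        loft = rec.loft_contours(css, sphere_poses, "bone")
        vol = rec.rasterize_stack(sphere_labelmaps, sphere_poses, voxel_um=10.0)
        surf = rec.surface_from_volume(vol, "bone", smoothing_iters=0)
        v_loft = loft.trimesh().volume
        v_surf = mor.mesh_volume_tetra(surf)
        assert abs(v_loft - v_surf) / v_surf < 0.03
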