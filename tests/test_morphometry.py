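"""Tetrahedral volumes, fractions, diameters, thickness, modality comparison."""

import math

import numpy as np
import pytest
import trimesh

from microgrind import morphometry as mor
from microgrind import reconstruction as rec
from microgrind.phantom import CLASS_INDEX
from microgrind.reconstruction import LabelVolume, SurfaceMesh


def _mesh(tm, tissue="bone"):
    return SurfaceMesh.from_trimesh(tm, tissue)


class TestMeshVolumeTetra:
    def test_unit_cube(self):
        box = trimesh.creation.box(extents=(1000.0, 1000.0, 1000.0))
        assert mor.mesh_volume_tetra(_mesh(box)) == 1e9

    def test_regular_tetrahedron(self):
        a = 1000.0
        verts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
        verts *= a / (2.0 * math.sqrt(2.0))
        tm = trimesh.Trimesh(verts, [[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
        tm.fix_normals()
        expected = a**3 / (6.0 * math.sqrt(2.0))
        assert mor.mesh_volume_tetra(_mesh(tm)) == pytest.approx(expected, rel=1e-9)

    def test_translation_invariance(self):
        tm = trimesh.creation.icosphere(subdivisions=3, radius=500.0)
        v0 = mor.mesh_volume_tetra(_mesh(tm))
        tm2 = tm.copy()
        tm2.apply_translation([1e6, -3e5, 7e4])
        assert mor.mesh_volume_tetra(_mesh(tm2)) == pytest.approx(v0, rel=1e-9)

    def test_non_watertight_rejected(self):
        box = trimesh.creation.box(extents=(10.0, 10.0, 10.0))
        holed = trimesh.Trimesh(box.vertices, box.faces[:-1])
        with pytest.raises(mor.NonWatertightMeshError):
            mor.mesh_volume_tetra(_mesh(holed))

    def test_agrees_with_voxel_count(self):
        vox = 10.0
        n = int(1100 / vox)
        idx = (np.arange(n) + 0.5) * vox - 550.0
        Z, Y, X = np.meshgrid(idx, idx, idx, indexing="ij")
        mask = X**2 + Y**2 + Z**2 <= 500.0**2
        vol = LabelVolume(np.where(mask, CLASS_INDEX["bone"], 0).astype(np.uint8), vox)
        mesh = rec.surface_from_volume(vol, "bone", smoothing_iters=0)
        assert mor.mesh_volume_tetra(mesh) == pytest.approx(vol.class_volumes()["bone"], rel=0.02)


class TestNotCalcifiedFraction:
    def test_arithmetic(self):
        assert mor.not_calcified_fraction({"bone": 99e6, "vessel": 1e6}) == pytest.approx(1.0)

    def test_no_internal_structures(self):
        assert mor.not_calcified_fraction({"bone": 1e8}) == 0.0

    def test_missing_bone_rejected(self):
        with pytest.raises(mor.MorphometryError):
            mor.not_calcified_fraction({"vessel": 1e6})

    def test_exterior_soft_tissue_excluded(self):
        # a mucosa-like layer draped outside the bone must not count
        vox = 5.0
        data = np.zeros((40, 40, 40), np.uint8)
        data[10:30, 10:30, 10:30] = CLASS_INDEX["bone"]
        data[15:25, 15:25, 15:25] = CLASS_INDEX["vessel"]
        data[5:8, :, :] = CLASS_INDEX["soft_tissue"]  # detached outer slab
        vol = LabelVolume(data, vox)
        interior = mor.interior_class_volumes(vol)
        assert interior["soft_tissue"] == 0.0
        frac = mor.not_calcified_fraction(interior)
        assert frac == pytest.approx(100.0 * 1000.0 / 8000.0, rel=1e-6)

    def test_phantom_matches_oracle(self, sphere_sim, sphere_poses, sphere_labelmaps):
        spec, _, _ = sphere_sim
        vol = rec.rasterize_stack(sphere_labelmaps, sphere_poses, voxel_um=10.0)
        frac = mor.not_calcified_fraction(mor.interior_class_volumes(vol))
        # analytic ratio over the ground span: both classes clipped identically,
        # so the channel/sphere ratio stays near the full-solid closed form
        tube_v = math.pi * 25.0**2 * 1000.0
        sphere_v = 4.0 / 3.0 * math.pi * 500.0**3
        expected = 100.0 * tube_v / sphere_v
        assert frac == pytest.approx(expected, rel=0.10)


def _cylinder_volume(d_um, vox=5.0, length_vox=60):
    r = d_um / 2.0 / vox
    n = int(2 * r + 13)
    idx = np.arange(n)
    X, Y = np.meshgrid(idx, idx)
    c = n / 2.0 - 0.5
    disk = (X - c) ** 2 + (Y - c) ** 2 <= r**2
    data = np.zeros((length_vox, n, n), np.uint8)
    data[5:-5, disk] = CLASS_INDEX["vessel"]
    return LabelVolume(data, vox)


class TestChannelDiameters:
    @pytest.mark.parametrize("d_um", [20.0, 50.0, 80.0])
    def test_cylinder_within_one_voxel(self, d_um):
        dist = mor.channel_diameters(_cylinder_volume(d_um))
        assert dist.n_samples > 0
        assert abs(dist.median_um - d_um) <= 5.0

    def test_torus_tube(self):
        vox, R, rt = 3.0, 60.0, 15.0
        n = int(2 * (R + rt) / vox) + 9
        nz = int(2 * rt / vox) + 9
        ij = (np.arange(n) - n / 2 + 0.5) * vox
        kz = (np.arange(nz) - nz / 2 + 0.5) * vox
        Z, Y, X = np.meshgrid(kz, ij, ij, indexing="ij")
        mask = (np.sqrt(X**2 + Y**2) - R) ** 2 + Z**2 <= rt**2
        vol = LabelVolume(np.where(mask, CLASS_INDEX["vessel"], 0).astype(np.uint8), vox)
        dist = mor.channel_diameters(vol)
        assert abs(dist.median_um - 30.0) <= 5.0

    def test_empty_mask(self):
        vol = LabelVolume(np.zeros((5, 5, 5), np.uint8), 5.0)
        dist = mor.channel_diameters(vol)
        assert dist.n_samples == 0
        assert math.isnan(dist.median_um)


def _ball_volume(r_um=500.0, vox=8.0, tissue="bone"):
    n = int(2 * r_um / vox) + 8
    idx = (np.arange(n) - n / 2 + 0.5) * vox
    Z, Y, X = np.meshgrid(idx, idx, idx, indexing="ij")
    mask = X**2 + Y**2 + Z**2 <= r_um**2
    return LabelVolume(np.where(mask, CLASS_INDEX[tissue], 0).astype(np.uint8), vox)


class TestWallThickness:
    def test_hollow_cylinder_fully_supplied(self):
        vox = 8.0
        ro, ri = 400.0, 280.0  # wall 120 um < 150 um limit
        n = int(2 * (ro + 40) / vox)
        ij = (np.arange(n) - n / 2 + 0.5) * vox
        X, Y = np.meshgrid(ij, ij)
        ann = (X**2 + Y**2 <= ro**2) & (X**2 + Y**2 >= ri**2)
        data = np.zeros((40, n, n), np.uint8)
        data[4:-4, ann] = CLASS_INDEX["bone"]
        rep = mor.wall_thickness(LabelVolume(data, vox), "bone", 150.0)
        assert rep.fully_diffusion_supplied
        assert rep.flagged_fraction_pct == 0.0
        # inscribed-sphere thickness reads slightly low on curved shells
        assert abs(rep.thickness_median_um - 120.0) <= 2.5 * vox

    def test_solid_sphere_core_fraction(self):
        rep = mor.wall_thickness(_ball_volume(), "bone", 150.0)
        expected = 100.0 * (350.0 / 500.0) ** 3
        assert abs(rep.flagged_fraction_pct - expected) <= 2.0
        assert not rep.fully_diffusion_supplied

    def test_plate_at_boundary(self):
        vox = 10.0
        data = np.zeros((60, 50, 50), np.uint8)
        data[10:10 + int(300 / vox), :, :] = CLASS_INDEX["bone"]  # 300 um plate
        rep = mor.wall_thickness(LabelVolume(data, vox), "bone", 150.0)
        # limiting case: half-thickness equals the limit, tolerance one voxel
        assert rep.flagged_fraction_pct <= 100.0 * vox / 300.0
        assert abs(rep.thickness_median_um - 300.0) <= 2 * vox

    def test_absent_class_rejected(self):
        vol = LabelVolume(np.zeros((5, 5, 5), np.uint8), 5.0)
        with pytest.raises(mor.MorphometryError, match="absent"):
            mor.wall_thickness(vol, "bone")


class TestCompareModalities:
    def _report(self, volumes):
        rep = mor.MorphometryReport()
        for name, cls_vols in volumes.items():
            rep.add(mor.StructureReport(name=name, class_volumes_um3=cls_vols,
                                        volume_method="voxel-count"))
        return rep

    def test_identical_reports(self):
        a = self._report({"malleus": {"bone": 1e8, "vessel": 1e6}})
        table = mor.compare_modalities(a, a)
        assert (table["abs_diff_um3"] == 0.0).all()
        assert (table["rel_diff_pct"].fillna(0.0) == 0.0).all()

    def test_differences_reported(self):
        a = self._report({"incus": {"bone": 1e8}})
        b = self._report({"incus": {"bone": 1.1e8}})
        table = mor.compare_modalities(a, b)
        assert table.loc[0, "rel_diff_pct"] == pytest.approx(10.0)

    def test_disjoint_structures_rejected(self):
        a = self._report({"malleus": {"bone": 1.0}})
        b = self._report({"stapes": {"bone": 1.0}})
        with pytest.raises(mor.MorphometryError, match="common"):
            mor.compare_modalities(a, b)
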