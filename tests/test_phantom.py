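"""Phantom generation and virtual-grinding simulator."""

import math

import numpy as np
import pytest

from microgrind import phantom
from microgrind.phantom import (
    GrindingSchedule,
    PhantomSpec,
    PhantomError,
    Solid,
    analytic_class_volumes,
    classify_points,
    make_ossicle_phantom,
    simulate_grinding,
)

SPHERE_V = 4.0 / 3.0 * math.pi * 500.0**3


class TestPresets:
    def test_two_sphere_contents(self):
        spec = make_ossicle_phantom("two_sphere_test", 0)
        kinds = {(s.kind, s.tissue) for s in spec.solids}
        assert kinds == {("sphere", "bone"), ("tube", "vessel")}
        sphere = next(s for s in spec.solids if s.kind == "sphere")
        tube = next(s for s in spec.solids if s.kind == "tube")
        assert sphere.radius == 500.0
        assert tube.radius == 25.0
        # the tube runs through the sphere center
        assert np.allclose(np.add(tube.p0, tube.p1) / 2.0, sphere.center)

    def test_determinism(self):
        a = make_ossicle_phantom("incus_like", 7)
        b = make_ossicle_phantom("incus_like", 7)
        assert a.to_dict() == b.to_dict()

    def test_seed_sensitivity(self):
        a = make_ossicle_phantom("incus_like", 7)
        b = make_ossicle_phantom("incus_like", 8)
        da = [s for s in a.to_dict()["solids"]]
        db = [s for s in b.to_dict()["solids"]]
        assert da != db

    def test_unknown_preset(self):
        with pytest.raises(PhantomError, match="unknown phantom preset"):
            make_ossicle_phantom("nonexistent", 0)

    @pytest.mark.parametrize(
        "name",
        ["two_sphere_test", "one_percent_channel", "incus_like", "malleus_like",
         "stapes_like", "y_branch_vessel"],
    )
    def test_all_presets_valid(self, name):
        spec = make_ossicle_phantom(name, 3)
        assert isinstance(spec, PhantomSpec)
        rt = PhantomSpec.from_dict(spec.to_dict())
        assert rt.to_dict() == spec.to_dict()

    def test_collinear_fiducials_rejected(self):
        with pytest.raises(PhantomError, match="collinear"):
            PhantomSpec(
                solids=(),
                block_size=(100.0, 100.0, 100.0),
                fiducial_columns=((10.0, 10.0), (50.0, 50.0), (90.0, 90.0)),
            )


class TestAnalyticVolumes:
    def test_sphere_closed_form(self):
        spec = PhantomSpec(
            solids=(Solid("sphere", "bone", center=(505.0, 505.0, 505.0), radius=500.0),),
            block_size=(1010.0, 1010.0, 1010.0),
            fiducial_columns=((2.0, 2.0), (1008.0, 4.0), (4.0, 1008.0)),
            fiducial_radius=1.0,
        )
        vols, n = analytic_class_volumes(spec, voxel_um=2.0)
        assert n == 505**3
        assert vols["bone"] == pytest.approx(SPHERE_V, rel=0.005)

    def test_empty_spec(self):
        spec = PhantomSpec(
            solids=(),
            block_size=(100.0, 100.0, 100.0),
            fiducial_columns=((2.0, 2.0), (98.0, 4.0), (4.0, 98.0)),
            fiducial_radius=1.0,
        )
        vols, _ = analytic_class_volumes(spec, voxel_um=2.0)
        for name in ("bone", "vessel", "cartilage", "soft_tissue"):
            assert vols[name] == 0.0

    def test_sphere_with_tube(self):
        spec = make_ossicle_phantom("two_sphere_test", 0)
        vols, _ = analytic_class_volumes(spec, voxel_um=2.0)
        tube_v = math.pi * 25.0**2 * 1000.0
        assert vols["vessel"] == pytest.approx(tube_v, rel=0.01)
        # bone is the sphere minus the channel carved through it
        assert vols["bone"] == pytest.approx(SPHERE_V - tube_v, rel=0.01)

    def test_oracle_convergence(self):
        spec = PhantomSpec(
            solids=(Solid("sphere", "bone", center=(110.0, 110.0, 110.0), radius=100.0),),
            block_size=(220.0, 220.0, 220.0),
            fiducial_columns=((2.0, 2.0), (218.0, 4.0), (4.0, 218.0)),
            fiducial_radius=1.0,
        )
        v4, _ = analytic_class_volumes(spec, voxel_um=4.0)
        v2, _ = analytic_class_volumes(spec, voxel_um=2.0)
        assert abs(v4["bone"] - v2["bone"]) / v2["bone"] < 0.005

    def test_overlap_precedence(self):
        # a vessel inside cartilage inside bone: channels are never occluded
        spec = PhantomSpec(
            solids=(
                Solid("sphere", "bone", center=(50.0, 50.0, 50.0), radius=40.0),
                Solid("sphere", "cartilage", center=(50.0, 50.0, 50.0), radius=20.0),
                Solid("sphere", "vessel", center=(50.0, 50.0, 50.0), radius=10.0),
            ),
            block_size=(100.0, 100.0, 100.0),
            fiducial_columns=((2.0, 2.0), (98.0, 4.0), (4.0, 98.0)),
            fiducial_radius=1.0,
        )
        lab = classify_points(spec, np.array([[50.0, 50.0, 50.0], [50.0, 50.0, 65.0], [50.0, 50.0, 85.0]]))
        assert list(lab) == [phantom.VESSEL, phantom.CARTILAGE, phantom.BONE]


class TestSimulateGrinding:
    def test_noise_free_csv_increments(self, stain):
        spec = make_ossicle_phantom("two_sphere_test", 0)
        sched = GrindingSchedule(
            n_runs=10, abrasion_noise_sd_um=0.0,
            jitter_translation_sd_um=0.0, jitter_rotation_sd_deg=0.0,
        )
        res = simulate_grinding(spec, sched, stain=stain, seed=0)
        diffs = res.abrasion[["thickness_A_um", "thickness_B_um", "thickness_C_um"]].diff().iloc[1:]
        assert (diffs == -35).all().all()

    def test_tilted_csv_consistent_with_plane(self, stain):
        # tilt calibrated for ~35 um abrasion at mark A, ~94 um at far corner
        spec = make_ossicle_phantom("two_sphere_test", 0)
        t = 59.0 / ((1400.0 - 130.0) + (1400.0 - 130.0))
        sched = GrindingSchedule(
            n_runs=8, tilt=(t, t), abrasion_noise_sd_um=0.0,
            jitter_translation_sd_um=0.0, jitter_rotation_sd_deg=0.0,
        )
        res = simulate_grinding(spec, sched, stain=stain, seed=0)
        diffs = res.abrasion[["thickness_A_um", "thickness_B_um", "thickness_C_um"]].diff().iloc[1:]
        # per-run removal differs between the marks ...
        assert (diffs["thickness_A_um"] != diffs["thickness_B_um"]).any()
        # ... and the three CSV readings lie exactly on the stored true plane
        anchors = np.asarray(spec.fiducial_columns)
        for pose, (_, row) in zip(res.true_poses, res.abrasion.iterrows()):
            z = pose.plane_z(anchors[:, 0], anchors[:, 1])
            t3 = row[["thickness_A_um", "thickness_B_um", "thickness_C_um"]].to_numpy(float)
            assert np.all(np.abs((spec.block_size[2] - z) - t3) <= 0.5)  # caliper rounding

    def test_determinism(self, stain):
        spec = make_ossicle_phantom("two_sphere_test", 0)
        sched = GrindingSchedule(n_runs=4)
        a = simulate_grinding(spec, sched, stain=stain, seed=9)
        b = simulate_grinding(spec, sched, stain=stain, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a.images, b.images))
        assert a.abrasion.equals(b.abrasion)

    def test_thickness_monotone(self, sphere_sim):
        _, _, res = sphere_sim
        t = res.abrasion[["thickness_A_um", "thickness_B_um", "thickness_C_um"]]
        assert (t.diff().iloc[1:] <= 0).all().all()

    def test_plane_exit_stops_simulation(self, stain):
        spec = make_ossicle_phantom("two_sphere_test", 0)  # depth 1300
        sched = GrindingSchedule(n_runs=60, abrasion_noise_sd_um=0.0,
                                 jitter_translation_sd_um=0.0, jitter_rotation_sd_deg=0.0)
        res = simulate_grinding(spec, sched, stain=stain, seed=0)
        assert res.runs_completed == 37  # 37 * 35 = 1295 < 1300 < 38 * 35
        assert len(res.abrasion) == 37

    def test_truth_labels_match_classify_points(self, sphere_sim):
        spec, sched, res = sphere_sim
        k = len(res.true_labels) // 2
        pose, lab = res.true_poses[k], res.true_labels[k]
        H, W = lab.shape
        jx, jy = np.meshgrid(np.arange(W) + 0.5, np.arange(H) + 0.5)
        px = np.stack([jx.ravel(), jy.ravel()], axis=1)
        xy = pose.image_px_to_block_um(px, sched.pixel_size_um)
        pts = np.column_stack([xy, pose.plane_z(xy[:, 0], xy[:, 1])])
        assert np.array_equal(classify_points(spec, pts).reshape(H, W), lab)
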