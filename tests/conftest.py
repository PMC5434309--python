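import numpy as np
import pytest

from microgrind import phantom, registration, segmentation


@pytest.fixture(scope="session")
def stain():
    return phantom.default_stain_model()


@pytest.fixture(scope="session")
def sphere_sim(stain):
    """A default-noise grinding run of the bone-sphere + channel phantom.

    Session-scoped: rendering 34 stained slices (covering the whole sphere)
    is the expensive part shared by the registration, segmentation,
    reconstruction and morphometry tests.
    """
    spec = phantom.make_ossicle_phantom("two_sphere_test", 0)
    schedule = phantom.GrindingSchedule(n_runs=34)
    result = phantom.simulate_grinding(spec, schedule, stain=stain, seed=42)
    return spec, schedule, result


@pytest.fixture(scope="session")
def sphere_poses(sphere_sim, stain):
    spec, schedule, result = sphere_sim
    return registration.build_pose_stack(
        {p.run: im for p, im in zip(result.true_poses, result.images)},
        result.abrasion,
        np.asarray(spec.fiducial_columns),
        spec.block_size[2],
        schedule.pixel_size_um,
        expected_radius_px=spec.fiducial_radius / schedule.pixel_size_um,
        stain=stain,
    )


@pytest.fixture(scope="session")
def sphere_labelmaps(sphere_sim, stain):
    spec, schedule, result = sphere_sim
    return [
        segmentation.classify_pixels(
            im, stain, run=p.run, pixel_size_um=schedule.pixel_size_um
        )
        for p, im in zip(result.true_poses, result.images)
    ]
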