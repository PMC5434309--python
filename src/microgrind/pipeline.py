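"""Pipeline configuration and orchestration.

``run_pipeline`` sequences the five stages — (optional) simulate, register,
segment, rasterize + surface, measure — writing every stage artifact to the
working directory together with a log of input/output checksums.  Rerunning
with an identical configuration reproduces byte-identical artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as mio
from . import morphometry, phantom, reconstruction, registration, segmentation

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, run: int | None, cause: Exception):
        at = f" (run {run})" if run is not None else ""
        super().__init__(f"stage {stage!r}{at} failed: {cause}")
        self.stage = stage
        self.run = run
        self.cause = cause


@dataclass
class SimulateConfig:
    preset: str = "two_sphere_test"
    n_runs: int = 30
    nominal_abrasion_um: float = 35.0
    tilt: tuple[float, float] = (0.0, 0.0)
    abrasion_noise_sd_um: float = 2.0
    jitter_translation_sd_um: float = 10.0
    jitter_rotation_sd_deg: float = 0.5
    pixel_size_um: float = 5.0
    stain_noise_sd: float = 4.0


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; every default is printed to the log."""

    workdir: str = "out"
    seed: int = 0
    simulate: SimulateConfig | None = None
    images_dir: str | None = None
    abrasion_csv: str | None = None
    anchors_um: list | None = None
    block_depth_um: float | None = None
    pixel_size_um: float = 5.0
    fiducial_radius_um: float = 50.0
    voxel_um: float | None = None
    tilt_aware: bool = True
    smoothing_iters: int = 10
    min_area_um2: float = 200.0
    diffusion_limit_um: float = 150.0
    structures: list = field(default_factory=lambda: ["bone", "vessel"])
    allow_scale: bool = True
    structure_name: str = "specimen"

    def validate(self) -> None:
        for name in ("pixel_size_um", "fiducial_radius_um", "min_area_um2",
                     "diffusion_limit_um"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.voxel_um is not None and self.voxel_um <= 0:
            raise ConfigError("voxel_um must be positive")
        if self.simulate is None:
            if not self.images_dir or not self.abrasion_csv:
                raise ConfigError("need images_dir and abrasion_csv when not simulating")
            for p in (self.images_dir, self.abrasion_csv):
                if not Path(p).exists():
                    raise ConfigError(f"path does not exist: {p}")
            if self.anchors_um is None or self.block_depth_um is None:
                raise ConfigError("need anchors_um and block_depth_um when not simulating")


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline configuration and validate it."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("simulate", None)
    cfg = PipelineConfig(**raw)
    if sim is not None:
        if "tilt" in sim:
            sim["tilt"] = tuple(sim["tilt"])
        cfg.simulate = SimulateConfig(**sim)
    cfg.validate()
    return cfg


def _log_artifact(log_lines: list[str], stage: str, path: Path) -> None:
    line = f"{stage}: {path.name} sha256={mio.sha256_of(path)}"
    log.info(line)
    log_lines.append(line)


def run_pipeline(config: PipelineConfig) -> morphometry.MorphometryReport:
    """Execute the full pipeline described by ``config``.

    Stage order: simulate (optional) -> register -> segment -> rasterize ->
    surface -> measure.  Every stage writes its artifact under the working
    directory; any stage error aborts with the stage name and run index.
    Returns the morphometry report (also written as JSON + CSV).
    """
    config.validate()
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"config: {json.dumps(_config_dict(config), sort_keys=True)}"]

    stain = phantom.default_stain_model(
        noise_sd=config.simulate.stain_noise_sd if config.simulate else 4.0
    )

    # --- stage 1: simulate (optional) ------------------------------------
    if config.simulate is not None:
        sc = config.simulate
        try:
            spec = phantom.make_ossicle_phantom(sc.preset, seed=config.seed)
            schedule = phantom.GrindingSchedule(
                n_runs=sc.n_runs,
                nominal_abrasion_um=sc.nominal_abrasion_um,
                tilt=sc.tilt,
                abrasion_noise_sd_um=sc.abrasion_noise_sd_um,
                jitter_translation_sd_um=sc.jitter_translation_sd_um,
                jitter_rotation_sd_deg=sc.jitter_rotation_sd_deg,
                pixel_size_um=sc.pixel_size_um,
            )
            result = phantom.simulate_grinding(spec, schedule, stain=stain, seed=config.seed)
            sim_dir = workdir / "simulated"
            result.write(sim_dir)
        except Exception as e:  # noqa: BLE001
            raise StageError("simulate", None, e) from e
        _log_artifact(log_lines, "simulate", sim_dir / "abrasion.csv")
        images = {p.run: img for p, img in zip(result.true_poses, result.images)}
        abrasion = result.abrasion
        anchors = np.asarray(spec.fiducial_columns, dtype=np.float64)
        block_depth = spec.block_size[2]
        pixel_size = sc.pixel_size_um
        fid_radius_px = spec.fiducial_radius / pixel_size
    else:
        images = mio.read_slice_stack(config.images_dir)
        abrasion = mio.read_abrasion_csv(config.abrasion_csv)
        anchors = np.asarray(config.anchors_um, dtype=np.float64)
        block_depth = float(config.block_depth_um)
        pixel_size = config.pixel_size_um
        fid_radius_px = config.fiducial_radius_um / pixel_size

    # --- stage 2: register ------------------------------------------------
    try:
        poses = registration.build_pose_stack(
            images,
            abrasion,
            anchors,
            block_depth,
            pixel_size,
            expected_radius_px=fid_radius_px,
            stain=stain,
            allow_scale=config.allow_scale,
        )
    except Exception as e:  # noqa: BLE001
        raise StageError("register", None, e) from e
    poses_path = workdir / "poses.json"
    mio.write_pose_stack(poses_path, poses)
    _log_artifact(log_lines, "register", poses_path)

    # --- stage 3: segment ---------------------------------------------------
    labelmaps = []
    seg_dir = workdir / "labels"
    seg_dir.mkdir(exist_ok=True)
    for pose in poses:
        try:
            lm = segmentation.classify_pixels(
                images[pose.run], stain, run=pose.run, pixel_size_um=pixel_size
            )
        except Exception as e:  # noqa: BLE001
            raise StageError("segment", pose.run, e) from e
        labelmaps.append(lm)
        mio.write_label_png(seg_dir / mio.LABEL_IMAGE_PATTERN.format(run=pose.run), lm.labels)
    _log_artifact(log_lines, "segment", seg_dir / mio.LABEL_IMAGE_PATTERN.format(run=poses[0].run))

    # --- stage 4: reconstruct ----------------------------------------------
    try:
        vol = reconstruction.rasterize_stack(
            labelmaps, poses, voxel_um=config.voxel_um, tilt_aware=config.tilt_aware
        )
    except Exception as e:  # noqa: BLE001
        raise StageError("reconstruct", None, e) from e
    vol_path = workdir / "label_volume.nrrd"
    mio.write_nrrd(vol_path, vol)
    _log_artifact(log_lines, "reconstruct", vol_path)

    mesh_volumes: dict[str, float] = {}
    for tissue in config.structures:
        try:
            mesh = reconstruction.surface_from_volume(
                vol, tissue, smoothing_iters=config.smoothing_iters
            )
        except reconstruction.ReconstructionError as e:
            log.info("surface %s skipped: %s", tissue, e)
            continue
        except Exception as e:  # noqa: BLE001
            raise StageError("surface", None, e) from e
        mesh_path = workdir / f"surface_{tissue}.stl"
        mesh.export(mesh_path)
        mesh.export(workdir / f"surface_{tissue}.ply")
        _log_artifact(log_lines, "surface", mesh_path)
        if mesh.watertight:
            mesh_volumes[tissue] = morphometry.mesh_volume_tetra(mesh)

    # --- stage 5: measure ----------------------------------------------------
    try:
        rep = morphometry.measure_structure(
            config.structure_name,
            vol,
            mesh_volumes=mesh_volumes or None,
            diffusion_limit_um=config.diffusion_limit_um,
        )
    except Exception as e:  # noqa: BLE001
        raise StageError("measure", None, e) from e
    report = morphometry.MorphometryReport()
    report.add(rep)
    report.to_json(workdir / "report.json")
    report.to_csv(workdir / "report.csv")
    _log_artifact(log_lines, "measure", workdir / "report.json")

    (workdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return report


def _config_dict(config: PipelineConfig) -> dict:
    d = {k: v for k, v in vars(config).items() if k != "simulate"}
    d["simulate"] = vars(config.simulate) if config.simulate else None
    return json.loads(json.dumps(d, default=list))
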