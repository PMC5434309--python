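"""File formats: slice TIFFs, label PNGs, caliper CSV, pose JSON, NRRD.

All artifacts written here are re-readable by the functions in this module;
physical scale (pixel or voxel size) is always carried in metadata and never
guessed on read.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .phantom import LABEL_PALETTE, TISSUE_CLASSES, GrindingResult, PhantomSpec, TruePose
from .reconstruction import LabelVolume
from .registration import SlicePose

RUN_IMAGE_PATTERN = "run_{run:04d}.tif"
LABEL_IMAGE_PATTERN = "labels_{run:04d}.png"

_RGB_TO_CLASS = {rgb: idx for idx, rgb in LABEL_PALETTE.items()}


class FormatError(ValueError):
    pass


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Slice images
# ---------------------------------------------------------------------------

def write_slice_image(path, image: np.ndarray, pixel_size_um: float) -> None:
    """8-bit RGB TIFF with the pixel size recorded in the resolution tags."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        # resolution is pixels per centimeter
        res = 1e4 / pixel_size_um
        tifffile.imwrite(
            path,
            image,
            photometric="rgb",
            resolution=(res, res),
            resolutionunit="CENTIMETER",
            description=json.dumps({"pixel_size_um": pixel_size_um}),
        )
    else:
        iio.imwrite(path, image)


def read_slice_image(path) -> tuple[np.ndarray, float | None]:
    """Read a slice photograph; returns (image, pixel_size_um or None)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            img = page.asarray()
            px = None
            desc = page.tags.get("ImageDescription")
            if desc is not None:
                try:
                    px = json.loads(desc.value).get("pixel_size_um")
                except (json.JSONDecodeError, AttributeError):
                    px = None
            if px is None:
                res = page.tags.get("XResolution")
                unit = page.tags.get("ResolutionUnit")
                if res is not None and unit is not None and unit.value == 3:
                    num, den = res.value
                    px = 1e4 * den / num
        return img, px
    return np.asarray(iio.imread(path)), None


def read_slice_stack(image_dir) -> dict[int, np.ndarray]:
    """All run_####.tif/.png images of a directory, keyed by run index."""
    image_dir = Path(image_dir)
    images: dict[int, np.ndarray] = {}
    for p in sorted(image_dir.iterdir()):
        m = re.fullmatch(r"run_(\d{4})\.(tif|tiff|png)", p.name)
        if m:
            images[int(m.group(1))] = read_slice_image(p)[0]
    if not images:
        raise FormatError(f"no run_####.tif images found in {image_dir}")
    return images


# ---------------------------------------------------------------------------
# Label maps (palette PNGs)
# ---------------------------------------------------------------------------

def write_label_png(path, labels: np.ndarray) -> None:
    rgb = np.zeros((*labels.shape, 3), dtype=np.uint8)
    for idx, color in LABEL_PALETTE.items():
        rgb[labels == idx] = color
    iio.imwrite(path, rgb)


def read_label_png(path) -> np.ndarray:
    rgb = np.asarray(iio.imread(path))[..., :3]
    labels = np.zeros(rgb.shape[:2], dtype=np.uint8)
    for (r, g, b), idx in _RGB_TO_CLASS.items():
        labels[(rgb[..., 0] == r) & (rgb[..., 1] == g) & (rgb[..., 2] == b)] = idx
    return labels


# ---------------------------------------------------------------------------
# Abrasion CSV & poses
# ---------------------------------------------------------------------------

ABRASION_COLUMNS = ["run", "thickness_A_um", "thickness_B_um", "thickness_C_um"]


def write_abrasion_csv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, columns=ABRASION_COLUMNS)


def read_abrasion_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ABRASION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


def write_pose_stack(path, poses: list[SlicePose]) -> None:
    with open(path, "w") as fh:
        json.dump([p.to_dict() for p in poses], fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_pose_stack(path) -> list[SlicePose]:
    with open(path) as fh:
        return [SlicePose.from_dict(d) for d in json.load(fh)]


# ---------------------------------------------------------------------------
# Truth bundle
# ---------------------------------------------------------------------------

def write_grinding_result(result: GrindingResult, out_dir) -> None:
    """Write images, caliper CSV and the truth bundle of a simulation."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth_dir = out_dir / "truth"
    truth_dir.mkdir(exist_ok=True)
    px = result.pixel_size_um
    for pose, img, lab in zip(result.true_poses, result.images, result.true_labels):
        write_slice_image(out_dir / RUN_IMAGE_PATTERN.format(run=pose.run), img, px)
        write_label_png(truth_dir / LABEL_IMAGE_PATTERN.format(run=pose.run), lab)
    write_abrasion_csv(out_dir / "abrasion.csv", result.abrasion)
    bundle = {
        "spec": result.spec.to_dict(),
        "pixel_size_um": px,
        "class_palette": {TISSUE_CLASSES[i]: list(LABEL_PALETTE[i]) for i in LABEL_PALETTE},
        "poses": [
            {
                "run": p.run,
                "angle_deg": p.angle_deg,
                "tx_um": p.tx_um,
                "ty_um": p.ty_um,
                "gx": p.gx,
                "gy": p.gy,
                "c_um": p.c_um,
            }
            for p in result.true_poses
        ],
    }
    with open(truth_dir / "poses.json", "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth_bundle(out_dir) -> tuple[PhantomSpec, list[TruePose], dict[int, np.ndarray], float]:
    out_dir = Path(out_dir)
    with open(out_dir / "truth" / "poses.json") as fh:
        bundle = json.load(fh)
    spec = PhantomSpec.from_dict(bundle["spec"])
    poses = [TruePose(**d) for d in bundle["poses"]]
    labels = {
        p.run: read_label_png(out_dir / "truth" / LABEL_IMAGE_PATTERN.format(run=p.run))
        for p in poses
    }
    return spec, poses, labels, float(bundle["pixel_size_um"])


# ---------------------------------------------------------------------------
# NRRD label volumes
# ---------------------------------------------------------------------------
# Minimal NRRD0004 subset: unsigned char raster, raw or gzip encoding, with
# voxel size in "space directions" and origin in "space origin".

def write_nrrd(path, vol: LabelVolume, compressed: bool = True) -> None:
    data = vol.data  # (z, y, x) C-order
    v = vol.voxel_um
    ox, oy, oz = vol.origin_um
    header = [
        "NRRD0004",
        "# label volume written by microgrind",
        "type: unsigned char",
        "dimension: 3",
        "space: right-anterior-superior",
        f"sizes: {data.shape[2]} {data.shape[1]} {data.shape[0]}",
        f"space directions: ({v},0,0) (0,{v},0) (0,0,{v})",
        "kinds: domain domain domain",
        "endian: little",
        f"encoding: {'gzip' if compressed else 'raw'}",
        f"space origin: ({ox},{oy},{oz})",
        "",
        "",
    ]
    # sizes are fastest-to-slowest: x y z for C-ordered (z, y, x) data
    raw = data.tobytes()
    if compressed:
        raw = gzip.compress(raw, mtime=0)
    with open(path, "wb") as fh:
        fh.write("\n".join(header).encode("ascii"))
        fh.write(raw)


def _parse_vector_triplet(text: str) -> list[tuple[float, ...]]:
    return [
        tuple(float(x) for x in m.group(1).split(","))
        for m in re.finditer(r"\(([^)]*)\)", text)
    ]


def read_nrrd(path) -> LabelVolume:
    with open(path, "rb") as fh:
        blob = fh.read()
    head_end = blob.find(b"\n\n")
    if not blob.startswith(b"NRRD") or head_end < 0:
        raise FormatError(f"{path}: not an NRRD file")
    fields = {}
    for line in blob[:head_end].decode("ascii").splitlines()[1:]:
        if line.startswith("#") or ":" not in line:
            continue
        key, val = line.split(":", 1)
        fields[key.strip()] = val.strip()
    if fields.get("type") not in ("unsigned char", "uchar", "uint8"):
        raise FormatError(f"{path}: unsupported NRRD type {fields.get('type')!r}")
    if "space directions" not in fields:
        raise FormatError(f"{path}: missing voxel-size metadata (space directions)")
    dirs = _parse_vector_triplet(fields["space directions"])
    steps = [np.linalg.norm(d) for d in dirs]
    if not np.allclose(steps, steps[0]):
        raise FormatError(f"{path}: anisotropic voxels not supported")
    sizes = [int(s) for s in fields["sizes"].split()]
    origin = (0.0, 0.0, 0.0)
    if "space origin" in fields:
        origin = _parse_vector_triplet(fields["space origin"])[0]
    raw = blob[head_end + 2:]
    if fields.get("encoding") == "gzip":
        raw = gzip.decompress(raw)
    elif fields.get("encoding") != "raw":
        raise FormatError(f"{path}: unsupported encoding {fields.get('encoding')!r}")
    nx, ny, nz = sizes
    data = np.frombuffer(raw, dtype=np.uint8).reshape(nz, ny, nx)
    return LabelVolume(data=data.copy(), voxel_um=float(steps[0]), origin_um=tuple(origin))


# ---------------------------------------------------------------------------
# TIFF label-volume stacks
# ---------------------------------------------------------------------------

def write_label_volume_tiff(path, vol: LabelVolume) -> None:
    res = 1e4 / vol.voxel_um
    tifffile.imwrite(
        path,
        vol.data,
        photometric="minisblack",
        resolution=(res, res),
        resolutionunit="CENTIMETER",
        description=json.dumps(
            {"voxel_um": vol.voxel_um, "origin_um": list(vol.origin_um)}, sort_keys=True
        ),
    )


def read_label_volume_tiff(path) -> LabelVolume:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].tags.get("ImageDescription")
        meta = None
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except json.JSONDecodeError:
                meta = None
        if not meta or "voxel_um" not in meta:
            raise FormatError(
                f"{path}: TIFF stack lacks voxel-size metadata; physical scale "
                "is never guessed"
            )
    return LabelVolume(
        data=np.asarray(data, dtype=np.uint8),
        voxel_um=float(meta["voxel_um"]),
        origin_um=tuple(meta.get("origin_um", (0.0, 0.0, 0.0))),
    )


def import_external_label_volume(path) -> LabelVolume:
    """Load an externally produced label volume (NRRD or TIFF stack).

    This is the entry point for e.g. a uCT-derived calcified/not-calcified
    segmentation so it can be compared against a histology reconstruction.
    Files without voxel-size metadata are rejected.
    """
    path = Path(path)
    if path.suffix.lower() == ".nrrd":
        return read_nrrd(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return read_label_volume_tiff(path)
    raise FormatError(f"{path}: unsupported volume format {path.suffix!r}")
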