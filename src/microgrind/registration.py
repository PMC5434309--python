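"""Recover the full 3D pose of each ground plane.

Each slice photograph contains the cross-sections of three vertical fiducial
columns.  Detecting their centers and fitting a least-squares similarity
(2D Procrustes) against the known column anchors recovers the in-plane
placement of the photograph; solving the exact 3x3 linear system through the
three caliper thickness readings recovers the (possibly inclined) cut plane.
Together these give a :class:`SlicePose` per run — the software equivalent of
stacking ring markers at the measured abrasion intervals in a CAD program.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure

from .phantom import FIDUCIAL, StainModel, default_stain_model

log = logging.getLogger(__name__)


class FiducialDetectionError(RuntimeError):
    """Fewer than three fiducial candidates were found."""


class ReflectionError(ValueError):
    """The point correspondence would require a mirror transform."""


class SingularGeometryError(ValueError):
    """Fiducial anchors are collinear; the plane is underdetermined."""


class PoseStackError(ValueError):
    """Inconsistent image/CSV stack (missing runs, non-monotone planes)."""


def canonical_fiducial_order(points: np.ndarray) -> np.ndarray:
    """Order three 2D points canonically: A, then B, C counter-clockwise.

    A is the point with the lowest ``x * 1e6 + y`` rank; B and C are the
    remaining two ordered so that the triangle A-B-C has positive signed
    area.  Applying the same rule in image and block coordinates yields
    consistent correspondences because slices are never mirrored.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.shape != (3, 2):
        raise ValueError("expected exactly three 2D points")
    order = np.argsort(pts[:, 0] * 1e6 + pts[:, 1])
    a, b, c = pts[order]
    cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
    if cross < 0:
        order[[1, 2]] = order[[2, 1]]
    return order


@dataclass(frozen=True)
class FiducialSet:
    """Three detected fiducial centers (pixel-center coords) labeled A/B/C."""

    centers_px: np.ndarray  # (3, 2) as (x, y), sub-pixel
    confidences: np.ndarray  # (3,)
    run: int | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.centers_px, dtype=np.float64)
        d = np.linalg.norm(c[[0, 0, 1]] - c[[1, 2, 2]], axis=1)
        if np.any(d <= 5.0):
            raise ValueError("fiducial centers closer than 5 px")
        area2 = abs(
            (c[1, 0] - c[0, 0]) * (c[2, 1] - c[0, 1])
            - (c[1, 1] - c[0, 1]) * (c[2, 0] - c[0, 0])
        )
        if area2 <= 0:
            raise ValueError("fiducial centers are collinear")


def detect_fiducials(
    image: np.ndarray,
    expected_radius_px: float,
    stain: StainModel | None = None,
    run: int | None = None,
) -> FiducialSet:
    """Locate the three fiducial disk cross-sections in a stained photograph.

    Pixels are gated by Mahalanobis distance to the fiducial stain color,
    cleaned morphologically, and connected components are scored by how
    closely their area matches the expected disk area.  The three
    highest-confidence sub-pixel centroids are returned in canonical A/B/C
    order.  A fourth candidate scoring within 90 % of the third triggers an
    ambiguity warning in the log.
    """
    if stain is None:
        stain = default_stain_model()
    img = np.asarray(image, dtype=np.float64)
    mu = np.asarray(stain.means["fiducial"])
    cov = np.asarray(stain.covs["fiducial"], dtype=np.float64)
    # Floor the gate width: rendered colors are quantized to 8 bits, so a
    # nearly noise-free model would otherwise reject every pixel.
    cov = cov + np.eye(3) * 4.0
    icov = np.linalg.inv(cov)
    d = img - mu
    maha2 = np.einsum("...i,ij,...j->...", d, icov, d)
    mask = maha2 < 25.0  # 5-sigma gate

    mask = ndi.binary_opening(mask, structure=np.ones((3, 3), bool))
    lab, n = ndi.label(mask)
    if n < 3:
        raise FiducialDetectionError(
            f"run {run}: found {n} fiducial candidates, need 3"
        )
    expected_area = math.pi * expected_radius_px**2
    props = measure.regionprops(lab)
    scored = []
    for p in props:
        conf = math.exp(-abs(p.area - expected_area) / expected_area)
        # centroid is in index space; +0.5 converts to pixel-center coords
        cy, cx = p.centroid
        scored.append((conf, cx + 0.5, cy + 0.5))
    scored.sort(key=lambda s: -s[0])
    if len(scored) < 3:
        raise FiducialDetectionError(f"run {run}: found {len(scored)} candidates")
    if len(scored) >= 4 and scored[3][0] >= 0.9 * scored[2][0]:
        log.warning(
            "run %s: ambiguous fiducial detection (4th candidate confidence "
            "%.3f vs 3rd %.3f); keeping top 3",
            run,
            scored[3][0],
            scored[2][0],
        )
    top = scored[:3]
    centers = np.array([[s[1], s[2]] for s in top])
    confs = np.array([s[0] for s in top])
    order = canonical_fiducial_order(centers)
    return FiducialSet(centers_px=centers[order], confidences=confs[order], run=run)


@dataclass(frozen=True)
class SimilarityTransform:
    """In-plane similarity mapping image pixels to block um.

    ``block = scale * R(angle) @ (px * pixel_size) + (tx, ty)``
    """

    angle_deg: float
    tx_um: float
    ty_um: float
    scale: float
    pixel_size_um: float
    residual_px: float = 0.0

    def matrix(self) -> tuple[np.ndarray, np.ndarray]:
        th = math.radians(self.angle_deg)
        R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        return self.scale * R, np.array([self.tx_um, self.ty_um])

    def image_px_to_block_um(self, pts_px: np.ndarray) -> np.ndarray:
        A, t = self.matrix()
        return np.asarray(pts_px, dtype=np.float64) * self.pixel_size_um @ A.T + t

    def block_um_to_image_px(self, pts_um: np.ndarray) -> np.ndarray:
        A, t = self.matrix()
        return (np.asarray(pts_um, dtype=np.float64) - t) @ np.linalg.inv(A).T / self.pixel_size_um


def estimate_inplane_transform(
    found: FiducialSet,
    reference_anchors_um: np.ndarray,
    pixel_size_um: float,
    allow_scale: bool = True,
    scale_bounds: tuple[float, float] = (0.98, 1.02),
) -> SimilarityTransform:
    """Least-squares similarity (Procrustes) from detected marks to anchors.

    Three point pairs over-determine the four similarity parameters, so a
    nonzero RMS residual is possible and is reported as a drift alarm (e.g.
    fiducial stick wobble).  A correspondence requiring a reflection raises
    :class:`ReflectionError` — ground surfaces cannot be mirrored.  The
    estimated scale absorbs run-to-run photography distance changes and is
    clamped to ``scale_bounds``.
    """
    src = np.asarray(found.centers_px, dtype=np.float64) * pixel_size_um
    dst = np.asarray(reference_anchors_um, dtype=np.float64)
    dst = dst[canonical_fiducial_order(dst)]
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    sc = src - mu_s
    dc = dst - mu_d
    H = dc.T @ sc / 3.0
    U, D, Vt = np.linalg.svd(H)
    if np.linalg.det(U @ Vt) < 0:
        raise ReflectionError("fit requires a reflection; slices cannot be mirrored")
    R = U @ Vt
    var_s = float((sc**2).sum()) / 3.0
    if allow_scale:
        scale = float(D.sum()) / var_s
        scale = float(np.clip(scale, *scale_bounds))
    else:
        scale = 1.0
    t = mu_d - scale * R @ mu_s
    angle = math.degrees(math.atan2(R[1, 0], R[0, 0]))
    pred = src @ (scale * R).T + t
    residual = float(np.sqrt(((pred - dst) ** 2).sum(axis=1).mean())) / pixel_size_um
    return SimilarityTransform(
        angle_deg=angle,
        tx_um=float(t[0]),
        ty_um=float(t[1]),
        scale=scale,
        pixel_size_um=pixel_size_um,
        residual_px=residual,
    )


@dataclass(frozen=True)
class PlaneFit:
    """Cut plane ``z(x, y) = gx*x + gy*y + c`` from three caliper readings."""

    gx: float
    gy: float
    c_um: float

    @property
    def tilt_um_per_mm(self) -> float:
        return math.hypot(self.gx, self.gy) * 1000.0

    def z(self, x, y):
        return self.gx * np.asarray(x) + self.gy * np.asarray(y) + self.c_um


def plane_from_abrasion(
    thicknesses_um: np.ndarray,
    block_depth_um: float,
    anchors_um: np.ndarray,
) -> PlaneFit:
    """Exact plane through the three remaining-thickness measurements.

    Solves ``z(anchor_i) = block_depth - thickness_i`` — three unknowns,
    three equations, so the plane interpolates the readings exactly (no
    regression).
    """
    t = np.asarray(thicknesses_um, dtype=np.float64)
    anchors = np.asarray(anchors_um, dtype=np.float64)
    if t.shape != (3,) or not np.all(np.isfinite(t)):
        raise ValueError("need three finite thickness readings")
    a, b, c = anchors
    area2 = abs((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))
    span2 = max(np.ptp(anchors[:, 0]), np.ptp(anchors[:, 1])) ** 2
    if area2 <= 1e-9 * max(span2, 1.0):
        raise SingularGeometryError("anchors are collinear")
    A = np.column_stack([anchors, np.ones(3)])
    gx, gy, cc = np.linalg.solve(A, block_depth_um - t)
    return PlaneFit(gx=float(gx), gy=float(gy), c_um=float(cc))


@dataclass(frozen=True)
class SlicePose:
    """Full 3D placement of one ground plane."""

    run: int
    angle_deg: float
    tx_um: float
    ty_um: float
    scale: float
    gx: float
    gy: float
    c_um: float
    residual_px: float
    pixel_size_um: float

    @property
    def transform(self) -> SimilarityTransform:
        return SimilarityTransform(
            angle_deg=self.angle_deg,
            tx_um=self.tx_um,
            ty_um=self.ty_um,
            scale=self.scale,
            pixel_size_um=self.pixel_size_um,
            residual_px=self.residual_px,
        )

    def image_px_to_block_um(self, pts_px):
        return self.transform.image_px_to_block_um(pts_px)

    def block_um_to_image_px(self, pts_um):
        return self.transform.block_um_to_image_px(pts_um)

    def plane_z(self, x, y):
        return self.gx * np.asarray(x) + self.gy * np.asarray(y) + self.c_um

    def to_dict(self) -> dict:
        return {
            "run": self.run,
            "angle_deg": self.angle_deg,
            "tx_um": self.tx_um,
            "ty_um": self.ty_um,
            "scale": self.scale,
            "gx": self.gx,
            "gy": self.gy,
            "c_um": self.c_um,
            "residual_px": self.residual_px,
            "pixel_size_um": self.pixel_size_um,
        }

    @classmethod
    def from_dict(cls, d) -> "SlicePose":
        return cls(**{k: d[k] for k in (
            "run", "angle_deg", "tx_um", "ty_um", "scale",
            "gx", "gy", "c_um", "residual_px", "pixel_size_um")})


def build_pose_stack(
    images: dict[int, np.ndarray],
    abrasion: pd.DataFrame,
    anchors_um: np.ndarray,
    block_depth_um: float,
    pixel_size_um: float,
    expected_radius_px: float,
    stain: StainModel | None = None,
    allow_scale: bool = True,
) -> list[SlicePose]:
    """Estimate one :class:`SlicePose` per run from images plus caliper CSV.

    Runs are matched by index (CSV row order is irrelevant); a missing CSV
    row is a hard error naming the run, as is a non-monotone mean plane
    height (a physical impossibility for a grinding process).  Mean gap
    sizes are logged.
    """
    csv_by_run = {int(r["run"]): r for _, r in abrasion.iterrows()}
    anchors = np.asarray(anchors_um, dtype=np.float64)
    anchors = anchors[canonical_fiducial_order(anchors)]
    poses: list[SlicePose] = []
    for run in sorted(images):
        if run not in csv_by_run:
            raise PoseStackError(f"no abrasion CSV row for run {run}")
        row = csv_by_run[run]
        t = np.array([
            row["thickness_A_um"], row["thickness_B_um"], row["thickness_C_um"]
        ], dtype=np.float64)
        found = detect_fiducials(images[run], expected_radius_px, stain=stain, run=run)
        tf = estimate_inplane_transform(found, anchors, pixel_size_um, allow_scale=allow_scale)
        plane = plane_from_abrasion(t, block_depth_um, anchors)
        poses.append(
            SlicePose(
                run=run,
                angle_deg=tf.angle_deg,
                tx_um=tf.tx_um,
                ty_um=tf.ty_um,
                scale=tf.scale,
                gx=plane.gx,
                gy=plane.gy,
                c_um=plane.c_um,
                residual_px=tf.residual_px,
                pixel_size_um=pixel_size_um,
            )
        )
    heights = [float(np.mean(p.plane_z(anchors[:, 0], anchors[:, 1]))) for p in poses]
    bad = [poses[i + 1].run for i in range(len(poses) - 1) if heights[i + 1] <= heights[i]]
    if bad:
        raise PoseStackError(f"non-monotone mean plane height at runs {bad}")
    if len(heights) > 1:
        gaps = np.diff(heights)
        log.info(
            "pose stack: %d runs, mean gap %.2f um (min %.2f, max %.2f)",
            len(poses), gaps.mean(), gaps.min(), gaps.max(),
        )
    return poses
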