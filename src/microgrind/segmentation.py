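"""Stain-based tissue classification and contour extraction.

The stained surface photographs are segmented with a per-class Gaussian RGB
color model (an automatic stand-in for manual line tracing in a CAD program):
each pixel takes the maximum-likelihood class, followed by a small majority
filter.  Class masks are turned into sub-pixel closed contours in block
coordinates, and manual contour files in a simple CSV polyline dialect can be
imported so a real study can trace structures by hand instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from shapely.geometry import Polygon
from skimage import measure

from .phantom import CLASS_INDEX, TISSUE_CLASSES, StainModel
from .registration import SlicePose

log = logging.getLogger(__name__)

#: Euclidean RGB distance below which two class means are flagged as
#: poorly separable.
SEPARABILITY_THRESHOLD = 20.0

MIN_SAMPLES_PER_CLASS = 50


class StainFitError(ValueError):
    pass


class ContourFormatError(ValueError):
    pass


@dataclass(frozen=True)
class TissueLabelMap:
    """Per-pixel tissue class raster for one slice."""

    labels: np.ndarray  # (H, W) uint8, values index TISSUE_CLASSES
    run: int
    pixel_size_um: float

    def mask(self, tissue: str) -> np.ndarray:
        return self.labels == CLASS_INDEX[tissue]


def fit_stain_model(samples: dict[str, np.ndarray], **stain_kwargs) -> StainModel:
    """Fit per-class color mean and covariance from labeled pixel samples.

    ``samples`` maps every tissue class name to an (N, 3) uint8/float RGB
    array with at least 50 pixels.  Covariances are ridge-regularized
    (+1 intensity-unit^2 on the diagonal) so nearly constant samples stay
    positive definite.  Class means closer than the separability threshold
    trigger a ``UserWarning``.
    """
    missing = [c for c in TISSUE_CLASSES if c not in samples]
    if missing:
        raise StainFitError(f"missing sample classes: {missing}")
    means = {}
    covs = {}
    for name in TISSUE_CLASSES:
        arr = np.asarray(samples[name], dtype=np.float64)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise StainFitError(f"samples for {name!r} must be (N, 3) RGB")
        if len(arr) < MIN_SAMPLES_PER_CLASS:
            raise StainFitError(
                f"class {name!r} has {len(arr)} sample pixels, need >= {MIN_SAMPLES_PER_CLASS}"
            )
        means[name] = tuple(arr.mean(axis=0))
        cov = np.cov(arr.T) + np.eye(3)
        covs[name] = tuple(tuple(row) for row in cov)
    for i, a in enumerate(TISSUE_CLASSES):
        for b in TISSUE_CLASSES[i + 1:]:
            d = np.linalg.norm(np.subtract(means[a], means[b]))
            if d < SEPARABILITY_THRESHOLD:
                warnings.warn(
                    f"stain classes {a!r} and {b!r} are poorly separable "
                    f"(mean color distance {d:.1f})",
                    UserWarning,
                    stacklevel=2,
                )
    return StainModel(means=means, covs=covs, **stain_kwargs)


def classify_pixels(
    image: np.ndarray,
    model: StainModel,
    run: int = 0,
    pixel_size_um: float = 1.0,
    majority_radius_px: int = 1,
    model_show_through: bool = True,
) -> TissueLabelMap:
    """Per-pixel maximum-likelihood tissue class under the Gaussian model.

    Ties break toward the lowest class index in canonical order.  A majority
    filter over a square window of half-width ``majority_radius_px``
    suppresses salt noise (radius 1 by default; note it biases widths of
    structures thinner than ~3 px).

    With ``model_show_through`` (default), extra mixture components are
    placed along each resin-to-class color segment and mapped back to resin:
    structures shimmering through the transparent resin then classify as the
    surface class (resin) instead of leaking into whichever tissue color the
    blend happens to pass near.  Disable for opaque-resin preparations.
    """
    img = np.asarray(image, dtype=np.float64)
    H, W = img.shape[:2]
    flat = img.reshape(-1, 3)
    n_cls = len(TISSUE_CLASSES)
    comp_means: list[np.ndarray] = []
    comp_covs: list[np.ndarray] = []
    comp_label: list[int] = []
    resin_mu = np.asarray(model.means["resin"])
    resin_cov = np.asarray(model.covs["resin"], dtype=np.float64)
    for i, name in enumerate(TISSUE_CLASSES):
        comp_means.append(np.asarray(model.means[name]))
        comp_covs.append(np.asarray(model.covs[name], dtype=np.float64))
        comp_label.append(i)
    if model_show_through:
        w_max = model.show_through_opacity
        for i, name in enumerate(TISSUE_CLASSES):
            if name in ("resin", "fiducial"):
                continue
            mu = np.asarray(model.means[name])
            cov = np.asarray(model.covs[name], dtype=np.float64)
            for w in (w_max / 3.0, 2.0 * w_max / 3.0, w_max):
                comp_means.append(resin_mu + w * (mu - resin_mu))
                comp_covs.append(0.5 * (resin_cov + cov))
                comp_label.append(CLASS_INDEX["resin"])
    ll = np.empty((flat.shape[0], len(comp_means)))
    for i, (mu, cov) in enumerate(zip(comp_means, comp_covs)):
        icov = np.linalg.inv(cov)
        _, logdet = np.linalg.slogdet(cov)
        d = flat - mu
        ll[:, i] = -0.5 * (np.einsum("ni,ij,nj->n", d, icov, d) + logdet)
    comp = np.argmax(ll, axis=1)
    labels = np.asarray(comp_label, dtype=np.uint8)[comp].reshape(H, W)

    if majority_radius_px > 0:
        size = 2 * majority_radius_px + 1
        counts = np.empty((n_cls, H, W))
        for i in range(n_cls):
            counts[i] = ndi.uniform_filter((labels == i).astype(np.float64), size=size)
        labels = np.argmax(counts, axis=0).astype(np.uint8)
    return TissueLabelMap(labels=labels, run=run, pixel_size_um=pixel_size_um)


def deep_vessel_evidence(image: np.ndarray, model: StainModel) -> np.ndarray:
    """Soft evidence [0, 1] that a pixel shows a vessel shimmering through resin.

    Projects each pixel color onto the resin-to-vessel color axis; pixels
    classified as resin but pulled toward the vessel color score > 0.  This
    exposes sub-surface vessel courses without attempting 3D deconvolution.
    """
    img = np.asarray(image, dtype=np.float64)
    resin = np.asarray(model.means["resin"])
    vessel = np.asarray(model.means["vessel"])
    axis = vessel - resin
    t = (img - resin) @ axis / float(axis @ axis)
    return np.clip(t, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Contours
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContourPolygon:
    """One closed polygon in block um: CCW exterior ring plus CW holes."""

    tissue: str
    exterior: np.ndarray  # (N, 2), first point not repeated
    holes: tuple[np.ndarray, ...] = ()

    def shapely(self) -> Polygon:
        return Polygon(self.exterior, [h for h in self.holes])

    @property
    def area_um2(self) -> float:
        return float(self.shapely().area)


@dataclass
class ContourSet:
    """Closed polygons per tissue class for one slice, in block coordinates."""

    polygons: dict[str, list[ContourPolygon]] = field(default_factory=dict)
    run: int | None = None

    def for_class(self, tissue: str) -> list[ContourPolygon]:
        return self.polygons.get(tissue, [])

    def add(self, poly: ContourPolygon) -> None:
        self.polygons.setdefault(poly.tissue, []).append(poly)


def _ring_area(ring: np.ndarray) -> float:
    """Signed shoelace area; positive for counter-clockwise."""
    x, y = ring[:, 0], ring[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _orient(ring: np.ndarray, ccw: bool) -> np.ndarray:
    if (_ring_area(ring) > 0) != ccw:
        return ring[::-1]
    return ring


def extract_contours(
    labelmap: TissueLabelMap,
    tissue: str,
    pose: SlicePose | None = None,
    min_area_um2: float = 200.0,
) -> ContourSet:
    """Sub-pixel iso-contours of one class mask, in block coordinates.

    Marching-squares contours of the class indicator at level 0.5 are
    transformed by ``pose`` (identity if None), grouped into exterior rings
    with their holes, oriented (outer CCW, holes CW) and filtered by
    ``min_area_um2`` (default 200 um^2: below ~2 px at working magnification,
    indistinguishable from stain debris).
    """
    mask = labelmap.mask(tissue).astype(np.float64)
    px = labelmap.pixel_size_um
    padded = np.pad(mask, 1)
    raw = measure.find_contours(padded, 0.5)
    rings_um = []
    for r in raw:
        # find_contours yields (row, col) in padded index space where integer
        # coordinates are pixel centers; unpad, convert to pixel-center
        # coords, then to um.
        pts_px = np.column_stack([r[:, 1] - 1 + 0.5, r[:, 0] - 1 + 0.5])
        if np.allclose(pts_px[0], pts_px[-1]):
            pts_px = pts_px[:-1]
        if len(pts_px) < 3:
            continue
        if pose is not None:
            pts_um = pose.image_px_to_block_um(pts_px)
        else:
            pts_um = pts_px * px
        rings_um.append(pts_um)
    # group holes under exteriors by containment depth; a ring's own
    # vertices lie on it, so testing a vertex against the *other* rings
    # gives the nesting level regardless of any holes it embraces itself
    from shapely.geometry import Point

    polys = [Polygon(r) for r in rings_um]
    depth = []
    for i, r in enumerate(rings_um):
        probe = Point(r[0])
        depth.append(sum(1 for j, q in enumerate(polys) if j != i and q.contains(probe)))
    out = ContourSet(run=labelmap.run)
    for i, p in enumerate(polys):
        if depth[i] % 2 != 0:
            continue  # a hole; attached below
        holes = []
        for j, r in enumerate(rings_um):
            if j != i and depth[j] == depth[i] + 1 and p.contains(Point(r[0])):
                holes.append(_orient(rings_um[j], ccw=False))
        exterior = _orient(rings_um[i], ccw=True)
        cp = ContourPolygon(tissue=tissue, exterior=exterior, holes=tuple(holes))
        if cp.area_um2 >= min_area_um2:
            out.add(cp)
    return out


MANUAL_CONTOUR_COLUMNS = ["class", "polygon_id", "ring_id", "x_um", "y_um"]


def load_manual_contours(path, pose: SlicePose | None = None) -> ContourSet:
    """Load manually traced contours from the documented CSV polyline format.

    Columns: ``class,polygon_id,ring_id,x_um,y_um``; ring 0 is the exterior,
    higher ring ids are holes; every ring must repeat its first point as its
    last (explicitly closed) and be simple (non-self-intersecting).
    Coordinates are image-plane um and are mapped to block coordinates by
    ``pose`` if given.
    """
    df = pd.read_csv(path)
    missing = [c for c in MANUAL_CONTOUR_COLUMNS if c not in df.columns]
    if missing:
        raise ContourFormatError(f"{path}: missing columns {missing}")
    out = ContourSet()
    for (tissue, pid), poly_df in df.groupby(["class", "polygon_id"], sort=True):
        rings = {}
        for rid, ring_df in poly_df.groupby("ring_id", sort=True):
            pts = ring_df[["x_um", "y_um"]].to_numpy(dtype=np.float64)
            if len(pts) < 4 or not np.allclose(pts[0], pts[-1]):
                raise ContourFormatError(
                    f"{path}: polygon {tissue}/{pid} ring {rid} is not closed"
                )
            ring = pts[:-1]
            if not Polygon(ring).is_simple or not Polygon(ring).is_valid:
                raise ContourFormatError(
                    f"{path}: polygon {tissue}/{pid} ring {rid} self-intersects"
                )
            if pose is not None:
                ring = pose.image_px_to_block_um(ring / pose.pixel_size_um)
            rings[rid] = ring
        ring_ids = sorted(rings)
        exterior = _orient(rings[ring_ids[0]], ccw=True)
        holes = tuple(_orient(rings[r], ccw=False) for r in ring_ids[1:])
        out.add(ContourPolygon(tissue=str(tissue), exterior=exterior, holes=holes))
    return out


def write_contours(contour_set: ContourSet, path) -> None:
    """Write a :class:`ContourSet` in the manual-contour CSV dialect."""
    rows = []
    pid = 0
    for tissue in sorted(contour_set.polygons):
        for poly in contour_set.polygons[tissue]:
            for rid, ring in enumerate((poly.exterior, *poly.holes)):
                closed = np.vstack([ring, ring[:1]])
                for x, y in closed:
                    rows.append((tissue, pid, rid, x, y))
            pid += 1
    pd.DataFrame(rows, columns=MANUAL_CONTOUR_COLUMNS).to_csv(path, index=False)
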