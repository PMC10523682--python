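"""Calibrated instance morphometry: area, Feret diameters, centroid, border.

Cell size is reported both as cross-sectional area and as the minimum Feret
diameter (MinFeret) — the smallest distance between two parallel lines
enclosing the object.  MinFeret is the preferred size readout for
cardiomyocytes because, unlike area, it is nearly independent of the angle
at which an elongated cell is cut by the section plane.

Pixel model
-----------
Each pixel is treated as a unit square; Feret diameters are computed on the
convex hull of all pixel *corner* points (rotating calipers).  This matches
common image-analysis Feret implementations, gives a single pixel a
MinFeret of one pixel (not zero), and makes the measurement well defined
for degenerate one-row instances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .segmentation import LabelMap

CLASS_CM = "cardiomyocyte"
CLASS_NUCLEUS = "cm_nucleus"
CLASS_CAPILLARY = "capillary"
CLASS_REMOVED = "removed"

CLASSES = (CLASS_CM, CLASS_NUCLEUS, CLASS_CAPILLARY, CLASS_REMOVED)


@dataclass
class InstanceRecord:
    """One segmented object with its calibrated measurements."""

    instance_id: int
    cls: str
    pixel_count: int
    area_um2: float
    feret_max_um: float
    feret_min_um: float
    min_feret_angle_deg: float
    centroid_x_um: float
    centroid_y_um: float
    touches_border: bool
    reason: str = ""
    host_cm_id: int | None = None  # for nuclei: the containing cardiomyocyte


def instance_mask(labels: LabelMap, instance_id: int) -> np.ndarray:
    mask = labels.labels == instance_id
    if not mask.any():
        raise KeyError(f"instance {instance_id} not present in label map")
    return mask


def measure_area(
    labels: LabelMap, instance_id: int, microns_per_pixel: float
) -> float:
    """Calibrated area: pixel count × (µm/px)²."""
    if microns_per_pixel <= 0:
        raise ValueError("microns_per_pixel must be > 0")
    return int(instance_mask(labels, instance_id).sum()) * microns_per_pixel**2


def _pixel_corner_hull(coords: np.ndarray) -> np.ndarray:
    """Convex-hull vertices of the unit-square corners of pixel coords.

    ``coords`` is (n, 2) in (row, col); returns (m, 2) hull vertices in
    (x, y) pixel units, counter-clockwise.
    """
    rows = coords[:, 0].astype(float)
    cols = coords[:, 1].astype(float)
    corners = np.concatenate(
        [
            np.stack([cols, rows], axis=1),
            np.stack([cols + 1, rows], axis=1),
            np.stack([cols, rows + 1], axis=1),
            np.stack([cols + 1, rows + 1], axis=1),
        ]
    )
    corners = np.unique(corners, axis=0)
    hull = ConvexHull(corners)
    return corners[hull.vertices]


def feret_from_points(points: np.ndarray) -> tuple[float, float, float]:
    """(max Feret, min Feret, caliper angle°) of a convex point set.

    ``points`` are the convex-hull vertices (any planar unit).  The minimum
    Feret is attained with the caliper parallel to some hull edge, so it is
    the minimum over edges of the extent perpendicular to that edge; the
    maximum Feret is the largest pairwise vertex distance.  The returned
    angle is the direction of the restricting parallel lines, in degrees in
    [0, 180).
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least two points")
    feret_max = float(pdist(pts).max())

    feret_min = np.inf
    angle = 0.0
    n = len(pts)
    for i in range(n):
        edge = pts[(i + 1) % n] - pts[i]
        norm = np.hypot(*edge)
        if norm == 0:
            continue
        # width of the point set perpendicular to this edge
        ux, uy = edge / norm
        d = pts - pts[i]
        width = np.abs(ux * d[:, 1] - uy * d[:, 0]).max()
        if width < feret_min:
            feret_min = float(width)
            angle = float(np.degrees(np.arctan2(edge[1], edge[0])) % 180.0)
    return feret_max, feret_min, angle


def feret_diameters(
    labels: LabelMap, instance_id: int, microns_per_pixel: float
) -> tuple[float, float, float]:
    """Calibrated (max Feret µm, min Feret µm, caliper angle°) of an instance."""
    coords = np.argwhere(instance_mask(labels, instance_id))
    fmax, fmin, angle = feret_from_points(_pixel_corner_hull(coords))
    return fmax * microns_per_pixel, fmin * microns_per_pixel, angle


def touches_border(labels: LabelMap, instance_id: int) -> bool:
    """True iff any instance pixel lies on the first/last row or column."""
    mask = instance_mask(labels, instance_id)
    return bool(
        mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any()
    )


def measure_instances(
    labels: LabelMap,
    microns_per_pixel: float,
    classes: dict[int, tuple[str, str]] | None = None,
    hosts: dict[int, int] | None = None,
) -> list[InstanceRecord]:
    """Measure every labeled instance in one pass.

    ``classes`` optionally maps instance id → (class, reason); unmapped ids
    default to "removed".  ``hosts`` maps nucleus ids to their containing
    cardiomyocyte id.  Centroids are unweighted means of pixel centers
    (0-based, origin top-left, y downward) scaled to µm.
    """
    if microns_per_pixel <= 0:
        raise ValueError("microns_per_pixel must be > 0")
    arr = labels.labels
    h, w = arr.shape
    border = np.zeros(labels.n_labels + 1, dtype=bool)
    for edge in (arr[0, :], arr[-1, :], arr[:, 0], arr[:, -1]):
        border[np.unique(edge)] = True

    records: list[InstanceRecord] = []
    from scipy import ndimage as ndi

    slices = ndi.find_objects(arr, max_label=labels.n_labels)
    for instance_id, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        local = arr[sl] == instance_id
        coords = np.argwhere(local)
        coords[:, 0] += sl[0].start
        coords[:, 1] += sl[1].start
        n_px = len(coords)
        fmax, fmin, angle = feret_from_points(_pixel_corner_hull(coords))
        cls, reason = (classes or {}).get(instance_id, (CLASS_REMOVED, "unclassified"))
        records.append(
            InstanceRecord(
                instance_id=instance_id,
                cls=cls,
                pixel_count=n_px,
                area_um2=n_px * microns_per_pixel**2,
                feret_max_um=fmax * microns_per_pixel,
                feret_min_um=fmin * microns_per_pixel,
                min_feret_angle_deg=angle,
                centroid_x_um=float(coords[:, 1].mean()) * microns_per_pixel,
                centroid_y_um=float(coords[:, 0].mean()) * microns_per_pixel,
                touches_border=bool(border[instance_id]),
                reason=reason,
                host_cm_id=(hosts or {}).get(instance_id),
            )
        )
    return records
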