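"""Seedable synthetic cardiac-histology fixtures with exact ground truth.

Cross-sectioned myocardium is emulated as a Voronoi tessellation of a
jittered hexagonal lattice: convex polygonal "cells" separated by a thin
pale boundary network (the silver-stained reticulum in brightfield, the
WGA-bright membrane in fluorescence), near-white capillary lumens at cell
junctions, and darker elliptical nuclei inside a fraction of cells.

Size control
------------
The lattice spacing sets the across-flats width of the hexagonal cells, so
the requested mean cell diameter (= MinFeret) is matched by a two-pass
self-calibration: tessellate once, measure the realized mean MinFeret of
interior cells from the exact polygons, rescale the lattice, tessellate
again.  The requested diameter SD is mapped to lattice jitter and is
therefore only approximate; the mean is matched in expectation.

Ground truth is analytic: polygon vertices give exact areas and Feret
diameters before rasterization, disk/ellipse parameters give capillary and
nucleus sizes, and the contact graph comes from polygon–disk distances.
A rasterized true label map is also provided for pixel-level comparisons.

Boundary-exercising anomalies (all off by default) let a single fixture
probe every classification threshold from both sides: ``n_small_cells``
(clusters of ~55 µm² cells between the human and mouse area floors),
``n_off_color_cells`` (green-rendered cells failing the HSB window),
``n_unstained_cells`` (near-white cells, too large for the capillary
window), ``n_oversized_nuclei`` (>100 µm² nuclei inside enlarged cells),
``n_undersized_nuclei`` (<6 µm² intracellular specks) and ``n_artifacts``
(sub-1.5 µm² debris on the boundary network).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, Voronoi, cKDTree
from shapely.geometry import Point, Polygon, box

from .color import hsb_to_rgb
from .config import AnalysisConfig
from .image import (
    BRIGHTFIELD,
    FLUORESCENCE,
    MARKER,
    MEMBRANE,
    NUCLEI,
    CalibratedImage,
)
from .morphometry import feret_from_points
from .segmentation import LabelMap

KIND_CELL = "cell"
KIND_SMALL_CELL = "small_cell"
KIND_MEGA_CELL = "mega_cell"
KIND_OFF_COLOR_CELL = "off_color_cell"
KIND_UNSTAINED_CELL = "unstained_cell"
KIND_NUCLEUS = "nucleus"
KIND_OVERSIZED_NUCLEUS = "oversized_nucleus"
KIND_UNDERSIZED_NUCLEUS = "undersized_nucleus"
KIND_CAPILLARY = "capillary"
KIND_ARTIFACT = "artifact"

CELL_KINDS = (
    KIND_CELL,
    KIND_SMALL_CELL,
    KIND_MEGA_CELL,
    KIND_OFF_COLOR_CELL,
    KIND_UNSTAINED_CELL,
)
NUCLEUS_KINDS = (KIND_NUCLEUS, KIND_OVERSIZED_NUCLEUS, KIND_UNDERSIZED_NUCLEUS)


@dataclass
class TissueSpec:
    """Generation parameters for one synthetic tissue field.

    Defaults emulate a healthy (sham) mouse left-ventricle cross-section
    field: 433 × 270 µm scanned at 0.25 µm/px (40× objective), mean cell
    diameter 14 µm, roughly one capillary per cell junction pair and a
    visible nucleus in about a third of the cells.
    """

    field_size_um: tuple[float, float] = (433.0, 270.0)
    microns_per_pixel: float = 0.25
    cell_diameter_um: tuple[float, float] = (14.0, 4.0)  # (mean, SD)
    capillary_density: float = 0.8  # probability of a capillary per junction
    nucleus_fraction: float = 0.32
    noise_sd: float = 2.0
    seed: int = 0
    n_cells: int | None = None  # overrides cell_diameter mean when set
    aspect_ratio: float = 1.0  # >1 elongates cells along x (longitudinal cut)
    boundary_halfwidth_um: float = 0.15
    capillary_radius_um: tuple[float, float] = (1.2, 2.2)
    nucleus_axes_um: tuple[float, float] = (2.8, 1.6)
    contact_distance_um: float = 2.0  # generating distance for contact truth
    expression_fractions: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0)
    n_small_cells: int = 0
    n_off_color_cells: int = 0
    n_unstained_cells: int = 0
    n_oversized_nuclei: int = 0
    n_undersized_nuclei: int = 0
    n_artifacts: int = 0

    def __post_init__(self) -> None:
        w, h = self.field_size_um
        if w <= 0 or h <= 0:
            raise ValueError("field_size_um must be positive")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be > 0")
        mean, sd = self.cell_diameter_um
        if mean <= 0 or sd < 0:
            raise ValueError("cell_diameter_um mean must be > 0 and SD >= 0")
        if self.n_cells is not None and self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not (0 <= self.capillary_density <= 1):
            raise ValueError("capillary_density must be in [0, 1]")
        if not (0 <= self.nucleus_fraction <= 1):
            raise ValueError("nucleus_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TissueSpec":
        d = json.loads(text)
        for key in (
            "field_size_um",
            "cell_diameter_um",
            "capillary_radius_um",
            "nucleus_axes_um",
            "expression_fractions",
        ):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class _Cell:
    gt_id: int
    polygon: Polygon
    kind: str
    touches_border: bool
    expression_fraction: float = 0.0


@dataclass
class _Nucleus:
    gt_id: int
    host_cell: int
    center: tuple[float, float]
    axes: tuple[float, float]  # semi-axes, µm
    angle_rad: float
    kind: str


@dataclass
class _Capillary:
    gt_id: int
    center: tuple[float, float]
    radius_um: float


@dataclass
class _Artifact:
    gt_id: int
    center: tuple[float, float]
    half_um: float  # half side length of the square speck


@dataclass
class TissueGeometry:
    """Exact generating geometry of one synthetic field."""

    spec: TissueSpec
    cells: list[_Cell]
    nuclei: list[_Nucleus]
    capillaries: list[_Capillary]
    artifacts: list[_Artifact]
    seeds_um: np.ndarray  # Voronoi seed points of the cells, (n, 2) x/y µm

    @property
    def shape_px(self) -> tuple[int, int]:
        w, h = self.spec.field_size_um
        mpp = self.spec.microns_per_pixel
        return int(round(h / mpp)), int(round(w / mpp))


@dataclass
class GroundTruth:
    """True label map, per-instance truth table and contact graph."""

    label_map: LabelMap
    table: pd.DataFrame  # one row per gt_id
    contacts: list[tuple[int, int]]  # (cell gt_id, capillary gt_id)
    cell_assignment: np.ndarray  # nearest-cell gt_id for every pixel
    boundary_mask: np.ndarray  # pale boundary network pixels
    edge_dist_um: np.ndarray  # distance of each pixel to its Voronoi edge


# --------------------------------------------------------------------------
# tessellation


def _hex_lattice_in(
    region: Polygon, spacing: float, aspect: float, jitter_frac: float, rng
) -> np.ndarray:
    """Jittered triangular lattice filling ``region`` (a rectangle)."""
    minx, miny, maxx, maxy = region.bounds
    sx = spacing * np.sqrt(aspect)
    sy = spacing / np.sqrt(aspect) * np.sqrt(3) / 2
    xs = np.arange(minx - 1.5 * spacing, maxx + 1.5 * spacing, sx)
    ys = np.arange(miny - 1.5 * spacing, maxy + 1.5 * spacing, sy)
    pts = []
    for j, y in enumerate(ys):
        off = (j % 2) * sx / 2
        for x in xs:
            pts.append((x + off, y))
    pts = np.asarray(pts, dtype=float)
    pts += rng.normal(0.0, jitter_frac * spacing, size=pts.shape)
    # mirroring (for finite Voronoi cells) requires seeds inside the region
    eps = 1e-3
    keep = (
        (pts[:, 0] > minx + eps)
        & (pts[:, 0] < maxx - eps)
        & (pts[:, 1] > miny + eps)
        & (pts[:, 1] < maxy - eps)
    )
    return pts[keep]


def _finite_voronoi_polygons(
    points: np.ndarray, mirror_box: Polygon, field: Polygon
) -> dict[int, Polygon]:
    """Clip the Voronoi cells of ``points`` to the field rectangle.

    Points are mirrored across the four edges of ``mirror_box`` (an
    extended field) so every cell is finite; the cells are then cropped to
    the true field.  Because the crop line cuts through cell bodies,
    border cells share a solid stretch of the image edge instead of the
    degenerate point contacts a border-aligned tessellation produces.
    """
    minx, miny, maxx, maxy = mirror_box.bounds
    mirrored = [points]
    for axis, lo, hi in ((0, minx, maxx), (1, miny, maxy)):
        for edge in (lo, hi):
            m = points.copy()
            m[:, axis] = 2 * edge - m[:, axis]
            mirrored.append(m)
    allpts = np.vstack(mirrored)
    vor = Voronoi(allpts)
    out: dict[int, Polygon] = {}
    for i in range(len(points)):
        region = vor.regions[vor.point_region[i]]
        if not region or -1 in region:
            continue
        poly = Polygon(vor.vertices[region])
        clipped = poly.intersection(field)
        if not clipped.is_empty and clipped.area > 1e-6:
            if clipped.geom_type == "MultiPolygon":
                clipped = max(clipped.geoms, key=lambda g: g.area)
            out[i] = clipped
    return out


def _regularize_border(
    pts: np.ndarray,
    polys: dict[int, Polygon],
    ext: Polygon,
    field: Polygon,
    clear_um: float,
    max_iter: int = 10,
) -> tuple[np.ndarray, dict[int, Polygon]]:
    """Remove pixel-scale ambiguities of the tessellation at the field edge.

    Cells must either cross the image border transversally (solid contact)
    or stay at least ``clear_um`` away from it; tessellation *vertices*
    hovering just inside the border create tangent contacts and
    border-parallel boundary strips whose border status is undecidable at
    pixel resolution.  Offending seeds are nudged perpendicular to the
    nearest edge (inward for in-field seeds, outward for margin seeds) and
    the tessellation is rebuilt, deterministically.
    """
    w_lo, h_lo, w_hi, h_hi = field.bounds
    for _ in range(max_iter):
        bad: set[int] = set()
        for i, p in polys.items():
            contact = p.exterior.intersection(field.exterior).length
            if 1e-9 < contact < 2.0:  # corner clip: contact too short
                bad.add(i)
                continue
            if contact < 1e-9 and p.exterior.distance(field.exterior) < 0.6 * clear_um:
                bad.add(i)  # interior cell hugging the border
                continue
            for x, y in p.exterior.coords[:-1]:
                d = min(x - w_lo, w_hi - x, y - h_lo, h_hi - y)
                if 0.01 < d < clear_um:
                    bad.add(i)
                    break
        if not bad:
            break
        for i in bad:
            x, y = pts[i]
            dists = {
                "x_lo": x - w_lo,
                "x_hi": w_hi - x,
                "y_lo": y - h_lo,
                "y_hi": h_hi - y,
            }
            edge = min(dists, key=lambda k: abs(dists[k]))
            inside = field.contains(Point(x, y))
            step = 1.5 if inside else -1.5
            if edge == "x_lo":
                pts[i][0] += step
            elif edge == "x_hi":
                pts[i][0] -= step
            elif edge == "y_lo":
                pts[i][1] += step
            else:
                pts[i][1] -= step
        np.clip(pts[:, 0], ext.bounds[0] + 0.01, ext.bounds[2] - 0.01, out=pts[:, 0])
        np.clip(pts[:, 1], ext.bounds[1] + 0.01, ext.bounds[3] - 0.01, out=pts[:, 1])
        polys = _finite_voronoi_polygons(pts, ext, field)
    return pts, polys


def _regularize_short_edges(
    pts: np.ndarray,
    polys: dict[int, Polygon],
    ext: Polygon,
    field: Polygon,
    min_len_um: float = 2.0,
    max_iter: int = 6,
) -> tuple[np.ndarray, dict[int, Polygon]]:
    """Lengthen near-degenerate Voronoi edges (almost-cocircular seeds).

    Two boundary bands meeting along a very short edge enclose a pale
    pocket large enough to segment as a spurious instance.  Moving the two
    seeds that share a short edge toward each other strengthens their
    Delaunay edge and lengthens the Voronoi edge between them.
    """
    for _ in range(max_iter):
        # vertex key -> list of (cell, vertex index)
        owners: dict[tuple[int, int], list[int]] = {}
        for i, p in polys.items():
            for x, y in p.exterior.coords[:-1]:
                owners.setdefault((int(round(x * 100)), int(round(y * 100))), []).append(i)
        moved = False
        done: set[tuple[int, int]] = set()
        for i, p in polys.items():
            coords = list(p.exterior.coords[:-1])
            n_v = len(coords)
            for k in range(n_v):
                x1, y1 = coords[k]
                x2, y2 = coords[(k + 1) % n_v]
                k1 = (int(round(x1 * 100)), int(round(y1 * 100)))
                k2 = (int(round(x2 * 100)), int(round(y2 * 100)))
                if (
                    np.hypot(x2 - x1, y2 - y1) < min_len_um
                    and len(owners.get(k1, ())) >= 3
                    and len(owners.get(k2, ())) >= 3
                ):
                    shared = set(owners[k1]) & set(owners[k2])
                    if len(shared) == 2:
                        a, b = sorted(shared)
                        if (a, b) not in done:
                            done.add((a, b))
                            step = 0.4 * (pts[b] - pts[a]) / max(
                                np.linalg.norm(pts[b] - pts[a]), 1e-9
                            )
                            pts[a] += step
                            pts[b] -= step
                            moved = True
                # acute corner of this cell at an interior junction vertex:
                # the thin wedge beyond the watershed line segments as a
                # spurious pale pocket; moving the seed toward the vertex
                # widens the angle
                x0, y0 = coords[k - 1]
                if len(owners.get(k1, ())) >= 3:
                    v1 = np.array([x0 - x1, y0 - y1])
                    v2 = np.array([x2 - x1, y2 - y1])
                    nrm = np.linalg.norm(v1) * np.linalg.norm(v2)
                    if nrm > 1e-12:
                        ang = np.degrees(
                            np.arccos(np.clip(np.dot(v1, v2) / nrm, -1, 1))
                        )
                        if ang < 30.0:
                            to_v = np.array([x1, y1]) - pts[i]
                            d = np.linalg.norm(to_v)
                            if d > 1e-9:
                                pts[i] += 0.5 * to_v / d
                                moved = True
        if not moved:
            break
        polys = _finite_voronoi_polygons(pts, ext, field)
    return pts, polys


def _interior_mean_minferet(polys: dict[int, Polygon], field: Polygon) -> float:
    vals = []
    for poly in polys.values():
        if poly.exterior.distance(field.exterior) < 1e-6:
            continue  # border cell, clipped
        pts = np.asarray(poly.exterior.coords[:-1])
        _, fmin, _ = feret_from_points(pts[ConvexHull(pts).vertices])
        vals.append(fmin)
    return float(np.mean(vals)) if vals else float("nan")


def generate_tissue(spec: TissueSpec) -> tuple[TissueGeometry, GroundTruth]:
    """Build the polygon tessellation and its exact ground truth."""
    w, h = spec.field_size_um
    field = box(0.0, 0.0, w, h)
    mean_d, sd_d = spec.cell_diameter_um

    if spec.n_cells == 1:
        return _single_cell_tissue(spec, field)

    if spec.n_cells is not None:
        # spacing such that n_cells hexagons of area (√3/2)s² tile the field
        spacing = float(np.sqrt(2.0 * w * h / (np.sqrt(3) * spec.n_cells)))
        if spacing < 4 * spec.microns_per_pixel:
            raise ValueError(
                f"infeasible packing: {spec.n_cells} cells in a "
                f"{w:.0f}x{h:.0f} um field"
            )
        calibrate = False
    else:
        spacing = mean_d
        calibrate = True
    jitter_frac = min(0.5 * sd_d / mean_d, 0.35) if mean_d > 0 else 0.0

    def _tessellate(s: float):
        rng = np.random.default_rng([spec.seed, 1])
        delta = 0.45 * s
        ext = box(-delta, -delta, w + delta, h + delta)
        pts = _hex_lattice_in(ext, s, spec.aspect_ratio, jitter_frac, rng)
        return pts, ext, _finite_voronoi_polygons(pts, ext, field)

    clear_um = max(1.0, 5 * spec.microns_per_pixel)
    pts, ext, polys = _tessellate(spacing)
    pts, polys = _regularize_border(pts, polys, ext, field, clear_um=clear_um)
    pts, polys = _regularize_short_edges(pts, polys, ext, field)
    if calibrate:
        # rescale until the realized mean MinFeret of interior cells (after
        # regularization, which shifts sizes slightly) matches the request
        for _ in range(3):
            realized = _interior_mean_minferet(polys, field)
            if not (np.isfinite(realized) and realized > 0):
                break
            if abs(realized - mean_d) / mean_d < 0.002:
                break
            spacing = spacing * mean_d / realized
            pts, ext, polys = _tessellate(spacing)
            pts, polys = _regularize_border(pts, polys, ext, field, clear_um=clear_um)
            pts, polys = _regularize_short_edges(pts, polys, ext, field)

    rng = np.random.default_rng([spec.seed, 2])

    # --- anomaly site selection on the lattice --------------------------
    # anomaly sites stay deep in the field so inserting or deleting their
    # seeds cannot disturb the regularized border geometry
    interior_ids = [
        i
        for i, p in polys.items()
        if p.exterior.distance(field.exterior) > 2 * spacing
    ]
    rng.shuffle(interior_ids)
    site_kind: dict[int, str] = {}
    cursor = 0

    def _take(n: int) -> list[int]:
        nonlocal cursor
        out = interior_ids[cursor: cursor + n]
        cursor += n
        return out

    small_sites = _take(spec.n_small_cells)
    mega_sites = _take(spec.n_oversized_nuclei)  # each hosts one big nucleus
    off_color_sites = set(_take(spec.n_off_color_cells))
    unstained_sites = set(_take(spec.n_unstained_cells))

    pts_list = [pts]
    drop = set()
    tree = cKDTree(pts)
    small_centers: list[int] = []
    for s in small_sites:
        # locally refine the lattice: the site and its six neighbors are
        # replaced by a √3-finer hexagonal patch whose center cell is a
        # clean hexagon of ~1/3 the normal area (≈57 µm² at the 14 µm
        # default diameter, between the human and mouse size floors)
        _, nbrs = tree.query(pts[s], k=7)
        for nb in nbrs:
            drop.add(int(nb))
        # ring radius such that the center hexagon *measures* ~42 µm² —
        # clearly below both cardiomyocyte area floors (50 µm² human,
        # 60 µm² mouse) yet far above the capillary/nucleus scale — after
        # the watershed line floods away the boundary-band share of its
        # perimeter; the six ring cells absorb the remaining territory and
        # stay far above both floors
        target = 42.0
        perim = 6 * np.sqrt(2 * 52.0 / (3 * np.sqrt(3)))
        loss = perim * (spec.boundary_halfwidth_um + 0.5 * spec.microns_per_pixel)
        rho = float(np.sqrt(2 * (target + loss) / np.sqrt(3)))
        theta = rng.uniform(0, 2 * np.pi)
        angles = theta + np.arange(6) * np.pi / 3
        patch = np.vstack(
            [
                pts[s],
                pts[s] + rho * np.stack([np.cos(angles), np.sin(angles)], axis=1),
            ]
        )
        # center of the patch is its first point
        small_centers.append(sum(len(p) for p in pts_list[1:]))
        pts_list.append(patch)
    for s in mega_sites:
        # delete this site's lattice neighbors: one enlarged cell
        _, nbrs = tree.query(pts[s], k=7)
        for nb in nbrs[1:]:
            drop.add(int(nb))
        site_kind[s] = KIND_MEGA_CELL

    if drop or len(pts_list) > 1:
        keep_mask = np.ones(len(pts), dtype=bool)
        keep_mask[list(drop)] = False
        keep_idx = np.flatnonzero(keep_mask)
        remap = {int(old): k for k, old in enumerate(keep_idx)}
        new_pts = np.vstack([pts[keep_mask]] + pts_list[1:])
        n_base = len(keep_idx)
        site_kind = {
            remap[i]: kind for i, kind in site_kind.items() if i in remap
        }
        for off in small_centers:
            site_kind[n_base + off] = KIND_SMALL_CELL
        off_color_sites = {remap[i] for i in off_color_sites if i in remap}
        unstained_sites = {remap[i] for i in unstained_sites if i in remap}
        pts = new_pts
        polys = _finite_voronoi_polygons(pts, ext, field)
        # deleting/inserting seeds can still ripple outward; re-verify the
        # border and junction regularity on the final tessellation
        pts, polys = _regularize_border(
            pts, polys, ext, field, clear_um=max(1.0, 5 * spec.microns_per_pixel)
        )
        pts, polys = _regularize_short_edges(pts, polys, ext, field)
    for i in off_color_sites:
        site_kind[i] = KIND_OFF_COLOR_CELL
    for i in unstained_sites:
        site_kind[i] = KIND_UNSTAINED_CELL

    # --- cells in raster order of their seed ----------------------------
    order = sorted(polys.keys(), key=lambda i: (pts[i][1], pts[i][0]))
    cells: list[_Cell] = []
    seed_rows = []
    gt_id = 0
    id_by_site: dict[int, int] = {}
    expr_cycle = spec.expression_fractions or (0.0,)
    k_expr = 0
    border_tol = 2 * spec.microns_per_pixel
    for site in order:
        poly = polys[site]
        gt_id += 1
        # border cells share a positive-length stretch of the field edge;
        # a single-point touch (Voronoi vertex on the edge) does not count
        near = poly.exterior.distance(field.exterior) < border_tol
        border = near and poly.exterior.intersection(field.exterior).length > 1e-9
        kind = site_kind.get(site, KIND_CELL)
        frac = 0.0
        if not border and kind in (KIND_CELL, KIND_MEGA_CELL):
            frac = float(expr_cycle[k_expr % len(expr_cycle)])
            k_expr += 1
        cells.append(
            _Cell(
                gt_id=gt_id,
                polygon=poly,
                kind=kind,
                touches_border=border,
                expression_fraction=frac,
            )
        )
        id_by_site[site] = gt_id
        seed_rows.append(pts[site])
    seeds_um = np.asarray(seed_rows, dtype=float)

    # --- nuclei ----------------------------------------------------------
    nuclei: list[_Nucleus] = []
    ax_a, ax_b = spec.nucleus_axes_um
    eligible = [
        c
        for c in cells
        if c.kind in (KIND_CELL,)
        and not c.touches_border
        and c.polygon.area >= 110.0  # room for a nucleus without pinching
    ]
    chosen = [c for c in eligible if rng.random() < spec.nucleus_fraction]
    mega_cells = [c for c in cells if c.kind == KIND_MEGA_CELL]
    margin = spec.boundary_halfwidth_um + 4 * spec.microns_per_pixel

    def _place_nucleus(cell: _Cell, a: float, b: float, kind: str) -> None:
        nonlocal gt_id
        cx, cy = cell.polygon.centroid.coords[0]
        if cell.polygon.exterior.distance(Point(cx, cy)) < a + margin:
            scale = max(
                (cell.polygon.exterior.distance(Point(cx, cy)) - margin) / a, 0.0
            )
            if scale * a < 0.3:
                return
            a, b = a * scale, b * scale
        if kind == KIND_NUCLEUS and np.pi * a * b < 8.0:
            # a shrunken nucleus this close to the 6 µm² floor would sit on
            # the classification boundary; skip it instead
            return
        gt_id += 1
        nuclei.append(
            _Nucleus(
                gt_id=gt_id,
                host_cell=cell.gt_id,
                center=(cx, cy),
                axes=(a, b),
                angle_rad=float(rng.uniform(0, np.pi)),
                kind=kind,
            )
        )

    for c in chosen:
        scale = rng.uniform(0.85, 1.2)
        _place_nucleus(c, ax_a * scale, ax_b * scale, KIND_NUCLEUS)
    for c in mega_cells:
        # >100 µm² nucleus: semi-axes 7 × 5 µm -> ~110 µm²
        _place_nucleus(c, 7.0, 5.0, KIND_OVERSIZED_NUCLEUS)
    undersized_hosts = [
        c for c in eligible if all(n.host_cell != c.gt_id for n in nuclei)
    ][: spec.n_undersized_nuclei]
    for c in undersized_hosts:
        # <6 µm² intracellular speck: semi-axes 1.0 × 0.6 µm -> ~1.9 µm²
        _place_nucleus(c, 1.0, 0.6, KIND_UNDERSIZED_NUCLEUS)

    # --- capillaries at junction vertices --------------------------------
    capillaries: list[_Capillary] = []
    r_lo, r_hi = spec.capillary_radius_um
    verts = _junction_vertices(cells, field, min_border_um=r_hi + 1.0)
    min_sep = 2 * r_hi + 2.5  # lumens must stay clearly separate basins
    accepted: list[tuple[float, float]] = []
    for vx, vy in verts:
        if rng.random() >= spec.capillary_density:
            continue
        if any(np.hypot(vx - ax, vy - ay) < min_sep for ax, ay in accepted):
            continue
        gt_id += 1
        capillaries.append(
            _Capillary(
                gt_id=gt_id,
                center=(float(vx), float(vy)),
                radius_um=float(rng.uniform(r_lo, r_hi)),
            )
        )
        accepted.append((vx, vy))

    # --- boundary-network artifacts --------------------------------------
    artifacts: list[_Artifact] = []
    edge_mids = _edge_midpoints(cells, field, min_border_um=3.0)
    rng.shuffle(edge_mids)
    used = 0
    cap_pts = [Point(c.center) for c in capillaries]
    for mx, my in edge_mids:
        if used >= spec.n_artifacts:
            break
        p = Point(mx, my)
        if any(p.distance(cp) < 5.0 for cp in cap_pts):
            continue
        gt_id += 1
        # 3×3 px dark speck: area (3·mpp)² = 0.56 µm² at 0.25 µm/px
        artifacts.append(
            _Artifact(
                gt_id=gt_id,
                center=(float(mx), float(my)),
                half_um=1.5 * spec.microns_per_pixel,
            )
        )
        used += 1

    geometry = TissueGeometry(
        spec=spec,
        cells=cells,
        nuclei=nuclei,
        capillaries=capillaries,
        artifacts=artifacts,
        seeds_um=seeds_um,
    )
    return geometry, _ground_truth(geometry)


def _single_cell_tissue(
    spec: TissueSpec, field: Polygon
) -> tuple[TissueGeometry, GroundTruth]:
    """Degenerate fixture: one rectangular cell filling the field interior."""
    w, h = spec.field_size_um
    inset = spec.boundary_halfwidth_um * 2 + 2 * spec.microns_per_pixel
    poly = box(inset, inset, w - inset, h - inset)
    cell = _Cell(gt_id=1, polygon=poly, kind=KIND_CELL, touches_border=False)
    geometry = TissueGeometry(
        spec=spec,
        cells=[cell],
        nuclei=[],
        capillaries=[],
        artifacts=[],
        seeds_um=np.asarray([[w / 2, h / 2]]),
    )
    return geometry, _ground_truth(geometry)


def _junction_vertices(
    cells: list[_Cell], field: Polygon, min_border_um: float
) -> list[tuple[float, float]]:
    """Polygon vertices shared by >= 3 cells, away from the field border."""
    counts: dict[tuple[int, int], int] = {}
    for c in cells:
        for x, y in set(c.polygon.exterior.coords[:-1]):
            key = (int(round(x * 100)), int(round(y * 100)))
            counts[key] = counts.get(key, 0) + 1
    minx, miny, maxx, maxy = field.bounds
    out = []
    for (kx, ky), n in sorted(counts.items()):
        if n < 3:
            continue
        x, y = kx / 100.0, ky / 100.0
        if (
            x - minx < min_border_um
            or maxx - x < min_border_um
            or y - miny < min_border_um
            or maxy - y < min_border_um
        ):
            continue
        out.append((x, y))
    return out


def _edge_midpoints(
    cells: list[_Cell], field: Polygon, min_border_um: float
) -> list[tuple[float, float]]:
    """Midpoints of shared cell edges (candidate artifact sites)."""
    seen: dict[tuple[int, int], int] = {}
    minx, miny, maxx, maxy = field.bounds
    out = []
    for c in cells:
        coords = c.polygon.exterior.coords
        for (x1, y1), (x2, y2) in zip(coords[:-1], coords[1:]):
            mx, my = (x1 + x2) / 2, (y1 + y2) / 2
            key = (int(round(mx * 100)), int(round(my * 100)))
            seen[key] = seen.get(key, 0) + 1
            if seen[key] == 2:  # interior edge, shared by two cells
                if (
                    mx - minx > min_border_um
                    and maxx - mx > min_border_um
                    and my - miny > min_border_um
                    and maxy - my > min_border_um
                ):
                    out.append((mx, my))
    return out


# --------------------------------------------------------------------------
# ground truth


def _polygon_feret(poly: Polygon) -> tuple[float, float]:
    pts = np.asarray(poly.exterior.coords[:-1], dtype=float)
    try:
        hull_pts = pts[ConvexHull(pts).vertices]
    except Exception:  # near-degenerate clipped polygon
        hull_pts = pts
    fmax, fmin, _ = feret_from_points(hull_pts)
    return fmax, fmin


def _ground_truth(geometry: TissueGeometry) -> GroundTruth:
    spec = geometry.spec
    mpp = spec.microns_per_pixel
    h_px, w_px = geometry.shape_px

    # pixel centers in µm (0-based centers, matching the morphometry module)
    ys = np.arange(h_px) * mpp
    xs = np.arange(w_px) * mpp

    # nearest-seed cell assignment and distance to the local Voronoi edge
    tree = cKDTree(geometry.seeds_um)
    grid = np.stack(np.meshgrid(xs, ys), axis=-1).reshape(-1, 2)
    if len(geometry.seeds_um) >= 2:
        dist2, idx2 = tree.query(grid, k=2)
        nearest = idx2[:, 0].reshape(h_px, w_px)
        d1, d2 = dist2[:, 0], dist2[:, 1]
        seed_sep = np.linalg.norm(
            geometry.seeds_um[idx2[:, 0]] - geometry.seeds_um[idx2[:, 1]], axis=1
        )
        edge_dist = (d2**2 - d1**2) / (2 * np.maximum(seed_sep, 1e-9))
        edge_dist = edge_dist.reshape(h_px, w_px)
    else:
        nearest = np.zeros((h_px, w_px), dtype=int)
        edge_dist = np.full((h_px, w_px), np.inf)

    cell_ids = np.asarray([c.gt_id for c in geometry.cells], dtype=np.int32)
    cell_assignment = cell_ids[nearest]
    boundary_mask = edge_dist < spec.boundary_halfwidth_um
    if len(geometry.cells) == 1:
        # single-cell fixture: boundary is the field-edge inset band
        poly = geometry.cells[0].polygon
        inside = _raster_polygon_mask(poly, xs, ys)
        boundary_mask = ~inside
        cell_assignment = np.where(inside, cell_ids[0], 0)
        edge_dist = np.where(inside, np.inf, 0.0)

    label = np.where(boundary_mask, 0, cell_assignment).astype(np.int32)

    # nuclei / capillaries / artifacts overwrite cells
    yy = ys[:, None]
    xx = xs[None, :]
    for nuc in geometry.nuclei:
        cx, cy = nuc.center
        a, b = nuc.axes
        ca, sa = np.cos(nuc.angle_rad), np.sin(nuc.angle_rad)
        u = (xx - cx) * ca + (yy - cy) * sa
        v = -(xx - cx) * sa + (yy - cy) * ca
        mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        label[mask] = nuc.gt_id
    for cap in geometry.capillaries:
        cx, cy = cap.center
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= cap.radius_um**2
        label[mask] = cap.gt_id
    for art in geometry.artifacts:
        cx, cy = art.center
        mask = (np.abs(xx - cx) <= art.half_um) & (np.abs(yy - cy) <= art.half_um)
        label[mask] = art.gt_id

    max_id = max(
        [c.gt_id for c in geometry.cells]
        + [n.gt_id for n in geometry.nuclei]
        + [c.gt_id for c in geometry.capillaries]
        + [a.gt_id for a in geometry.artifacts]
    )

    # truth table
    rows = []
    pix_counts = np.bincount(label.ravel(), minlength=max_id + 1)
    border_ids = set(
        np.unique(
            np.concatenate(
                [label[0, :], label[-1, :], label[:, 0], label[:, -1]]
            )
        )
    )
    w, h = spec.field_size_um
    field = box(0.0, 0.0, w, h)
    for c in geometry.cells:
        fmax, fmin = _polygon_feret(c.polygon)
        cx, cy = c.polygon.centroid.coords[0]
        # floods from both sides meet mid-band, so a cell's measurable
        # basin is its polygon minus the half-band plus half a watershed
        # line pixel along every interior (shared) edge
        interior_len = (
            c.polygon.exterior.length
            - c.polygon.exterior.intersection(field.exterior).length
        )
        est_area = c.polygon.area - (
            spec.boundary_halfwidth_um + 0.5 * mpp
        ) * interior_len
        rows.append(
            dict(
                gt_id=c.gt_id,
                kind=c.kind,
                est_area_um2=est_area,
                area_um2=c.polygon.area,
                pixel_count=int(pix_counts[c.gt_id]),
                feret_max_um=fmax,
                feret_min_um=fmin,
                centroid_x_um=cx,
                centroid_y_um=cy,
                touches_border=c.touches_border or (c.gt_id in border_ids),
                host_cell=np.nan,
                expression_fraction=c.expression_fraction,
            )
        )
    for n in geometry.nuclei:
        a, b = n.axes
        rows.append(
            dict(
                gt_id=n.gt_id,
                kind=n.kind,
                area_um2=np.pi * a * b,
                pixel_count=int(pix_counts[n.gt_id]),
                feret_max_um=2 * max(a, b),
                feret_min_um=2 * min(a, b),
                centroid_x_um=n.center[0],
                centroid_y_um=n.center[1],
                touches_border=n.gt_id in border_ids,
                host_cell=n.host_cell,
                expression_fraction=np.nan,
            )
        )
    for cap in geometry.capillaries:
        rows.append(
            dict(
                gt_id=cap.gt_id,
                kind=KIND_CAPILLARY,
                area_um2=np.pi * cap.radius_um**2,
                pixel_count=int(pix_counts[cap.gt_id]),
                feret_max_um=2 * cap.radius_um,
                feret_min_um=2 * cap.radius_um,
                centroid_x_um=cap.center[0],
                centroid_y_um=cap.center[1],
                touches_border=cap.gt_id in border_ids,
                host_cell=np.nan,
                expression_fraction=np.nan,
            )
        )
    for a in geometry.artifacts:
        rows.append(
            dict(
                gt_id=a.gt_id,
                kind=KIND_ARTIFACT,
                area_um2=(2 * a.half_um) ** 2,
                pixel_count=int(pix_counts[a.gt_id]),
                feret_max_um=2 * a.half_um * np.sqrt(2),
                feret_min_um=2 * a.half_um,
                centroid_x_um=a.center[0],
                centroid_y_um=a.center[1],
                touches_border=a.gt_id in border_ids,
                host_cell=np.nan,
                expression_fraction=np.nan,
            )
        )
    table = pd.DataFrame(rows).set_index("gt_id", drop=False)

    # contact graph from exact geometry
    contacts = []
    for cap in geometry.capillaries:
        p = Point(cap.center)
        for c in geometry.cells:
            if c.polygon.distance(p) - cap.radius_um <= spec.contact_distance_um:
                contacts.append((c.gt_id, cap.gt_id))

    return GroundTruth(
        label_map=LabelMap(labels=label, n_labels=max_id),
        table=table,
        contacts=contacts,
        cell_assignment=cell_assignment,
        boundary_mask=boundary_mask,
        edge_dist_um=np.asarray(edge_dist, dtype=float),
    )


def _raster_polygon_mask(
    poly: Polygon, xs: np.ndarray, ys: np.ndarray
) -> np.ndarray:
    # only used for the axis-aligned single-cell fixture
    minx, miny, maxx, maxy = poly.bounds
    return (
        (xs[None, :] >= minx)
        & (xs[None, :] <= maxx)
        & (ys[:, None] >= miny)
        & (ys[:, None] <= maxy)
    )


# --------------------------------------------------------------------------
# rendering


def _noise(rng, arr: np.ndarray, sd: float) -> np.ndarray:
    if sd > 0:
        arr = arr + rng.normal(0.0, sd, size=arr.shape)
    return np.clip(np.round(arr), 0, 255).astype(np.uint8)


def render_brightfield(
    geometry: TissueGeometry, gt: GroundTruth | None = None
) -> CalibratedImage:
    """Render a silver-stain-like RGB brightfield image.

    Muscle cells get reddish-purple fills inside the classifier's HSB
    window (hue 280–340°, saturation 40–90 %, brightness 60–95 %); the
    boundary network, capillary lumens and unstained cells are pale
    (saturation below the window floor); nuclei are dark blue-gray
    (brightness below the floor); off-color cells are green.
    """
    spec = geometry.spec
    if gt is None:
        gt = _ground_truth(geometry)
    rng = np.random.default_rng([spec.seed, 3])
    label = gt.label_map.labels
    h_px, w_px = label.shape

    # per-instance colors
    color_of: dict[int, np.ndarray] = {}
    for c in geometry.cells:
        if c.kind == KIND_OFF_COLOR_CELL:
            hsb = (rng.uniform(100, 140), rng.uniform(45, 80), rng.uniform(60, 90))
        elif c.kind == KIND_UNSTAINED_CELL:
            hsb = (rng.uniform(300, 340), rng.uniform(2, 6), rng.uniform(93, 97))
        else:
            hsb = (rng.uniform(280, 340), rng.uniform(40, 90), rng.uniform(60, 95))
        color_of[c.gt_id] = hsb_to_rgb(*hsb).astype(float)
    for n in geometry.nuclei:
        color_of[n.gt_id] = hsb_to_rgb(
            rng.uniform(230, 250), rng.uniform(30, 40), rng.uniform(35, 45)
        ).astype(float)
    for cap in geometry.capillaries:
        color_of[cap.gt_id] = hsb_to_rgb(
            rng.uniform(300, 340), rng.uniform(2, 6), rng.uniform(94, 98)
        ).astype(float)
    for a in geometry.artifacts:
        color_of[a.gt_id] = hsb_to_rgb(350.0, 40.0, 40.0).astype(float)

    pale = hsb_to_rgb(320.0, 8.0, 92.0).astype(float)  # boundary network
    img = np.empty((h_px, w_px, 3), dtype=float)
    img[:] = pale
    max_id = gt.label_map.n_labels
    lut = np.tile(pale, (max_id + 1, 1))
    for i, col in color_of.items():
        lut[i] = col
    img = lut[label]
    return CalibratedImage(
        microns_per_pixel=spec.microns_per_pixel,
        modality=BRIGHTFIELD,
        pixels=_noise(rng, img, spec.noise_sd),
        meta={"synthetic": True, "seed": spec.seed},
    )


def expression_target_masks(
    geometry: TissueGeometry, gt: GroundTruth
) -> dict[int, np.ndarray]:
    """Per-cell marker-positive pixel masks realizing each cell's fraction.

    The positive pixels are an exact-count uniform random subset of the
    cell's full Voronoi territory (a speckled expression pattern, like a
    granular cytoplasmic marker).  Spatial uniformity is the point: the
    measured cardiomyocyte region is the watershed basin, whose boundary
    never lands exactly on the territory outline, and a uniform speckle
    keeps the positive fraction of *any* such subset at ``f`` up to
    hypergeometric noise well below one percentage point.
    """
    spec = geometry.spec
    out: dict[int, np.ndarray] = {}
    for c in geometry.cells:
        f = c.expression_fraction
        if f <= 0:
            continue
        territory = gt.cell_assignment == c.gt_id
        if f >= 1.0:
            out[c.gt_id] = territory
            continue
        coords = np.argwhere(territory)
        n_target = int(round(f * len(coords)))
        rng = np.random.default_rng([spec.seed, 5, c.gt_id])
        pick = coords[rng.permutation(len(coords))[:n_target]]
        mask = np.zeros_like(territory)
        mask[pick[:, 0], pick[:, 1]] = True
        out[c.gt_id] = mask
    return out


def render_fluorescence(
    geometry: TissueGeometry,
    marker_role: str = "endothelium",
    gt: GroundTruth | None = None,
) -> CalibratedImage:
    """Render membrane / nuclei / marker channels of the tissue.

    ``marker_role='endothelium'`` draws capillary disks (lumen + one-pixel
    endothelial wall) in the marker channel; ``'intracellular_expression'``
    draws per-cell positive areas matching each cell's ground-truth
    fraction instead.
    """
    spec = geometry.spec
    if gt is None:
        gt = _ground_truth(geometry)
    rng = np.random.default_rng([spec.seed, 4])
    label = gt.label_map.labels
    h_px, w_px = label.shape
    mpp = spec.microns_per_pixel

    membrane = np.full((h_px, w_px), 15.0)
    # membranes must rasterize without 8-connected gaps or adjacent cell
    # interiors merge into one basin; enforce >= ~2 px ridge thickness
    memb_halfwidth = max(spec.boundary_halfwidth_um, 1.5 * mpp)
    membrane[gt.edge_dist_um < memb_halfwidth] = 200.0
    # endothelial membrane around capillary lumens
    cap_ids = [c.gt_id for c in geometry.capillaries]
    if cap_ids:
        cap_mask = np.isin(label, cap_ids)
        # 2-px endothelial ring: a 1-px ring leaks diagonally and the lumen
        # then merges with a neighboring cell basin
        ring = ndi.binary_dilation(cap_mask, iterations=2) & ~cap_mask
        membrane[ring] = 200.0

    nuc_channel = np.full((h_px, w_px), 10.0)
    nuc_ids = [n.gt_id for n in geometry.nuclei]
    if nuc_ids:
        nuc_channel[np.isin(label, nuc_ids)] = 220.0

    marker = np.full((h_px, w_px), 10.0)
    if marker_role == "endothelium":
        if cap_ids:
            cap_mask = np.isin(label, cap_ids)
            disk = ndi.binary_dilation(cap_mask, iterations=1)
            marker[disk] = 200.0
    elif marker_role == "intracellular_expression":
        for mask in expression_target_masks(geometry, gt).values():
            marker[mask] = 180.0
    else:
        raise ValueError(f"unknown marker_role {marker_role!r}")

    channels = {
        MEMBRANE: _noise(rng, membrane, spec.noise_sd).astype(float),
        NUCLEI: _noise(rng, nuc_channel, spec.noise_sd).astype(float),
        MARKER: _noise(rng, marker, spec.noise_sd).astype(float),
    }
    return CalibratedImage(
        microns_per_pixel=mpp,
        modality=FLUORESCENCE,
        channels=channels,
        meta={"synthetic": True, "seed": spec.seed, "marker_role": marker_role},
    )


# --------------------------------------------------------------------------
# evaluation helpers


def expected_classes(
    gt: GroundTruth,
    config: AnalysisConfig,
    modality: str = BRIGHTFIELD,
) -> dict[int, str]:
    """Apply the classification rules to the exact ground truth.

    Returns gt_id → expected class for every generated instance, using the
    analytic areas and the known positions (inside/outside cells), i.e. the
    class a perfect segmentation would receive under ``config``.  Mirrors
    the classifier's cascade: a nucleus inside a non-cardiomyocyte cell is
    *not* a cardiomyocyte nucleus (it falls through to the outside rules).
    """
    from .morphometry import CLASS_CAPILLARY, CLASS_CM, CLASS_NUCLEUS, CLASS_REMOVED

    table = gt.table
    out: dict[int, str] = {}
    cm_ids: set[int] = set()
    for _, row in table.iterrows():
        if row["kind"] not in CELL_KINDS:
            continue
        color_ok = row["kind"] in (KIND_CELL, KIND_SMALL_CELL, KIND_MEGA_CELL)
        if modality == FLUORESCENCE:
            color_ok = True  # size-only rule
        area = row.get("est_area_um2")
        if area is None or not np.isfinite(area):
            area = row["area_um2"]
        is_cm = (
            color_ok
            and area >= config.cm_min_area_um2
            and not (config.exclude_border_cm and row["touches_border"])
        )
        if is_cm:
            out[int(row["gt_id"])] = CLASS_CM
            cm_ids.add(int(row["gt_id"]))
        else:
            out[int(row["gt_id"])] = CLASS_REMOVED
    nuc_lo, nuc_hi = config.nucleus_area_um2
    cap_lo, cap_hi = config.capillary_area_um2
    for _, row in table.iterrows():
        kind = row["kind"]
        gid = int(row["gt_id"])
        area = row["area_um2"]
        if kind in CELL_KINDS:
            continue
        if kind in NUCLEUS_KINDS:
            host = int(row["host_cell"])
            if host in cm_ids:
                out[gid] = (
                    CLASS_NUCLEUS if nuc_lo <= area <= nuc_hi else CLASS_REMOVED
                )
            else:
                # inside a removed cell: counts as outside all cardiomyocytes
                out[gid] = (
                    CLASS_CAPILLARY if cap_lo <= area <= cap_hi else CLASS_REMOVED
                )
            continue
        # capillaries and artifacts are outside every cell by construction
        out[gid] = CLASS_CAPILLARY if cap_lo <= area <= cap_hi else CLASS_REMOVED
    return out


def match_instances(
    measured: LabelMap, gt: GroundTruth, min_overlap: float = 0.5
) -> dict[int, int]:
    """Map measured instance ids to ground-truth ids by majority overlap.

    A measured instance maps to the gt instance covering more than
    ``min_overlap`` of its pixels; unmatched instances are absent.
    """
    m = measured.labels.ravel()
    g = gt.label_map.labels.ravel()
    keep = m > 0
    pairs, counts = np.unique(
        np.stack([m[keep], g[keep]]), axis=1, return_counts=True
    )
    sizes = np.bincount(m[keep], minlength=measured.n_labels + 1)
    best: dict[int, tuple[int, int]] = {}
    for (mid, gid), cnt in zip(pairs.T, counts):
        if cnt > best.get(int(mid), (0, 0))[1]:
            best[int(mid)] = (int(gid), int(cnt))
    out = {}
    for mid, (gid, cnt) in best.items():
        if gid > 0 and cnt / sizes[mid] > min_overlap:
            out[mid] = gid
    return out


# --------------------------------------------------------------------------
# fixture files


def write_fixture(
    out_dir: str | Path,
    spec: TissueSpec,
    name: str = "fixture",
    modalities: tuple[str, ...] = (BRIGHTFIELD, FLUORESCENCE),
    marker_role: str = "endothelium",
) -> dict[str, Path]:
    """Write fixture images, ground-truth table and the spec echo to disk.

    Brightfield is written as PNG; fluorescence as a 3-page TIFF in channel
    order membrane, nuclei, marker.  The ground-truth table is CSV and the
    generating parameters a JSON echo, so a fixture directory is fully
    self-describing.
    """
    import tifffile
    from PIL import Image as PILImage

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geometry, gt = generate_tissue(spec)
    paths: dict[str, Path] = {}
    if BRIGHTFIELD in modalities:
        img = render_brightfield(geometry, gt)
        paths["brightfield"] = out / f"{name}_brightfield.png"
        PILImage.fromarray(img.pixels).save(paths["brightfield"])
    if FLUORESCENCE in modalities:
        img = render_fluorescence(geometry, marker_role, gt)
        stack = np.stack(
            [
                img.channels[MEMBRANE],
                img.channels[NUCLEI],
                img.channels[MARKER],
            ]
        ).astype(np.uint8)
        paths["fluorescence"] = out / f"{name}_fluorescence.tif"
        tifffile.imwrite(paths["fluorescence"], stack, photometric="minisblack")
    paths["ground_truth"] = out / f"{name}_ground_truth.csv"
    gt.table.to_csv(paths["ground_truth"], index=False)
    paths["contacts"] = out / f"{name}_true_contacts.csv"
    pd.DataFrame(gt.contacts, columns=["cell_gt_id", "capillary_gt_id"]).to_csv(
        paths["contacts"], index=False
    )
    paths["spec"] = out / f"{name}_spec.json"
    paths["spec"].write_text(spec.to_json())
    return paths
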