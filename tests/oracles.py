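"""Independent brute-force oracles used by the test suite.

Deliberately simple and slow: an angular scan for Feret diameters, a
steepest-descent flood for watershed basins, and all-pairs pixel distances
for capillary contacts.  They share no code path with the production
implementations they check.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist, pdist


def feret_scan(points: np.ndarray, step_deg: float = 0.01) -> tuple[float, float]:
    """(max, min) Feret by projecting onto directions 0–180°."""
    pts = np.asarray(points, dtype=float)
    angles = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    proj = pts @ dirs.T  # (n_points, n_angles)
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(pdist(pts).max()), float(widths.min())


def pixel_corner_points(mask: np.ndarray) -> np.ndarray:
    """All unit-square corner points of a pixel mask, (x, y)."""
    rows, cols = np.nonzero(mask)
    corners = np.concatenate(
        [
            np.stack([cols, rows], axis=1),
            np.stack([cols + 1, rows], axis=1),
            np.stack([cols, rows + 1], axis=1),
            np.stack([cols + 1, rows + 1], axis=1),
        ]
    ).astype(float)
    return np.unique(corners, axis=0)


def steepest_descent_basins(relief: np.ndarray) -> np.ndarray:
    """Basin id per pixel by 4-connected steepest descent; -1 = ambiguous.

    A pixel's basin is the regional minimum reached by repeatedly stepping
    to its strictly lowest 4-neighbor; ties for the lowest neighbor, or
    paths through ambiguous pixels, are marked -1 and excluded from
    comparisons.  Minima get ids in raster order of their first pixel.
    """
    relief = np.asarray(relief)
    h, w = relief.shape
    basin = np.full((h, w), 0, dtype=int)  # 0 = not yet computed
    # label regional minima (8-connected plateaus of local minima)
    from scipy import ndimage as ndi
    from skimage.morphology import local_minima

    minima = local_minima(relief, connectivity=2)
    markers, _ = ndi.label(minima, structure=np.ones((3, 3)))

    def descend(r: int, c: int, path: list) -> int:
        if basin[r, c] != 0:
            return basin[r, c]
        if markers[r, c] > 0:
            basin[r, c] = markers[r, c]
            return basin[r, c]
        nbrs = []
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                nbrs.append((relief[rr, cc], rr, cc))
        lowest = min(v for v, _, _ in nbrs)
        if lowest >= relief[r, c]:
            basin[r, c] = -1  # non-minimum plateau: ambiguous
            return -1
        cands = [(rr, cc) for v, rr, cc in nbrs if v == lowest]
        results = {descend(rr, cc, path) for rr, cc in cands}
        # a tie is harmless when every tied path reaches the same basin
        basin[r, c] = results.pop() if len(results) == 1 else -1
        return basin[r, c]

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(100000)
    try:
        for r in range(h):
            for c in range(w):
                descend(r, c, [])
    finally:
        sys.setrecursionlimit(old)
    return basin


def brute_force_contacts(
    labels: np.ndarray,
    cm_ids: list[int],
    cap_ids: list[int],
    max_distance_um: float,
    microns_per_pixel: float,
) -> dict[int, set[int]]:
    """All-pairs pixel-center distances between every CM and capillary."""
    out: dict[int, set[int]] = {i: set() for i in cm_ids}
    coords = {
        i: np.argwhere(labels == i).astype(float) for i in set(cm_ids) | set(cap_ids)
    }
    bound = max_distance_um / microns_per_pixel
    for cm in cm_ids:
        for cap in cap_ids:
            if cdist(coords[cm], coords[cap]).min() <= bound:
                out[cm].add(cap)
    return out
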