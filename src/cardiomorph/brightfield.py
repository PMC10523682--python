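"""Rule-based classification of watershed instances in silver-stained
brightfield images.

Classes and rules, applied in order (mutually exclusive, every instance gets
exactly one class):

1. **cardiomyocyte** — median instance color inside the muscle HSB window
   AND calibrated area ≥ the species minimum (60 µm² mouse / 50 µm² human)
   AND (by default) not touching the image border.
2. **cm_nucleus** — non-color-matched instance lying *within* a
   cardiomyocyte (≥ 50 % of its pixels inside one cardiomyocyte's
   hole-filled footprint), area 6–100 µm².
3. **capillary** — non-color-matched instance lying *outside* every
   cardiomyocyte (no overlap between the instance dilated by one pixel and
   any filled footprint, beyond the one-pixel watershed line), area
   1.5–100 µm².
4. **removed** — everything else, with the failed rule recorded.  In
   particular a color-matched (stained muscle) fragment below the
   cardiomyocyte size floor is debris, never a capillary: the
   unstained-lumen classes are reserved for instances failing the color
   match.

Color is summarized per instance by the *median* hue, saturation and
brightness of its pixels — robust against dark nucleus pixels and bright
boundary spill inside a cell region.  The hue window (default 240–360°)
does not wrap: a hue of 5° does not match even though it is visually red.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .color import rgb_to_hsb_image
from .config import AnalysisConfig
from .image import CalibratedImage
from .morphometry import (
    CLASS_CAPILLARY,
    CLASS_CM,
    CLASS_NUCLEUS,
    CLASS_REMOVED,
)
from .segmentation import LabelMap

_STRUCT4 = ndi.generate_binary_structure(2, 1)


def instance_median_hsb(
    image: CalibratedImage, labels: LabelMap, instance_id: int
) -> tuple[float, float, float]:
    """Median (hue°, saturation%, brightness%) over an instance's pixels."""
    mask = labels.labels == instance_id
    if not mask.any():
        raise KeyError(f"instance {instance_id} not present in label map")
    hsb = rgb_to_hsb_image(image.pixels[mask])
    med = np.median(hsb, axis=0)
    return float(med[0]), float(med[1]), float(med[2])


def hsb_in_range(
    h: float, s: float, b: float, hsb_range: tuple[float, ...]
) -> bool:
    h_lo, h_hi, s_lo, s_hi, b_lo, b_hi = hsb_range
    return (h_lo <= h <= h_hi) and (s_lo <= s <= s_hi) and (b_lo <= b <= b_hi)


def instance_color_match(
    image: CalibratedImage,
    labels: LabelMap,
    instance_id: int,
    hsb_range: tuple[float, ...],
) -> bool:
    """True iff the instance's median H, S and B each fall in the window."""
    return hsb_in_range(*instance_median_hsb(image, labels, instance_id), hsb_range)


def _border_flags(arr: np.ndarray, n_labels: int, margin: int = 2) -> np.ndarray:
    """Instances with any pixel within ``margin`` px of the image border.

    The margin covers instances separated from the border only by the thin
    watershed line / boundary network — such cells are partially captured
    just like cells sitting exactly on the border row.
    """
    flags = np.zeros(n_labels + 1, dtype=bool)
    for edge in (
        arr[:margin, :],
        arr[-margin:, :],
        arr[:, :margin],
        arr[:, -margin:],
    ):
        flags[np.unique(edge)] = True
    return flags


def classify_gomori(
    image: CalibratedImage,
    labels: LabelMap,
    config: AnalysisConfig,
) -> tuple[dict[int, tuple[str, str]], dict[int, int]]:
    """Classify every watershed instance of a brightfield image.

    Returns ``(classes, hosts)`` where ``classes`` maps instance id →
    (class, reason) for *all* ids 1..n_labels and ``hosts`` maps each
    nucleus id to its containing cardiomyocyte id.
    """
    if image.microns_per_pixel <= 0:
        raise ValueError("image calibration missing")
    arr = labels.labels
    mpp2 = image.microns_per_pixel**2
    n = labels.n_labels
    counts = np.bincount(arr.ravel(), minlength=n + 1)
    areas = counts * mpp2
    border = _border_flags(arr, n)

    # median HSB per instance
    hsb = rgb_to_hsb_image(image.pixels)
    order = np.argsort(arr.ravel(), kind="stable")
    flat_hsb = hsb.reshape(-1, 3)[order]
    offsets = np.cumsum(counts)

    def median_hsb(i: int) -> np.ndarray:
        return np.median(flat_hsb[offsets[i - 1]: offsets[i]], axis=0)

    classes: dict[int, tuple[str, str]] = {}
    hosts: dict[int, int] = {}

    # pass 1: cardiomyocytes by color + size (+ border rule)
    cm_ids: list[int] = []
    color_ok = np.zeros(n + 1, dtype=bool)
    for i in range(1, n + 1):
        if counts[i] == 0:
            classes[i] = (CLASS_REMOVED, "empty instance")
            continue
        color_ok[i] = hsb_in_range(*median_hsb(i), config.hsb_range)
        if not color_ok[i]:
            continue
        if areas[i] < config.cm_min_area_um2:
            # stained muscle fragments below the size floor are debris, not
            # capillaries: the unstained-lumen classes are reserved for
            # instances that fail the tissue color match
            classes[i] = (
                CLASS_REMOVED,
                f"stained instance below cardiomyocyte minimum "
                f"({areas[i]:.1f} um2 < {config.cm_min_area_um2} um2)",
            )
            continue
        if config.exclude_border_cm and border[i]:
            classes[i] = (
                CLASS_REMOVED,
                f"cardiomyocyte at image border (area {areas[i]:.1f} um2)",
            )
            continue
        classes[i] = (CLASS_CM, "")
        cm_ids.append(i)

    slices = ndi.find_objects(arr, max_label=n)

    # filled cardiomyocyte footprints (holes = intracellular instances)
    fill_id = np.zeros_like(arr, dtype=np.int32)
    for cm in cm_ids:
        sl = slices[cm - 1]
        filled = ndi.binary_fill_holes(arr[sl] == cm)
        sub = fill_id[sl]
        sub[filled] = cm
        fill_id[sl] = sub

    nuc_lo, nuc_hi = config.nucleus_area_um2
    cap_lo, cap_hi = config.capillary_area_um2
    h, w = arr.shape

    # pass 2: nuclei (inside a cardiomyocyte) and capillaries (outside all)
    for i in range(1, n + 1):
        if i in classes:
            continue
        sl = slices[i - 1]
        # window expanded by 1 px for the dilation test
        win = (
            slice(max(sl[0].start - 1, 0), min(sl[0].stop + 1, h)),
            slice(max(sl[1].start - 1, 0), min(sl[1].stop + 1, w)),
        )
        mask = arr[win] == i
        inside = fill_id[win][mask]
        inside = inside[inside > 0]
        frac_inside = len(inside) / counts[i]
        if frac_inside >= 0.5:
            host_counts = np.bincount(inside)
            host = int(host_counts.argmax())
            if host_counts[host] / counts[i] >= 0.5:
                if nuc_lo <= areas[i] <= nuc_hi:
                    classes[i] = (CLASS_NUCLEUS, "")
                    hosts[i] = host
                else:
                    classes[i] = (
                        CLASS_REMOVED,
                        f"inside cardiomyocyte but area {areas[i]:.2f} um2 "
                        f"outside [{nuc_lo}, {nuc_hi}]",
                    )
            else:
                classes[i] = (CLASS_REMOVED, "straddles cardiomyocyte boundary")
            continue
        dilated = ndi.binary_dilation(mask, structure=_STRUCT4)
        if not (fill_id[win][dilated] > 0).any():
            if cap_lo <= areas[i] <= cap_hi:
                classes[i] = (CLASS_CAPILLARY, "")
                continue
            classes[i] = (
                CLASS_REMOVED,
                f"outside cardiomyocytes but area {areas[i]:.2f} um2 outside "
                f"[{cap_lo}, {cap_hi}]",
            )
            continue
        classes[i] = (CLASS_REMOVED, "straddles cardiomyocyte boundary")

    return classes, hosts
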