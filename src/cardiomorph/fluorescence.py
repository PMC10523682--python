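"""Classification for membrane-stained fluorescence images.

The membrane (WGA) channel drives the watershed, but carries no class
information, so cardiomyocytes are identified by *size only*: any basin
whose calibrated area reaches the species minimum (and, by default, does
not touch the image border).  Nuclei and capillaries come from their own
channels by global auto-threshold:

* **cm_nucleus** — 8-connected component of the thresholded nuclei (DAPI)
  mask with ≥ 50 % of its pixels inside one cardiomyocyte's filled
  footprint and area within the nucleus window; components outside
  cardiomyocytes are non-cardiomyocyte nuclei and are excluded.
* **capillary** — 8-connected component of the thresholded endothelium
  (CD31) mask *after zeroing all cardiomyocyte footprint pixels*, with
  area within the capillary window.  Capillary masks and cardiomyocyte
  footprints are therefore pixel-disjoint by construction.
* **expression** — when the marker channel carries an intracellular signal
  (e.g. pro-ANP) instead of endothelium, its thresholded mask is returned
  unfiltered for per-cell positive-area quantification; no capillary class
  is produced.

Nucleus and capillary instances receive fresh ids continuing after the
watershed labels, and are painted into the returned analysis label map on
top of their underlying basin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_isodata, threshold_otsu

from .config import AnalysisConfig
from .image import MARKER, MEMBRANE, NUCLEI, CalibratedImage
from .morphometry import CLASS_CAPILLARY, CLASS_CM, CLASS_NUCLEUS, CLASS_REMOVED
from .segmentation import LabelMap

ROLE_ENDOTHELIUM = "endothelium"
ROLE_EXPRESSION = "intracellular_expression"

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class ChannelSet:
    """Named fluorescence channels sharing one pixel grid."""

    membrane: np.ndarray
    nuclei: np.ndarray | None = None
    marker: np.ndarray | None = None
    marker_role: str | None = None

    def __post_init__(self) -> None:
        self.membrane = np.asarray(self.membrane, dtype=float)
        for name in ("nuclei", "marker"):
            ch = getattr(self, name)
            if ch is not None:
                ch = np.asarray(ch, dtype=float)
                if ch.shape != self.membrane.shape:
                    raise ValueError(f"{name} channel dimensions differ from membrane")
                setattr(self, name, ch)
        if self.marker is not None and self.marker_role not in (
            ROLE_ENDOTHELIUM,
            ROLE_EXPRESSION,
        ):
            raise ValueError(
                "marker_role must be 'endothelium' or 'intracellular_expression' "
                "when a marker channel is present"
            )

    @classmethod
    def from_image(
        cls, image: CalibratedImage, marker_role: str | None = None
    ) -> "ChannelSet":
        ch = image.channels
        if MEMBRANE not in ch:
            raise ValueError("fluorescence image lacks a membrane channel")
        return cls(
            membrane=ch[MEMBRANE],
            nuclei=ch.get(NUCLEI),
            marker=ch.get(MARKER),
            marker_role=marker_role if MARKER in ch else None,
        )


def auto_threshold(
    channel: np.ndarray, method: str = "otsu"
) -> tuple[np.ndarray, float]:
    """Global histogram threshold of one channel.

    Returns ``(foreground mask, threshold value)``; foreground is
    ``channel > threshold``.  A constant channel has no contrast and raises.
    """
    channel = np.asarray(channel)
    if np.unique(channel).size < 2:
        raise ValueError("no contrast: channel is constant")
    if method == "otsu":
        t = threshold_otsu(channel)
    elif method == "isodata":
        t = threshold_isodata(channel)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return channel > t, float(t)


@dataclass
class FluoResult:
    """Outcome of fluorescence classification.

    ``labels`` holds the membrane basins plus capillary components (which
    are disjoint from cardiomyocyte footprints by construction).  Nucleus
    components overlap cardiomyocyte interiors, so they live in the
    separate ``nucleus_labels`` layer sharing the same id space; painting
    them into the main map would wrongly shrink cardiomyocyte areas.
    """

    labels: LabelMap  # basins + capillary instances
    nucleus_labels: np.ndarray  # nucleus instances only, ids continue labels'
    classes: dict[int, tuple[str, str]]
    hosts: dict[int, int]
    nuclei_mask: np.ndarray | None
    capillary_mask: np.ndarray | None
    expression_mask: np.ndarray | None
    thresholds: dict[str, float]
    max_id: int = 0


def classify_fluo(
    channels: ChannelSet,
    labels: LabelMap,
    config: AnalysisConfig,
    microns_per_pixel: float,
) -> FluoResult:
    """Classify basins and channel components of a fluorescence image."""
    if microns_per_pixel <= 0:
        raise ValueError("calibration missing")
    arr = labels.labels.copy()
    n = labels.n_labels
    mpp2 = microns_per_pixel**2
    counts = np.bincount(arr.ravel(), minlength=n + 1)
    from .brightfield import _border_flags

    border = _border_flags(arr, n)

    classes: dict[int, tuple[str, str]] = {}
    hosts: dict[int, int] = {}
    thresholds: dict[str, float] = {}

    # cardiomyocytes: size-only rule on membrane basins
    cm_ids = []
    for i in range(1, n + 1):
        area = counts[i] * mpp2
        if area < config.cm_min_area_um2:
            classes[i] = (
                CLASS_REMOVED,
                f"basin area {area:.1f} um2 below cardiomyocyte minimum",
            )
        elif config.exclude_border_cm and border[i]:
            classes[i] = (CLASS_REMOVED, "cardiomyocyte at image border")
        else:
            classes[i] = (CLASS_CM, "")
            cm_ids.append(i)

    slices = ndi.find_objects(arr, max_label=n)
    fill_id = np.zeros_like(arr, dtype=np.int32)
    for cm in cm_ids:
        sl = slices[cm - 1]
        filled = ndi.binary_fill_holes(arr[sl] == cm)
        sub = fill_id[sl]
        sub[filled] = cm
        fill_id[sl] = sub

    out = arr.astype(np.int32)
    nucleus_arr = np.zeros_like(out)
    next_id = n + 1

    nuclei_mask = None
    if channels.nuclei is not None:
        nuclei_mask, thresholds["nuclei"] = auto_threshold(
            channels.nuclei, config.autothreshold_method
        )
        comp, n_comp = ndi.label(nuclei_mask, structure=_STRUCT8)
        nuc_lo, nuc_hi = config.nucleus_area_um2
        comp_slices = ndi.find_objects(comp, max_label=n_comp)
        for c in range(1, n_comp + 1):
            sl = comp_slices[c - 1]
            mask = comp[sl] == c
            npx = int(mask.sum())
            area = npx * mpp2
            inside = fill_id[sl][mask]
            inside = inside[inside > 0]
            if len(inside) / npx < 0.5:
                continue  # nucleus outside cardiomyocytes: excluded
            host_counts = np.bincount(inside)
            host = int(host_counts.argmax())
            if host_counts[host] / npx < 0.5 or not (nuc_lo <= area <= nuc_hi):
                continue
            sub = nucleus_arr[sl]
            sub[mask] = next_id
            nucleus_arr[sl] = sub
            classes[next_id] = (CLASS_NUCLEUS, "")
            hosts[next_id] = host
            next_id += 1

    capillary_mask = None
    expression_mask = None
    if channels.marker is not None:
        marker_fg, thresholds["marker"] = auto_threshold(
            channels.marker, config.autothreshold_method
        )
        if channels.marker_role == ROLE_EXPRESSION:
            expression_mask = marker_fg
        elif channels.marker_role == ROLE_ENDOTHELIUM:
            marker_fg = marker_fg & (fill_id == 0)  # exclude cardiomyocyte area
            capillary_mask = np.zeros_like(marker_fg)
            comp, n_comp = ndi.label(marker_fg, structure=_STRUCT8)
            cap_lo, cap_hi = config.capillary_area_um2
            comp_slices = ndi.find_objects(comp, max_label=n_comp)
            for c in range(1, n_comp + 1):
                sl = comp_slices[c - 1]
                mask = comp[sl] == c
                area = int(mask.sum()) * mpp2
                if not (cap_lo <= area <= cap_hi):
                    continue
                sub = out[sl]
                sub[mask] = next_id
                out[sl] = sub
                cap_sub = capillary_mask[sl]
                cap_sub[mask] = True
                capillary_mask[sl] = cap_sub
                classes[next_id] = (CLASS_CAPILLARY, "")
                next_id += 1
        else:
            raise ValueError("marker channel present but marker_role not set")

    return FluoResult(
        labels=LabelMap(labels=out, n_labels=next_id - 1),
        nucleus_labels=nucleus_arr,
        classes=classes,
        hosts=hosts,
        nuclei_mask=nuclei_mask,
        capillary_mask=capillary_mask,
        expression_mask=expression_mask,
        thresholds=thresholds,
        max_id=next_id - 1,
    )
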