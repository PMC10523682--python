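"""Calibrated image containers and file I/O.

Brightfield images are 8-bit RGB arrays; fluorescence images are a set of
named single-channel intensity grids (e.g. ``membrane``/``nuclei``/``marker``
for WGA/DAPI/CD31).  The µm-per-pixel calibration is always supplied by the
caller — microscope exports routinely lose their metadata, so silent
inference from file headers is deliberately not attempted.

Fluorescence channels are normalized on load to a common [0, 255] float
scale (per-channel max scaling for 16-bit inputs); the applied scale factor
is recorded in ``CalibratedImage.meta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import tifffile
from PIL import Image

BRIGHTFIELD = "brightfield"
FLUORESCENCE = "fluorescence"

#: canonical channel roles for fluorescence mode
MEMBRANE, NUCLEI, MARKER = "membrane", "nuclei", "marker"


@dataclass
class CalibratedImage:
    """Pixel data plus spatial calibration and modality tag.

    ``pixels`` is an (H, W, 3) uint8 array for brightfield, or ``None`` for
    fluorescence, in which case ``channels`` maps channel names to (H, W)
    float arrays on a common [0, 255] scale.
    """

    microns_per_pixel: float
    modality: str
    pixels: np.ndarray | None = None
    channels: dict[str, np.ndarray] | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be > 0")
        if self.modality == BRIGHTFIELD:
            if self.pixels is None:
                raise ValueError("brightfield image requires RGB pixels")
            self.pixels = np.asarray(self.pixels)
            if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
                raise ValueError("brightfield pixels must be (H, W, 3)")
            if self.pixels.dtype != np.uint8:
                if self.pixels.min() < 0 or self.pixels.max() > 255:
                    raise ValueError("brightfield components must lie in [0, 255]")
                self.pixels = self.pixels.astype(np.uint8)
        elif self.modality == FLUORESCENCE:
            if not self.channels:
                raise ValueError("fluorescence image requires named channels")
            shapes = {c.shape for c in self.channels.values()}
            if len(shapes) != 1:
                raise ValueError(f"channel dimensions differ: {shapes}")
            self.channels = {
                k: np.asarray(v, dtype=float) for k, v in self.channels.items()
            }
        else:
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def shape(self) -> tuple[int, int]:
        if self.modality == BRIGHTFIELD:
            return self.pixels.shape[:2]
        return next(iter(self.channels.values())).shape

    @property
    def height_px(self) -> int:
        return self.shape[0]

    @property
    def width_px(self) -> int:
        return self.shape[1]

    @property
    def field_width_um(self) -> float:
        return self.width_px * self.microns_per_pixel

    @property
    def field_height_um(self) -> float:
        return self.height_px * self.microns_per_pixel


def _normalize_channel(arr: np.ndarray) -> tuple[np.ndarray, float]:
    """Scale a single channel to [0, 255] floats; return (channel, scale)."""
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2:
        raise ValueError("fluorescence channels must be single-plane 2D arrays")
    peak = arr.max()
    if peak <= 255:
        return arr, 1.0
    scale = 255.0 / peak
    return arr * scale, scale


def read_image(
    path: str | Path,
    microns_per_pixel: float,
    modality: str = BRIGHTFIELD,
    channel_map: Mapping[str, int | str | Path] | None = None,
) -> CalibratedImage:
    """Read an image file (PNG/JPEG/BMP/GIF/TIFF) with explicit calibration.

    For fluorescence, ``channel_map`` maps channel names to either page
    indices of a multi-page TIFF at ``path``, or to separate per-channel
    file paths (``path`` may then be ``None``-like, it is ignored for those
    entries).  At least two channels must resolve and one must be named
    ``"membrane"`` (the segmentation channel).
    """
    if microns_per_pixel <= 0:
        raise ValueError("microns_per_pixel must be > 0")

    if modality == BRIGHTFIELD:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(p)
        with Image.open(p) as im:
            rgb = np.asarray(im.convert("RGB"))
        return CalibratedImage(
            microns_per_pixel=microns_per_pixel,
            modality=BRIGHTFIELD,
            pixels=rgb,
            meta={"source": str(p)},
        )

    if modality != FLUORESCENCE:
        raise ValueError(f"unknown modality {modality!r}")
    if not channel_map or len(channel_map) < 2:
        raise ValueError("fluorescence mode requires a channel_map with >= 2 channels")
    if MEMBRANE not in channel_map:
        raise ValueError("channel_map must designate a 'membrane' channel")

    pages: np.ndarray | None = None
    channels: dict[str, np.ndarray] = {}
    scales: dict[str, float] = {}
    for name, ref in channel_map.items():
        if isinstance(ref, (int, np.integer)):
            if pages is None:
                p = Path(path)
                if not p.exists():
                    raise FileNotFoundError(p)
                pages = tifffile.imread(p)
                if pages.ndim == 2:
                    pages = pages[None]
            if ref >= len(pages):
                raise ValueError(f"channel {name!r}: page {ref} out of range")
            raw = pages[int(ref)]
        else:
            p = Path(ref)
            if not p.exists():
                raise FileNotFoundError(p)
            if p.suffix.lower() in (".tif", ".tiff"):
                raw = tifffile.imread(p)
            else:
                with Image.open(p) as im:
                    raw = np.asarray(im.convert("L"))
        channels[name], scales[name] = _normalize_channel(raw)
    return CalibratedImage(
        microns_per_pixel=microns_per_pixel,
        modality=FLUORESCENCE,
        channels=channels,
        meta={"source": str(path), "channel_scales": scales},
    )
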