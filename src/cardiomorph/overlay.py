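"""Color-coded overlay rendering for quality control and manual correction.

Each retained instance is tinted with a fixed per-class color (cyan for
cardiomyocytes, yellow for nuclei, magenta for capillaries) blended over
the base image, and its numeric id is drawn at the centroid so an analyst
can transcribe ids into an exclusion list.  Removed/excluded instances are
left untinted.  A legend CSV mapping id → class accompanies the image.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from .image import BRIGHTFIELD, MEMBRANE, NUCLEI, MARKER, CalibratedImage
from .morphometry import (
    CLASS_CAPILLARY,
    CLASS_CM,
    CLASS_NUCLEUS,
    InstanceRecord,
)
from .segmentation import LabelMap

CLASS_COLORS = {
    CLASS_CM: (0, 180, 180),
    CLASS_NUCLEUS: (230, 200, 0),
    CLASS_CAPILLARY: (220, 0, 220),
}
_TINT_ALPHA = 0.45

# fluorescence display mapping: channel -> RGB weights
_CHANNEL_DISPLAY = {MEMBRANE: (0, 1, 0), NUCLEI: (0, 0, 1), MARKER: (1, 0, 0)}


def base_rendering(image: CalibratedImage) -> np.ndarray:
    """RGB base image: brightfield as-is, fluorescence as a color composite."""
    if image.modality == BRIGHTFIELD:
        return image.pixels.copy()
    out = np.zeros((*image.shape, 3), dtype=float)
    for name, ch in image.channels.items():
        weights = _CHANNEL_DISPLAY.get(name, (1, 1, 1))
        scaled = np.clip(ch, 0, 255)
        for k in range(3):
            out[..., k] += weights[k] * scaled
    return np.clip(out, 0, 255).astype(np.uint8)


def render_overlay(
    image: CalibratedImage,
    labels: LabelMap,
    records: list[InstanceRecord],
    extra_layers: list[np.ndarray] | None = None,
    annotate_ids: bool = True,
) -> np.ndarray:
    """Tint retained instances by class over the base rendering.

    ``extra_layers`` are additional label arrays sharing the same id space
    (e.g. a fluorescence nucleus layer); they are searched for any record
    id not found in the primary map.
    """
    if labels.shape != image.shape:
        raise ValueError("label map and image dimensions must match")
    out = base_rendering(image).astype(float)
    layers = [labels.labels] + list(extra_layers or [])
    retained = [r for r in records if r.cls in CLASS_COLORS]
    for r in retained:
        color = np.array(CLASS_COLORS[r.cls], dtype=float)
        for layer in layers:
            mask = layer == r.instance_id
            if mask.any():
                out[mask] = (1 - _TINT_ALPHA) * out[mask] + _TINT_ALPHA * color
                break
    out = np.clip(np.round(out), 0, 255).astype(np.uint8)
    if annotate_ids and retained:
        im = Image.fromarray(out)
        draw = ImageDraw.Draw(im)
        mpp = image.microns_per_pixel
        for r in retained:
            x = r.centroid_x_um / mpp
            y = r.centroid_y_um / mpp
            draw.text((x, y), str(r.instance_id), fill=(255, 255, 255), anchor="mm")
        out = np.asarray(im)
    return out


def write_overlay(
    path_prefix: str | Path,
    image: CalibratedImage,
    labels: LabelMap,
    records: list[InstanceRecord],
    extra_layers: list[np.ndarray] | None = None,
) -> dict[str, Path]:
    """Write ``<prefix>_overlay.png`` and ``<prefix>_legend.csv``."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    overlay = render_overlay(image, labels, records, extra_layers)
    png = prefix.with_name(prefix.name + "_overlay.png")
    Image.fromarray(overlay).save(png)
    legend = pd.DataFrame(
        [
            {
                "instance_id": r.instance_id,
                "class": r.cls,
                "color_rgb": "/".join(map(str, CLASS_COLORS.get(r.cls, (0, 0, 0)))),
            }
            for r in records
            if r.cls in CLASS_COLORS
        ],
        columns=["instance_id", "class", "color_rgb"],
    )
    legend_path = prefix.with_name(prefix.name + "_legend.csv")
    legend.to_csv(legend_path, index=False)
    return {"overlay": png, "legend": legend_path}
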