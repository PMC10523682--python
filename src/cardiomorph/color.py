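"""RGB → HSB conversion in the units histology color windows are stated in.

HSB here is the standard hexcone hue/saturation/value model with hue in
degrees [0, 360) and saturation/brightness in percent [0, 100].  Achromatic
pixels get hue 0 with saturation 0.
"""

from __future__ import annotations

import numpy as np
from skimage.color import rgb2hsv


def rgb_to_hsb(r: float, g: float, b: float) -> tuple[float, float, float]:
    """Convert one 8-bit RGB triplet to (hue°, saturation%, brightness%)."""
    for v in (r, g, b):
        if not 0 <= v <= 255:
            raise ValueError(f"RGB component {v} outside [0, 255]")
    h, s, v = rgb_to_hsb_image(np.asarray([[[r, g, b]]], dtype=np.uint8))[0, 0]
    return float(h), float(s), float(v)


def rgb_to_hsb_image(rgb: np.ndarray) -> np.ndarray:
    """Vectorized conversion of an (..., 3) uint8 array to HSB.

    Returns a float array of the same leading shape with last axis
    (hue°, saturation%, brightness%).
    """
    hsv = rgb2hsv(np.asarray(rgb, dtype=np.uint8))
    out = np.empty_like(hsv, dtype=float)
    out[..., 0] = hsv[..., 0] * 360.0
    out[..., 1] = hsv[..., 1] * 100.0
    out[..., 2] = hsv[..., 2] * 100.0
    return out


def hsb_to_rgb(h: np.ndarray, s: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Inverse conversion for rendering: degrees/percent → uint8 RGB."""
    from skimage.color import hsv2rgb

    hsv = np.stack(
        [np.asarray(h) / 360.0, np.asarray(s) / 100.0, np.asarray(b) / 100.0],
        axis=-1,
    )
    return np.clip(np.round(hsv2rgb(hsv) * 255.0), 0, 255).astype(np.uint8)
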