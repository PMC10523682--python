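"""Analysis configuration: every threshold of the quantification pipeline.

All size thresholds are calibrated (µm or µm²) so a single configuration is
valid across magnifications; pixel-level equivalents are derived at run time
from the image's µm-per-pixel calibration.

Species presets encode the cardiomyocyte minimum cross-sectional area used to
separate true myocytes from interstitial fragments: 60 µm² for mouse tissue
and 50 µm² for human tissue.  All area comparisons are inclusive
(``>= minimum``, ``<= maximum``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

#: cardiomyocyte minimum cross-sectional area (µm²) per species
CM_MIN_AREA_PRESETS = {"mouse": 60.0, "human": 50.0}

#: default tissue color window for silver-stained brightfield muscle,
#: (hue_lo_deg, hue_hi_deg, sat_lo_pct, sat_hi_pct, bri_lo_pct, bri_hi_pct).
#: The hue window is treated as NON-wrapping: hues just above 0° (pure red)
#: do not match, only the magenta-to-red arc 240-360° does.
DEFAULT_HSB_RANGE = (240.0, 360.0, 32.0, 100.0, 54.0, 100.0)

_VALID_SPECIES = ("mouse", "human", "custom")
_VALID_THRESHOLD_METHODS = ("otsu", "isodata")


@dataclass
class AnalysisConfig:
    """Thresholds and switches controlling segmentation and classification.

    Parameters
    ----------
    watershed_tolerance
        Dynamic (h-minima depth) a regional minimum of the relief must have
        to seed its own catchment basin, in relief-intensity units.  Higher
        values merge over-segmented regions.  May be 0 (every regional
        minimum seeds a basin).
    hsb_range
        Hue/saturation/brightness window for brightfield muscle tissue,
        ``(h_lo, h_hi, s_lo, s_hi, b_lo, b_hi)`` in (degrees, percent,
        percent).  The hue interval does not wrap across 360°.
    species_preset
        ``"mouse"``, ``"human"`` or ``"custom"``.  Resolves
        ``cm_min_area_um2`` when that field is left unset.
    cm_min_area_um2
        Minimum cardiomyocyte cross-sectional area (µm²).  ``None`` means
        "use the species preset".
    nucleus_area_um2
        (min, max) admissible cardiomyocyte-nucleus area, µm².
    capillary_area_um2
        (min, max) admissible capillary area, µm².
    contact_max_distance_um
        Maximum edge-to-edge distance (µm) at which a capillary counts as
        bordering a cardiomyocyte.
    autothreshold_method
        Global histogram threshold used on fluorescence channels
        (``"otsu"`` or ``"isodata"``).
    exclude_border_cm
        Drop cardiomyocytes touching the image border (they are captured
        only partially).  Applies to cardiomyocytes only.
    """

    watershed_tolerance: float = 10.0
    hsb_range: tuple[float, float, float, float, float, float] = DEFAULT_HSB_RANGE
    species_preset: str = "mouse"
    cm_min_area_um2: float | None = None
    nucleus_area_um2: tuple[float, float] = (6.0, 100.0)
    capillary_area_um2: tuple[float, float] = (1.5, 100.0)
    contact_max_distance_um: float = 2.0
    autothreshold_method: str = "otsu"
    exclude_border_cm: bool = True

    def __post_init__(self) -> None:
        if self.species_preset not in _VALID_SPECIES:
            raise ValueError(
                f"unknown species preset {self.species_preset!r}; "
                f"expected one of {_VALID_SPECIES}"
            )
        if self.cm_min_area_um2 is None:
            if self.species_preset == "custom":
                raise ValueError(
                    "species_preset='custom' requires an explicit cm_min_area_um2"
                )
            self.cm_min_area_um2 = CM_MIN_AREA_PRESETS[self.species_preset]
        if self.watershed_tolerance < 0:
            raise ValueError("watershed_tolerance must be >= 0")
        if self.cm_min_area_um2 <= 0:
            raise ValueError("cm_min_area_um2 must be > 0")
        for name in ("nucleus_area_um2", "capillary_area_um2"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ValueError(f"{name} must satisfy 0 < min < max, got ({lo}, {hi})")
            setattr(self, name, (float(lo), float(hi)))
        if self.contact_max_distance_um <= 0:
            raise ValueError("contact_max_distance_um must be > 0")
        if self.autothreshold_method not in _VALID_THRESHOLD_METHODS:
            raise ValueError(
                f"unknown autothreshold_method {self.autothreshold_method!r}"
            )
        h_lo, h_hi, s_lo, s_hi, b_lo, b_hi = self.hsb_range
        if not (0 <= h_lo < h_hi <= 360):
            raise ValueError("hue window must satisfy 0 <= lo < hi <= 360 (no wrap)")
        for lo, hi, what in ((s_lo, s_hi, "saturation"), (b_lo, b_hi, "brightness")):
            if not (0 <= lo < hi <= 100):
                raise ValueError(f"{what} bounds must satisfy 0 <= lo < hi <= 100")
        self.hsb_range = tuple(float(v) for v in self.hsb_range)

    # -- (de)serialization ------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["hsb_range"] = list(self.hsb_range)
        d["nucleus_area_um2"] = list(self.nucleus_area_um2)
        d["capillary_area_um2"] = list(self.capillary_area_um2)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        kwargs = dict(d)
        for key in ("hsb_range", "nucleus_area_um2", "capillary_area_um2"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def replace(self, **changes: Any) -> "AnalysisConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        d = self.to_dict()
        # a species change must re-resolve the preset area unless pinned
        if "species_preset" in changes and "cm_min_area_um2" not in changes:
            d["cm_min_area_um2"] = None
        d.update(changes)
        return self.from_dict(d)


def load_config(path: str | Path, **overrides: Any) -> AnalysisConfig:
    """Read a flat key:value (YAML) configuration file, applying overrides.

    Keys mirror :class:`AnalysisConfig` field names; an unknown key raises a
    ``ValueError`` naming it.  ``overrides`` with value ``None`` are ignored
    so CLI options can be passed through unconditionally.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"configuration file {path} must contain a flat mapping")
    data.update({k: v for k, v in overrides.items() if v is not None})
    if "species_preset" in data and "cm_min_area_um2" not in data:
        data["cm_min_area_um2"] = None
    return AnalysisConfig.from_dict(data)


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
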