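"""End-to-end analysis: image → segmentation → classification → report.

These functions tie the modules together exactly as the command-line tool
does, and are the recommended entry points for scripted use.
"""

from __future__ import annotations

import numpy as np

from .brightfield import classify_gomori
from .config import AnalysisConfig
from .fluorescence import (
    ChannelSet,
    FluoResult,
    ROLE_ENDOTHELIUM,
    ROLE_EXPRESSION,
    classify_fluo,
)
from .image import BRIGHTFIELD, CalibratedImage
from .morphometry import (
    CLASS_CAPILLARY,
    CLASS_CM,
    measure_instances,
)
from .relations import count_capillary_contacts, expression_per_cm
from .report import ImageReport
from .segmentation import LabelMap, build_relief, merge_manual_lines, watershed_segment


def analyze_gomori(
    image: CalibratedImage,
    config: AnalysisConfig,
    image_id: str = "image",
    line_mask: np.ndarray | None = None,
    gaussian_sigma_px: float = 0.0,
) -> tuple[ImageReport, LabelMap]:
    """Analyze one silver-stained brightfield image.

    Returns the populated report and the watershed label map (for overlay
    rendering).  ``line_mask`` optionally adds user-drawn boundary lines
    before classification.
    """
    if image.modality != BRIGHTFIELD:
        raise ValueError("analyze_gomori expects a brightfield image")
    relief = build_relief(image, gaussian_sigma_px)
    labels = watershed_segment(relief, config.watershed_tolerance)
    if line_mask is not None:
        labels = merge_manual_lines(labels, relief, line_mask, config.watershed_tolerance)
    classes, hosts = classify_gomori(image, labels, config)
    records = measure_instances(labels, image.microns_per_pixel, classes, hosts)
    cms = [r for r in records if r.cls == CLASS_CM]
    caps = [r for r in records if r.cls == CLASS_CAPILLARY]
    contacts = count_capillary_contacts(
        cms, caps, labels, config.contact_max_distance_um, image.microns_per_pixel
    )
    report = ImageReport(
        image_id=image_id,
        records=records,
        config=config,
        microns_per_pixel=image.microns_per_pixel,
        contacts=contacts,
    )
    return report, labels


def analyze_fluorescence(
    image: CalibratedImage,
    config: AnalysisConfig,
    marker_role: str = ROLE_ENDOTHELIUM,
    image_id: str = "image",
    line_mask: np.ndarray | None = None,
) -> tuple[ImageReport, FluoResult]:
    """Analyze one membrane/nuclei/marker fluorescence image."""
    channels = ChannelSet.from_image(image, marker_role)
    if marker_role == ROLE_EXPRESSION and channels.marker is None:
        raise ValueError("expression analysis requires a marker channel")
    relief = build_relief(image)
    labels = watershed_segment(relief, config.watershed_tolerance)
    if line_mask is not None:
        labels = merge_manual_lines(labels, relief, line_mask, config.watershed_tolerance)
    result = classify_fluo(channels, labels, config, image.microns_per_pixel)

    records = measure_instances(
        result.labels, image.microns_per_pixel, result.classes, result.hosts
    )
    if result.nucleus_labels.any():
        nuc_map = LabelMap(labels=result.nucleus_labels, n_labels=result.max_id)
        records += measure_instances(
            nuc_map, image.microns_per_pixel, result.classes, result.hosts
        )
    records.sort(key=lambda r: r.instance_id)

    cms = [r for r in records if r.cls == CLASS_CM]
    contacts = None
    expressions = None
    if marker_role == ROLE_ENDOTHELIUM and result.capillary_mask is not None:
        caps = [r for r in records if r.cls == CLASS_CAPILLARY]
        contacts = count_capillary_contacts(
            cms,
            caps,
            result.labels,
            config.contact_max_distance_um,
            image.microns_per_pixel,
        )
    if marker_role == ROLE_EXPRESSION and result.expression_mask is not None:
        expressions = expression_per_cm(cms, result.labels, result.expression_mask)
    report = ImageReport(
        image_id=image_id,
        records=records,
        config=config,
        microns_per_pixel=image.microns_per_pixel,
        contacts=contacts,
        expressions=expressions,
    )
    return report, result


def suggest_tolerance(
    relief: np.ndarray, tolerances: list[float]
) -> dict[float, int]:
    """Label counts over a tolerance sweep (a quick over-segmentation probe)."""
    return {t: watershed_segment(relief, t).n_labels for t in tolerances}
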