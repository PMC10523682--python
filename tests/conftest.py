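"""Shared fixtures: small synthetic tissues, analyzed once per session."""

from __future__ import annotations

import pytest

from cardiomorph import (
    AnalysisConfig,
    TissueSpec,
    analyze_fluorescence,
    analyze_gomori,
    generate_tissue,
    render_brightfield,
    render_fluorescence,
)

TOLERANCE = 10.0


@pytest.fixture(scope="session")
def plain_tissue():
    """Noise-free 200×160 µm cross-section tissue with exact ground truth."""
    spec = TissueSpec(field_size_um=(200.0, 160.0), seed=3, noise_sd=0.0)
    geometry, gt = generate_tissue(spec)
    return spec, geometry, gt


@pytest.fixture(scope="session")
def brightfield_image(plain_tissue):
    _, geometry, gt = plain_tissue
    return render_brightfield(geometry, gt)


@pytest.fixture(scope="session")
def analyzed_brightfield(brightfield_image):
    config = AnalysisConfig(watershed_tolerance=TOLERANCE)
    report, labels = analyze_gomori(brightfield_image, config, image_id="plain")
    return config, report, labels


@pytest.fixture(scope="session")
def fluo_tissue():
    spec = TissueSpec(field_size_um=(160.0, 120.0), seed=11, noise_sd=0.0)
    geometry, gt = generate_tissue(spec)
    return spec, geometry, gt


@pytest.fixture(scope="session")
def fluo_image(fluo_tissue):
    _, geometry, gt = fluo_tissue
    return render_fluorescence(geometry, "endothelium", gt)


@pytest.fixture(scope="session")
def analyzed_fluo(fluo_image):
    config = AnalysisConfig(watershed_tolerance=TOLERANCE)
    report, result = analyze_fluorescence(
        fluo_image, config, marker_role="endothelium", image_id="fluo"
    )
    return config, report, result
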