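"""HSB color rules and the brightfield classification cascade."""

import numpy as np
import pytest

from cardiomorph import (
    AnalysisConfig,
    BRIGHTFIELD,
    CalibratedImage,
    LabelMap,
    classify_gomori,
    instance_color_match,
    rgb_to_hsb,
)
from cardiomorph.color import hsb_to_rgb
from cardiomorph.morphometry import (
    CLASS_CAPILLARY,
    CLASS_CM,
    CLASS_NUCLEUS,
    CLASS_REMOVED,
)

DEFAULT_RANGE = (240.0, 360.0, 32.0, 100.0, 54.0, 100.0)


class TestRgbToHsb:
    @pytest.mark.parametrize(
        "rgb, expected",
        [
            ((255, 0, 0), (0.0, 100.0, 100.0)),  # pure red
            ((255, 0, 255), (300.0, 100.0, 100.0)),  # magenta, inside window
            ((0, 255, 0), (120.0, 100.0, 100.0)),
        ],
    )
    def test_primaries(self, rgb, expected):
        h, s, b = rgb_to_hsb(*rgb)
        assert (h, s, b) == pytest.approx(expected)

    def test_achromatic_gray(self):
        h, s, b = rgb_to_hsb(128, 128, 128)
        assert h == 0.0
        assert s == 0.0
        assert b == pytest.approx(50.2, abs=0.1)

    def test_out_of_range_component(self):
        with pytest.raises(ValueError):
            rgb_to_hsb(300, 0, 0)


def _uniform_image(hsb, shape=(10, 10)):
    rgb = hsb_to_rgb(*[np.full(shape, v) for v in hsb])
    return CalibratedImage(microns_per_pixel=0.5, modality=BRIGHTFIELD, pixels=rgb)


class TestColorMatch:
    def _single_instance(self, shape=(10, 10)):
        return LabelMap(labels=np.ones(shape, dtype=np.int32), n_labels=1)

    def test_reddish_purple_matches(self):
        img = _uniform_image((320.0, 70.0, 78.0))
        assert instance_color_match(img, self._single_instance(), 1, DEFAULT_RANGE)

    def test_green_fails_hue(self):
        img = _uniform_image((120.0, 70.0, 78.0))
        assert not instance_color_match(img, self._single_instance(), 1, DEFAULT_RANGE)

    def test_dark_pixel_fails_brightness_floor(self):
        img = _uniform_image((300.0, 70.0, 40.0))
        assert not instance_color_match(img, self._single_instance(), 1, DEFAULT_RANGE)

    def test_hue_window_does_not_wrap(self):
        # visually red (hue ~5°) but outside the non-wrapping 240-360° arc
        img = _uniform_image((5.0, 80.0, 80.0))
        assert not instance_color_match(img, self._single_instance(), 1, DEFAULT_RANGE)


def _paint(pixels, labels, sl, label, hsb):
    pixels[sl] = hsb_to_rgb(*[np.full(pixels[sl].shape[:2], v) for v in hsb])
    labels[sl] = label


@pytest.fixture(scope="module")
def constructed_scene():
    """Hand-built label map exercising every rule at mpp = 0.5 µm/px.

    1: 900 px (225 µm²) reddish interior cell with a hole for the nucleus
    2: 220 px (55 µm²) reddish cell — between the human (50) and mouse (60)
       area floors, so its class flips with the species preset
    3: 24 px (6 µm²) dark nucleus inside instance 1's hole
    4: 6 px (1.5 µm²) pale lumen between cells
    5: 3 px (0.75 µm²) pale speck — below the capillary floor
    6: reddish cell touching the image border
    """
    h = w = 100
    pixels = np.zeros((h, w, 3), dtype=np.uint8)
    pixels[:] = hsb_to_rgb(
        np.full((h, w), 320.0), np.full((h, w), 8.0), np.full((h, w), 92.0)
    )
    labels = np.zeros((h, w), dtype=np.int32)
    red = (320.0, 70.0, 78.0)
    _paint(pixels, labels, (slice(10, 40), slice(10, 40)), 1, red)
    # nucleus hole inside instance 1: carve, then paint nucleus with a gap ring
    hole = (slice(20, 28), slice(20, 28))
    labels[hole] = 0
    nuc = (slice(22, 26), slice(21, 27))  # 4 × 6 = 24 px
    _paint(pixels, labels, nuc, 3, (240.0, 35.0, 40.0))
    _paint(pixels, labels, (slice(50, 70), slice(10, 21)), 2, red)  # 220 px
    _paint(pixels, labels, (slice(50, 52), slice(50, 53)), 4, (320.0, 4.0, 96.0))
    _paint(pixels, labels, (slice(80, 81), slice(50, 53)), 5, (320.0, 4.0, 96.0))
    _paint(pixels, labels, (slice(0, 20), slice(70, 95)), 6, red)
    image = CalibratedImage(
        microns_per_pixel=0.5, modality=BRIGHTFIELD, pixels=pixels
    )
    return image, LabelMap(labels=labels, n_labels=6)


class TestClassifyGomori:
    def test_mouse_preset(self, constructed_scene):
        image, labels = constructed_scene
        config = AnalysisConfig(species_preset="mouse")
        classes, hosts = classify_gomori(image, labels, config)
        assert classes[1][0] == CLASS_CM
        assert classes[2][0] == CLASS_REMOVED  # 55 µm² < 60 µm² mouse floor
        assert classes[3][0] == CLASS_NUCLEUS
        assert hosts[3] == 1
        assert classes[4][0] == CLASS_CAPILLARY
        assert classes[5][0] == CLASS_REMOVED  # 0.75 µm² < 1.5 µm² floor
        assert classes[6][0] == CLASS_REMOVED  # border exclusion

    def test_human_preset_flips_small_cell(self, constructed_scene):
        image, labels = constructed_scene
        config = AnalysisConfig(species_preset="human")
        classes, _ = classify_gomori(image, labels, config)
        assert classes[2][0] == CLASS_CM  # 55 µm² >= 50 µm² human floor

    def test_border_cm_kept_when_exclusion_off(self, constructed_scene):
        image, labels = constructed_scene
        config = AnalysisConfig(species_preset="mouse", exclude_border_cm=False)
        classes, _ = classify_gomori(image, labels, config)
        assert classes[6][0] == CLASS_CM

    def test_every_instance_classified_exactly_once(self, constructed_scene):
        image, labels = constructed_scene
        classes, _ = classify_gomori(image, labels, AnalysisConfig())
        assert sorted(classes) == list(range(1, labels.n_labels + 1))

    def test_raising_floor_never_increases_cm_count(self, constructed_scene):
        image, labels = constructed_scene
        counts = []
        for floor in (40.0, 60.0, 100.0, 300.0):
            config = AnalysisConfig(
                species_preset="custom", cm_min_area_um2=floor
            )
            classes, _ = classify_gomori(image, labels, config)
            counts.append(sum(1 for c, _ in classes.values() if c == CLASS_CM))
        assert counts == sorted(counts, reverse=True)

    def test_deterministic(self, constructed_scene):
        image, labels = constructed_scene
        config = AnalysisConfig()
        assert classify_gomori(image, labels, config) == classify_gomori(
            image, labels, config
        )


class TestClassifyOnFixture:
    def test_counts_match_ground_truth(self, plain_tissue, analyzed_brightfield):
        from collections import Counter

        from cardiomorph import expected_classes

        _, _, gt = plain_tissue
        config, report, _ = analyzed_brightfield
        measured = Counter(r.cls for r in report.records)
        expected = Counter(expected_classes(gt, config).values())
        for cls in (CLASS_CM, CLASS_NUCLEUS, CLASS_CAPILLARY):
            assert measured[cls] == expected[cls]

    def test_partition_covers_all_labels(self, analyzed_brightfield):
        _, report, labels = analyzed_brightfield
        assert len(report.records) == labels.n_labels
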