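"""Synthetic-tissue generator: determinism, ground-truth consistency."""

import numpy as np
import pandas as pd
import pytest

from cardiomorph import (
    TissueSpec,
    generate_tissue,
    render_brightfield,
    render_fluorescence,
)
from cardiomorph.brightfield import hsb_in_range
from cardiomorph.color import rgb_to_hsb_image
from cardiomorph.config import DEFAULT_HSB_RANGE
from cardiomorph.synthetic import write_fixture


class TestGenerateTissue:
    def test_same_seed_identical_ground_truth(self):
        spec = TissueSpec(field_size_um=(120.0, 90.0), seed=7)
        _, gt1 = generate_tissue(spec)
        _, gt2 = generate_tissue(spec)
        assert np.array_equal(gt1.label_map.labels, gt2.label_map.labels)
        pd.testing.assert_frame_equal(gt1.table, gt2.table)
        assert gt1.contacts == gt2.contacts

    def test_different_seeds_differ(self):
        a = generate_tissue(TissueSpec(field_size_um=(120.0, 90.0), seed=1))[1]
        b = generate_tissue(TissueSpec(field_size_um=(120.0, 90.0), seed=2))[1]
        assert not np.array_equal(a.label_map.labels, b.label_map.labels)

    def test_single_cell_degenerate(self):
        geometry, gt = generate_tissue(
            TissueSpec(field_size_um=(60.0, 50.0), n_cells=1, seed=0)
        )
        assert len(geometry.cells) == 1
        assert len(geometry.capillaries) == 0
        interior = gt.label_map.labels.max()
        assert interior == 1

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError):
            TissueSpec(n_cells=0)

    def test_mean_minferet_matches_request(self):
        # one large field gives ~500 interior cells for the mean check
        spec = TissueSpec(
            field_size_um=(360.0, 280.0), cell_diameter_um=(14.0, 4.0), seed=5
        )
        _, gt = generate_tissue(spec)
        cells = gt.table[(gt.table.kind == "cell") & (~gt.table.touches_border)]
        assert len(cells) >= 300
        mean = cells.feret_min_um.mean()
        se = cells.feret_min_um.std() / np.sqrt(len(cells))
        assert abs(mean - 14.0) <= 3 * se

    def test_size_windows_respected_by_construction(self):
        spec = TissueSpec(field_size_um=(160.0, 120.0), seed=3)
        _, gt = generate_tissue(spec)
        nuc = gt.table[gt.table.kind == "nucleus"]
        cap = gt.table[gt.table.kind == "capillary"]
        assert ((nuc.area_um2 >= 6) & (nuc.area_um2 <= 100)).all()
        assert ((cap.area_um2 >= 1.5) & (cap.area_um2 <= 100)).all()

    def test_every_instance_has_one_truth_row(self):
        spec = TissueSpec(field_size_um=(120.0, 90.0), seed=9)
        _, gt = generate_tissue(spec)
        rendered_ids = set(np.unique(gt.label_map.labels)) - {0}
        assert rendered_ids <= set(gt.table.gt_id)
        assert not gt.table.gt_id.duplicated().any()

    def test_contact_graph_references_valid_ids(self):
        spec = TissueSpec(field_size_um=(160.0, 120.0), seed=4)
        geometry, gt = generate_tissue(spec)
        cell_ids = {c.gt_id for c in geometry.cells}
        cap_ids = {c.gt_id for c in geometry.capillaries}
        assert all(a in cell_ids and b in cap_ids for a, b in gt.contacts)


class TestRenderBrightfield:
    def test_same_seed_identical_pixels(self):
        spec = TissueSpec(field_size_um=(100.0, 80.0), seed=7)
        geometry, gt = generate_tissue(spec)
        img1 = render_brightfield(geometry, gt)
        img2 = render_brightfield(geometry, gt)
        assert np.array_equal(img1.pixels, img2.pixels)

    def test_cell_pixels_pass_color_match_noise_free(self):
        spec = TissueSpec(field_size_um=(100.0, 80.0), seed=2, noise_sd=0.0)
        geometry, gt = generate_tissue(spec)
        img = render_brightfield(geometry, gt)
        hsb = rgb_to_hsb_image(img.pixels)
        for cell in geometry.cells[:10]:
            mask = gt.label_map.labels == cell.gt_id
            med = np.median(hsb[mask], axis=0)
            assert hsb_in_range(*med, DEFAULT_HSB_RANGE)

    def test_capillary_lumens_fail_color_match(self):
        spec = TissueSpec(field_size_um=(160.0, 120.0), seed=2, noise_sd=0.0)
        geometry, gt = generate_tissue(spec)
        img = render_brightfield(geometry, gt)
        hsb = rgb_to_hsb_image(img.pixels)
        for cap in geometry.capillaries[:10]:
            mask = gt.label_map.labels == cap.gt_id
            med = np.median(hsb[mask], axis=0)
            assert not hsb_in_range(*med, DEFAULT_HSB_RANGE)
            assert med[1] < 32.0  # unstained: saturation below the floor


class TestRenderFluorescence:
    def test_channels_share_shape_and_are_deterministic(self):
        spec = TissueSpec(field_size_um=(100.0, 80.0), seed=7)
        geometry, gt = generate_tissue(spec)
        a = render_fluorescence(geometry, "endothelium", gt)
        b = render_fluorescence(geometry, "endothelium", gt)
        assert a.channels.keys() == b.channels.keys()
        for name in a.channels:
            assert np.array_equal(a.channels[name], b.channels[name])

    def test_expression_role_swaps_marker_content(self):
        spec = TissueSpec(field_size_um=(100.0, 80.0), seed=7, noise_sd=0.0)
        geometry, gt = generate_tissue(spec)
        endo = render_fluorescence(geometry, "endothelium", gt)
        expr = render_fluorescence(geometry, "intracellular_expression", gt)
        assert not np.array_equal(endo.channels["marker"], expr.channels["marker"])

    def test_unknown_role_rejected(self):
        spec = TissueSpec(field_size_um=(80.0, 60.0), seed=0)
        geometry, gt = generate_tissue(spec)
        with pytest.raises(ValueError):
            render_fluorescence(geometry, "nonsense", gt)


class TestWriteFixture:
    def test_files_written_and_byte_identical_across_runs(self, tmp_path):
        spec = TissueSpec(field_size_um=(80.0, 60.0), seed=7)
        p1 = write_fixture(tmp_path / "a", spec)
        p2 = write_fixture(tmp_path / "b", spec)
        for key in ("brightfield", "fluorescence", "ground_truth", "spec"):
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_spec_json_round_trip(self, tmp_path):
        spec = TissueSpec(field_size_um=(80.0, 60.0), seed=3, noise_sd=1.0)
        assert TissueSpec.from_json(spec.to_json()) == spec
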