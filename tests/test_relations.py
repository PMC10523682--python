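"""Capillary contacts against a brute-force distance oracle; summaries."""

import numpy as np
import pytest

from cardiomorph import (
    LabelMap,
    count_capillary_contacts,
    expression_per_cm,
    measure_instances,
    summarize_image,
)
from cardiomorph.morphometry import (
    CLASS_CAPILLARY,
    CLASS_CM,
    InstanceRecord,
)
from oracles import brute_force_contacts


def _random_scene(seed, size=96, n_cm=4, n_cap=8, mpp=0.5):
    """Disjoint rectangular cardiomyocytes and capillary specks."""
    rng = np.random.default_rng(seed)
    labels = np.zeros((size, size), dtype=np.int32)
    next_id = 1
    cm_ids, cap_ids = [], []
    for _ in range(n_cm):
        for _attempt in range(50):
            r, c = rng.integers(2, size - 24, 2)
            hgt, wdt = rng.integers(12, 22, 2)
            region = labels[r: r + hgt, c: c + wdt]
            if (region == 0).all():
                region[:] = next_id
                cm_ids.append(next_id)
                next_id += 1
                break
    for _ in range(n_cap):
        for _attempt in range(80):
            r, c = rng.integers(1, size - 4, 2)
            region = labels[r: r + 2, c: c + 2]
            if (region == 0).all():
                region[:] = next_id
                cap_ids.append(next_id)
                next_id += 1
                break
    lm = LabelMap(labels=labels, n_labels=next_id - 1)
    classes = {i: (CLASS_CM, "") for i in cm_ids}
    classes.update({i: (CLASS_CAPILLARY, "") for i in cap_ids})
    records = measure_instances(lm, mpp, classes)
    cms = [r for r in records if r.cls == CLASS_CM]
    caps = [r for r in records if r.cls == CLASS_CAPILLARY]
    return lm, cms, caps, mpp


class TestContacts:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_all_pairs(self, seed):
        lm, cms, caps, mpp = _random_scene(seed)
        results = count_capillary_contacts(cms, caps, lm, 2.0, mpp)
        oracle = brute_force_contacts(
            lm.labels,
            [r.instance_id for r in cms],
            [r.instance_id for r in caps],
            2.0,
            mpp,
        )
        for res in results:
            assert set(res.capillary_ids) == oracle[res.cm_id]
            assert res.n_contacts == len(oracle[res.cm_id])

    def test_monotone_in_distance_bound(self):
        lm, cms, caps, mpp = _random_scene(3)
        prev = None
        for d in (0.5, 1.0, 2.0, 4.0, 8.0):
            counts = [
                r.n_contacts
                for r in count_capillary_contacts(cms, caps, lm, d, mpp)
            ]
            if prev is not None:
                assert all(a >= b for a, b in zip(counts, prev))
            prev = counts

    def test_contact_beyond_bound_excluded(self):
        labels = np.zeros((40, 40), dtype=np.int32)
        labels[5:15, 5:15] = 1  # CM
        labels[5:7, 22:24] = 2  # capillary at 7 px = 3.5 µm gap
        labels[5:7, 17:19] = 3  # capillary at 2 px = 1.0 µm gap
        lm = LabelMap(labels=labels, n_labels=3)
        classes = {1: (CLASS_CM, ""), 2: (CLASS_CAPILLARY, ""), 3: (CLASS_CAPILLARY, "")}
        records = measure_instances(lm, 0.5, classes)
        cms = [r for r in records if r.cls == CLASS_CM]
        caps = [r for r in records if r.cls == CLASS_CAPILLARY]
        (res,) = count_capillary_contacts(cms, caps, lm, 2.0, 0.5)
        assert res.capillary_ids == (3,)

    def test_no_capillaries_yields_zero_counts(self):
        lm, cms, _, mpp = _random_scene(1, n_cap=0)
        results = count_capillary_contacts(cms, [], lm, 2.0, mpp)
        assert all(r.n_contacts == 0 and r.cc_per_area == 0.0 for r in results)

    def test_cc_per_area_identity(self):
        lm, cms, caps, mpp = _random_scene(2)
        for res in count_capillary_contacts(cms, caps, lm, 2.0, mpp):
            area = next(r.area_um2 for r in cms if r.instance_id == res.cm_id)
            assert res.cc_per_area * area == pytest.approx(res.n_contacts)

    def test_nonpositive_bound_rejected(self):
        lm, cms, caps, mpp = _random_scene(0)
        with pytest.raises(ValueError):
            count_capillary_contacts(cms, caps, lm, 0.0, mpp)


class TestExpression:
    def _cm_scene(self):
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[4:14, 4:14] = 1  # 100 px CM
        lm = LabelMap(labels=labels, n_labels=1)
        records = measure_instances(lm, 1.0, {1: (CLASS_CM, "")})
        return lm, records

    def test_half_coverage(self):
        lm, records = self._cm_scene()
        mask = np.zeros((20, 20), dtype=bool)
        mask[4:9, 4:14] = True  # upper half of the CM
        (res,) = expression_per_cm(records, lm, mask)
        assert res.positive_pct == pytest.approx(50.0)

    def test_empty_and_full_masks(self):
        lm, records = self._cm_scene()
        (zero,) = expression_per_cm(records, lm, np.zeros((20, 20), dtype=bool))
        (full,) = expression_per_cm(records, lm, np.ones((20, 20), dtype=bool))
        assert zero.positive_pct == 0.0
        assert full.positive_pct == 100.0

    def test_dimension_mismatch(self):
        lm, records = self._cm_scene()
        with pytest.raises(ValueError):
            expression_per_cm(records, lm, np.zeros((5, 5), dtype=bool))

    def test_invariant_under_relabeling(self):
        lm, records = self._cm_scene()
        mask = np.zeros((20, 20), dtype=bool)
        mask[4:9, 4:14] = True
        relabeled = LabelMap(labels=(lm.labels * 7), n_labels=7)
        rec7 = [
            InstanceRecord(
                instance_id=7,
                cls=CLASS_CM,
                pixel_count=records[0].pixel_count,
                area_um2=records[0].area_um2,
                feret_max_um=0,
                feret_min_um=0,
                min_feret_angle_deg=0,
                centroid_x_um=0,
                centroid_y_um=0,
                touches_border=False,
            )
        ]
        (a,) = expression_per_cm(records, lm, mask)
        (b,) = expression_per_cm(rec7, relabeled, mask)
        assert a.positive_pct == b.positive_pct


def _record(i, cls, area, minferet):
    return InstanceRecord(
        instance_id=i,
        cls=cls,
        pixel_count=int(area),
        area_um2=area,
        feret_max_um=minferet * 2,
        feret_min_um=minferet,
        min_feret_angle_deg=0.0,
        centroid_x_um=0.0,
        centroid_y_um=0.0,
        touches_border=False,
    )


class TestSummaries:
    def test_mean_and_sample_sd(self):
        records = [_record(1, CLASS_CM, 100.0, 10.0), _record(2, CLASS_CM, 300.0, 14.0)]
        summary = summarize_image(records).set_index("class")
        row = summary.loc[CLASS_CM]
        assert row["n"] == 2
        assert row["mean_area_um2"] == pytest.approx(200.0)
        assert row["sd_area_um2"] == pytest.approx(np.sqrt(20000.0))

    def test_single_instance_sd_missing_not_zero(self):
        summary = summarize_image([_record(1, CLASS_CM, 100.0, 10.0)]).set_index(
            "class"
        )
        assert np.isnan(summary.loc[CLASS_CM, "sd_area_um2"])

    def test_per_cm_ratio_then_average(self):
        from cardiomorph import ContactResult

        records = [
            _record(1, CLASS_CM, 200.0, 10.0),
            _record(2, CLASS_CM, 200.0, 10.0),
            _record(3, CLASS_CM, 250.0, 10.0),
        ]
        contacts = [
            ContactResult(cm_id=1, n_contacts=3, cc_per_area=3 / 200),
            ContactResult(cm_id=2, n_contacts=3, cc_per_area=3 / 200),
            ContactResult(cm_id=3, n_contacts=4, cc_per_area=4 / 250),
        ]
        summary = summarize_image(records, contacts).set_index("class")
        row = summary.loc[CLASS_CM]
        assert row["mean_capillary_contacts"] == pytest.approx(10 / 3)
        assert row["mean_cc_per_area_um2"] == pytest.approx(
            np.mean([0.015, 0.015, 0.016])
        )

    def test_empty_class_reports_n_zero(self):
        summary = summarize_image([]).set_index("class")
        assert (summary["n"] == 0).all()
        assert summary["mean_area_um2"].isna().all()
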