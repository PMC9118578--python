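"""Manual-correction merge semantics and counting."""

import numpy as np
import pytest

from pollenquant.corrections import CorrectionSet, Edit, apply_corrections, count
from pollenquant.detection import Detection


def _auto(points):
    return [
        Detection(point=p, region_label=i + 1, source="auto", category="total")
        for i, p in enumerate(points)
    ]


def _edits(*specs) -> CorrectionSet:
    return CorrectionSet("img", tuple(Edit(r, c, cat, act) for r, c, cat, act in specs))


class TestApplyCorrections:
    def test_add_totals(self):
        dets, unmatched = apply_corrections(
            _auto([(10, 10), (50, 50), (90, 90)]),
            _edits((20, 20, "total", "add"), (70, 70, "total", "add")),
        )
        assert len(dets) == 5 and not unmatched
        assert sum(d.source == "manual" for d in dets) == 2

    def test_remove_nearest_within_radius(self):
        dets, unmatched = apply_corrections(
            _auto([(10, 10)]), _edits((12, 11, "total", "remove")), match_radius=15
        )
        assert dets == [] and not unmatched

    def test_remove_beyond_radius_is_reported(self):
        dets, unmatched = apply_corrections(
            _auto([(10, 10)]), _edits((60, 60, "total", "remove")), match_radius=15
        )
        assert len(dets) == 1 and len(unmatched) == 1

    def test_add_germinated_marks_nearest_grain(self):
        dets, _ = apply_corrections(_auto([(10, 10)]), _edits((11, 10, "germinated", "add")))
        assert len(dets) == 1 and dets[0].category == "germinated"

    def test_add_germinated_far_from_grains_creates_one(self):
        dets, _ = apply_corrections(_auto([(10, 10)]), _edits((80, 80, "germinated", "add")))
        assert len(dets) == 2
        new = [d for d in dets if d.source == "manual"]
        assert new[0].category == "germinated" and new[0].point == (80, 80)

    def test_remove_germinated_keeps_grain(self):
        dets, _ = apply_corrections(
            _auto([(10, 10)]),
            _edits((10, 10, "germinated", "add"), (10, 10, "germinated", "remove")),
        )
        assert len(dets) == 1 and dets[0].category == "total"

    def test_removing_grain_drops_its_germinated_mark(self):
        dets, _ = apply_corrections(
            _auto([(10, 10)]),
            _edits((10, 10, "germinated", "add"), (10, 10, "total", "remove")),
        )
        assert dets == []

    def test_equidistant_tie_breaks_by_row_then_col(self):
        auto = _auto([(20, 10), (10, 20), (10, 0)])  # (10, 0) and (10, 20) tie on row
        dets, _ = apply_corrections(auto, _edits((10, 10, "total", "remove")), match_radius=15)
        remaining = {d.point for d in dets}
        assert remaining == {(20, 10), (10, 20)}  # smallest row, then smallest col removed

    def test_empty_edit_list_is_identity(self):
        auto = _auto([(1, 1), (2, 2)])
        dets, unmatched = apply_corrections(auto, CorrectionSet("img"))
        assert dets == auto and not unmatched

    def test_order_is_significant(self):
        # removing then adding at the same point leaves one manual grain;
        # adding then removing leaves the other grain standing
        auto = _auto([(10, 10)])
        seq1 = _edits((10, 10, "total", "remove"), (10, 10, "total", "add"))
        seq2 = _edits((10, 10, "total", "add"), (10, 10, "total", "remove"))
        d1, _ = apply_corrections(auto, seq1)
        d2, _ = apply_corrections(auto, seq2)
        assert [d.source for d in d1] == ["manual"]
        assert len(d2) == 1


class TestCount:
    @pytest.mark.parametrize(
        "n_total,n_germ,percent", [(50, 25, 50.0), (40, 0, 0.0), (3, 3, 100.0)]
    )
    def test_percent_formula(self, n_total, n_germ, percent):
        dets = _auto([(i, i) for i in range(n_total)])
        dets = [d.as_germinated() if i < n_germ else d for i, d in enumerate(dets)]
        result = count(dets, "img")
        assert (result.n_total, result.n_germinated) == (n_total, n_germ)
        assert result.percent_germination == pytest.approx(percent)
        assert not result.undefined

    def test_empty_image_percent_is_undefined(self):
        result = count([], "img")
        assert result.undefined and result.percent_germination is None


def _random_case(rng):
    n_auto = rng.integers(0, 12)
    auto = _auto([tuple(rng.integers(0, 100, 2).astype(float)) for _ in range(n_auto)])
    n_edits = rng.integers(0, 15)
    edits = tuple(
        Edit(
            float(rng.integers(0, 100)),
            float(rng.integers(0, 100)),
            ("total", "germinated")[rng.integers(2)],
            ("add", "remove")[rng.integers(2)],
        )
        for _ in range(n_edits)
    )
    return auto, CorrectionSet("img", edits)


def test_randomized_edit_sequences_preserve_invariants():
    """1,000 random cases: counts stay consistent and replay is deterministic."""
    rng = np.random.default_rng(2024)
    for _ in range(1000):
        auto, corrections = _random_case(rng)
        dets, unmatched = apply_corrections(auto, corrections)
        result = count(dets, "img")
        assert 0 <= result.n_germinated <= result.n_total
        # pure total-additions grow the count by exactly k
        k = rng.integers(1, 5)
        adds = CorrectionSet(
            "img", tuple(Edit(float(i), 0.0, "total", "add") for i in range(k))
        )
        dets2, _ = apply_corrections(dets, adds)
        assert len(dets2) == len(dets) + k
        # deterministic replay
        replay, unmatched2 = apply_corrections(auto, corrections)
        assert replay == dets and unmatched2 == unmatched
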