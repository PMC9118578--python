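"""Tube extraction, skeleton length measurement, and the germination rule."""

import numpy as np
import pytest

from pollenquant.detection import Detection, detect_discs, label_regions, suppress_tubes
from pollenquant.germination import (
    TubeMeasurement,
    classify_germination,
    extract_tube,
    measure_tubes,
    tube_length,
)
from pollenquant.segmentation import BinaryMask

from conftest import rasterize_ellipse


def _disc(shape, center, radius):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _scene_with_tube(radius=14, tube_len=60, width=3):
    """Disc at (60, 60) with a straight horizontal appendage of given length."""
    px = np.zeros((120, 240), dtype=bool)
    px |= _disc(px.shape, (60, 60), radius)
    half = width // 2
    start = 60 + radius
    px[60 - half : 60 + half + 1, start : start + tube_len] = True
    return BinaryMask(px, "scene")


class TestExtractTube:
    def test_bare_disc_has_empty_tube(self, disc_mask):
        (grain,) = label_regions(disc_mask)
        assert not extract_tube(disc_mask, grain).any()

    def test_straight_appendage_is_recovered(self):
        mask = _scene_with_tube(tube_len=60)
        grain = label_regions(suppress_tubes(mask, 4))[0]
        tube = extract_tube(mask, grain)
        # oracle: the appendage is everything right of the disc
        assert tube.any()
        assert tube[:, : int(60 + grain.equivalent_diameter / 2 - 1)].sum() == 0
        assert 100 < tube.sum() < 240  # ~3 x 60 minus the disc overlap

    def test_disjoint_discs_each_have_no_tube(self):
        px = _disc((100, 200), (50, 50), 15) | _disc((100, 200), (50, 150), 15)
        mask = BinaryMask(px, "two")
        for grain in label_regions(mask):
            assert not extract_tube(mask, grain).any()

    def test_missing_component_raises(self, disc_mask):
        (grain,) = label_regions(disc_mask)
        empty = BinaryMask(np.zeros_like(disc_mask.pixels), "empty")
        with pytest.raises(KeyError):
            extract_tube(empty, grain)


class TestTubeLength:
    def test_empty_mask_is_zero(self):
        assert tube_length(np.zeros((10, 10), bool)) == 0.0

    def test_straight_bar_within_ten_percent(self):
        bar = np.zeros((20, 100), dtype=bool)
        bar[8:11, 20:80] = True  # 3 x 60
        assert tube_length(bar) == pytest.approx(60, rel=0.10)

    def test_quarter_circle_arc_within_ten_percent(self):
        # stroke along a radius-40 quarter arc, analytic length pi*40/2
        t = np.linspace(0, np.pi / 2, 200)
        pts = np.stack([60 - 40 * np.sin(t), 20 + 40 * np.cos(t)], axis=1)
        rr, cc = np.mgrid[0:100, 0:100]
        arc = np.zeros((100, 100), dtype=bool)
        for p in pts:
            arc |= (rr - p[0]) ** 2 + (cc - p[1]) ** 2 <= 1.5**2
        assert tube_length(arc) == pytest.approx(np.pi * 40 / 2, rel=0.10)

    def test_stray_speck_does_not_add_to_length(self):
        bar = np.zeros((20, 100), dtype=bool)
        bar[8:11, 20:80] = True
        bar[2, 2] = True
        assert tube_length(bar) == pytest.approx(60, rel=0.10)


def _straight_stroke(angle_deg):
    theta = np.deg2rad(angle_deg)
    t = np.linspace(0, 60, 120)
    pts = np.stack([80 - t * np.sin(theta), 80 + t * np.cos(theta)], axis=1)
    rr, cc = np.mgrid[0:160, 0:160]
    stroke = np.zeros((160, 160), dtype=bool)
    for p in pts:
        stroke |= (rr - p[0]) ** 2 + (cc - p[1]) ** 2 <= 1.5**2
    return stroke


@pytest.mark.parametrize("angle_deg", [15, 30, 45, 60, 90, 135, 180])
def test_tube_length_rotation_invariant(angle_deg):
    """A straight 60-px stroke measures within 10% of its unrotated length."""
    base = tube_length(_straight_stroke(0))
    rotated = tube_length(_straight_stroke(angle_deg))
    assert rotated == pytest.approx(base, rel=0.10)
    assert base == pytest.approx(60, rel=0.10)


class TestClassify:
    @pytest.mark.parametrize(
        "length,diameter,germinated",
        [(50, 30, True), (30, 30, False), (0, 30, False), (30.001, 30, True)],
    )
    def test_strict_length_rule(self, length, diameter, germinated):
        m = TubeMeasurement(grain_label=1, tube_length=length, grain_diameter=diameter)
        assert m.germinated is germinated
        det = Detection(point=(0, 0), region_label=1, source="auto", category="total")
        (out,) = classify_germination([det], [m])
        assert (out.category == "germinated") is germinated

    def test_manual_detections_pass_through(self):
        det = Detection(point=(0, 0), region_label=None, source="manual", category="total")
        assert classify_germination([det], []) == [det]


def test_measure_tubes_end_to_end():
    """Tube length of a disc+appendage scene lands within rasterization error."""
    mask = _scene_with_tube(radius=14, tube_len=60)
    grains = label_regions(suppress_tubes(mask, 4))
    (m,) = measure_tubes(mask, grains)
    assert m.grain_diameter == pytest.approx(28, abs=1.5)
    assert m.tube_length == pytest.approx(60, rel=0.15)
    assert m.germinated  # 60 > 28


def test_clump_tube_assigned_to_nearest_grain():
    """Overlapping grains sharing one component: only the grain nearer the
    tube scores its length, the other scores 0."""
    from pollenquant.detection import RegionShape

    px = np.zeros((120, 260), dtype=bool)
    px |= _disc(px.shape, (60, 60), 14)
    px |= _disc(px.shape, (60, 80), 14)  # overlapping neighbour: one component
    px[59:62, 94:174] = True  # 80-px tube off the right grain
    mask = BinaryMask(px, "clump")

    def grain(label, col):
        return RegionShape(
            label=label,
            area=616,
            centroid=(60.0, float(col)),
            major_axis_length=28.0,
            minor_axis_length=28.0,
            eccentricity=0.0,
            equivalent_diameter=28.0,
        )

    measurements = measure_tubes(mask, [grain(1, 60), grain(2, 80)])
    by_label = {m.grain_label: m for m in measurements}
    assert by_label[1].tube_length == 0.0
    assert by_label[2].tube_length == pytest.approx(80, rel=0.2)
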