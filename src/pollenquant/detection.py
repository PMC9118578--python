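"""Grain candidate detection by region shape.

Pollen grains are nearly circular, while tubes, debris and clumps are
elongated.  Each 8-connected foreground component is summarised by its
moment-based shape statistics and accepted as a grain when its eccentricity
is strictly below a cut-off (default 0.65; a circle has eccentricity 0, a
line approaches 1).

Eccentricity is computed from the eigenvalues l1 >= l2 of the region's
second-central-moment matrix as sqrt(1 - l2/l1), which for a solid ellipse
recovers the analytic value sqrt(1 - (b/a)^2).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Optional

import numpy as np
from skimage import measure, morphology

from .segmentation import BinaryMask

Category = Literal["total", "germinated"]
Source = Literal["auto", "manual"]

DEFAULT_ECCENTRICITY_MAX = 0.65


@dataclass(frozen=True)
class RegionShape:
    """Moment-based geometry of one connected foreground region.

    ``equivalent_diameter`` is the diameter of the circle with the region's
    area, 2*sqrt(area/pi).  Axis lengths are those of the ellipse with the
    same second central moments as the region.
    """

    label: int
    area: int
    centroid: tuple[float, float]  # (row, col)
    major_axis_length: float
    minor_axis_length: float
    eccentricity: float
    equivalent_diameter: float


@dataclass(frozen=True)
class Detection:
    """A point marking one pollen grain.

    Automatic detections carry the label of the region they came from;
    manual ones (from correction edits) do not.  ``germinated`` detections
    are also counted in the total class.
    """

    point: tuple[float, float]  # (row, col)
    region_label: Optional[int]
    source: Source
    category: Category

    def as_germinated(self) -> "Detection":
        return replace(self, category="germinated")

    def as_total(self) -> "Detection":
        return replace(self, category="total")


def label_regions(mask: BinaryMask) -> list[RegionShape]:
    """Label 8-connected components and measure their shape statistics.

    Labels are consecutive positive integers in raster-scan order of each
    component's first pixel.  An empty mask yields an empty list.
    """
    labels = measure.label(mask.pixels, connectivity=2)
    shapes: list[RegionShape] = []
    for props in measure.regionprops(labels):
        shapes.append(
            RegionShape(
                label=int(props.label),
                area=int(props.area),
                centroid=(float(props.centroid[0]), float(props.centroid[1])),
                major_axis_length=float(props.axis_major_length),
                minor_axis_length=float(props.axis_minor_length),
                eccentricity=float(props.eccentricity),
                equivalent_diameter=float(props.equivalent_diameter_area),
            )
        )
    shapes.sort(key=lambda s: s.label)
    return shapes


def detect_discs(
    regions: list[RegionShape], eccentricity_max: float = DEFAULT_ECCENTRICITY_MAX
) -> list[Detection]:
    """Accept regions with eccentricity strictly under the cut-off as grains.

    Returns one automatic total-class detection per accepted region, placed
    at the region centroid, in region label order.  Regions exactly at the
    cut-off are rejected.
    """
    if not 0 <= eccentricity_max < 1:
        raise ValueError(f"eccentricity_max must be in [0, 1), got {eccentricity_max}")
    return [
        Detection(point=r.centroid, region_label=r.label, source="auto", category="total")
        for r in regions
        if r.eccentricity < eccentricity_max
    ]


def suppress_tubes(mask: BinaryMask, opening_radius: int = 4) -> BinaryMask:
    """Erase thin tube strokes by a morphological opening, keeping grain bodies.

    A grain that has already extended a tube forms one elongated component
    whose eccentricity exceeds the disc cut-off, so it would be missed by
    shape filtering alone.  Opening with a disc structuring element removes
    structures narrower than about twice the radius (tubes are a few pixels
    wide) while grain bodies, an order of magnitude wider, survive with
    their shape essentially intact.  Running disc detection on the opened
    mask therefore finds germinated and non-germinated grains alike; tube
    geometry is measured afterwards on the original mask.
    """
    if opening_radius <= 0:
        return BinaryMask(mask.pixels.copy(), mask.source_image_id)
    footprint = morphology.disk(opening_radius)
    opened = morphology.opening(mask.pixels, footprint)
    return BinaryMask(opened, mask.source_image_id)
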