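"""Automated germination scoring by tube length.

A pollen grain counts as germinated only when the tube it has extended is
longer than the grain's own diameter.  In the interactive workflow that
judgement is made by eye; here it is automated: the tube is the part of the
grain's connected component lying outside the grain disc, its length is the
geodesic length of its morphological skeleton (orthogonal steps count 1,
diagonal steps sqrt(2)), and the strict rule ``tube_length > grain_diameter``
decides germination.  Automatic marks remain overridable by correction
edits downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from skimage import measure, morphology

from .detection import Detection, RegionShape
from .segmentation import BinaryMask

_SQRT2 = float(np.sqrt(2.0))

# A rasterized disc's rim extends slightly past the circle with its
# equivalent diameter (pixelation loses area at the rim), so the excision
# disc gets a one-pixel margin to avoid leaving rim slivers behind.
RIM_MARGIN = 1.0


@dataclass(frozen=True)
class TubeMeasurement:
    """Tube length versus grain diameter for one detected grain."""

    grain_label: int
    tube_length: float
    grain_diameter: float

    @property
    def germinated(self) -> bool:
        return self.tube_length > self.grain_diameter


def _component_label_at(labels: np.ndarray, grain: RegionShape) -> int:
    """Label of the mask component holding the grain, located by centroid.

    The grain may have been measured on a tube-suppressed mask, so labels
    are matched spatially: the nearest foreground pixel to the grain
    centroid within one grain radius.
    """
    h, w = labels.shape
    r0, c0 = grain.centroid
    ri, ci = int(round(r0)), int(round(c0))
    if 0 <= ri < h and 0 <= ci < w and labels[ri, ci] > 0:
        return int(labels[ri, ci])
    radius = max(2, int(np.ceil(grain.equivalent_diameter / 2)) + 1)
    rlo, rhi = max(0, ri - radius), min(h, ri + radius + 1)
    clo, chi = max(0, ci - radius), min(w, ci + radius + 1)
    window = labels[rlo:rhi, clo:chi]
    rows, cols = np.nonzero(window)
    if rows.size == 0:
        raise KeyError(f"grain {grain.label} has no foreground component near {grain.centroid}")
    dist2 = (rows + rlo - r0) ** 2 + (cols + clo - c0) ** 2
    best = int(np.argmin(dist2))
    return int(window[rows[best], cols[best]])


def _disc_stamp(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def extract_tube(mask: BinaryMask, grain: RegionShape) -> np.ndarray:
    """Pixels of the grain's component outside the grain disc.

    The disc has the grain's equivalent diameter (plus a one-pixel
    rasterization margin) and is centred at its centroid; a bare, tube-less
    grain therefore yields an empty tube mask.  Raises ``KeyError`` when no
    component lies near the grain centroid.
    """
    labels = measure.label(mask.pixels, connectivity=2)
    comp = _component_label_at(labels, grain)
    component = labels == comp
    disc = _disc_stamp(mask.shape, grain.centroid, grain.equivalent_diameter / 2.0 + RIM_MARGIN)
    return component & ~disc


def tube_length(tube_mask: np.ndarray) -> float:
    """Geodesic skeleton length of a tube mask, in pixels.

    The mask is skeletonised and each connected skeleton piece measured as
    the longest shortest path between its pixels (unit cost for orthogonal
    steps, sqrt(2) for diagonal); the longest piece is reported, so stray
    specks do not inflate the estimate.  Empty masks measure 0.
    """
    tube_mask = np.asarray(tube_mask, dtype=bool)
    if not tube_mask.any():
        return 0.0
    # Lee's method: markedly less end/segment erosion than Zhang thinning
    # on the diagonal staircase patterns thin tubes produce
    skel = morphology.skeletonize(tube_mask, method="lee").astype(bool)
    if not skel.any():
        # A mask too small to carry a skeleton is not a measurable tube.
        return 0.0
    pieces = measure.label(skel, connectivity=2)
    best = 0.0
    for lab in range(1, pieces.max() + 1):
        best = max(best, _geodesic_diameter(pieces == lab))
    return best


def _geodesic_diameter(skel: np.ndarray) -> float:
    """Longest shortest path within one connected skeleton piece.

    Uses the two-sweep heuristic (farthest point from an arbitrary start,
    then farthest from that), exact on trees — which branchless or mildly
    branched skeletons are.
    """
    rows, cols = np.nonzero(skel)
    n = rows.size
    if n == 1:
        return 0.0
    index = {(int(r), int(c)): i for i, (r, c) in enumerate(zip(rows, cols))}
    src, dst, wts = [], [], []
    for (r, c), i in index.items():
        for dr, dc in ((0, 1), (1, -1), (1, 0), (1, 1)):
            j = index.get((r + dr, c + dc))
            if j is not None:
                w = 1.0 if dr == 0 or dc == 0 else _SQRT2
                src.append(i)
                dst.append(j)
                wts.append(w)
    graph = coo_matrix((wts + wts, (src + dst, dst + src)), shape=(n, n)).tocsr()
    d0 = dijkstra(graph, indices=0, directed=False)
    far = int(np.argmax(np.where(np.isfinite(d0), d0, -1)))
    d1 = dijkstra(graph, indices=far, directed=False)
    d1 = d1[np.isfinite(d1)]
    return float(d1.max())


def measure_tubes(mask: BinaryMask, grains: list[RegionShape]) -> list[TubeMeasurement]:
    """Measure tube length for every detected grain.

    Each grain's tube is sought within its own connected component of the
    full (unsuppressed) mask.  When several detected grains share one
    component — a clump with a tube — the tube is credited to the grain
    whose centroid is nearest to it and the others score 0, erring toward
    under-calling so that manual correction can resolve the clump.
    """
    labels = measure.label(mask.pixels, connectivity=2)
    by_component: dict[int, list[RegionShape]] = {}
    for grain in grains:
        comp = _component_label_at(labels, grain)
        by_component.setdefault(comp, []).append(grain)

    results: dict[int, TubeMeasurement] = {}
    for comp, members in by_component.items():
        component = labels == comp
        tube = component.copy()
        for grain in members:
            tube &= ~_disc_stamp(
                mask.shape, grain.centroid, grain.equivalent_diameter / 2.0 + RIM_MARGIN
            )
        length = tube_length(tube)
        if len(members) == 1 or length == 0.0:
            owner = members[0]
        else:
            trows, tcols = np.nonzero(tube)
            dists = [
                np.min((trows - g.centroid[0]) ** 2 + (tcols - g.centroid[1]) ** 2)
                for g in members
            ]
            owner = members[int(np.argmin(dists))]
        for grain in members:
            results[grain.label] = TubeMeasurement(
                grain_label=grain.label,
                tube_length=length if grain.label == owner.label else 0.0,
                grain_diameter=grain.equivalent_diameter,
            )
    return [results[g.label] for g in grains]


def classify_germination(
    detections: list[Detection], measurements: list[TubeMeasurement]
) -> list[Detection]:
    """Set the germinated mark on detections whose tube exceeds the grain diameter.

    The rule is strict: a tube exactly as long as the diameter does not
    germinate the grain.  Detections without a matching measurement are
    returned unchanged.
    """
    germinated_labels = {m.grain_label for m in measurements if m.germinated}
    out = []
    for det in detections:
        if det.region_label is not None and det.region_label in germinated_labels:
            out.append(det.as_germinated())
        else:
            out.append(det)
    return out
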