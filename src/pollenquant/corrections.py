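"""Manual-correction semantics and germination counts.

The published workflow is interactive: after automatic disc detection the
user clicks to add missed grains, remove false positives, and mark which
grains have germinated.  Here the clicks are an ordered list of edits, each
a point with a category (``total`` or ``germinated``) and an action (``add``
or ``remove``).  Edits act on the nearest existing detection within a match
radius; replay of the same edit list is deterministic (ties broken by
smallest row, then smallest column).

A detection with category ``germinated`` is still a grain, so it counts in
both classes; germinated marks attach to grains, which enforces
``n_germinated <= n_total``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .detection import Detection

DEFAULT_MATCH_RADIUS = 15.0

CATEGORIES = ("total", "germinated")
ACTIONS = ("add", "remove")


@dataclass(frozen=True)
class Edit:
    """One correction: a point, the class it concerns, and add/remove."""

    row: float
    col: float
    category: str
    action: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}; expected one of {CATEGORIES}")
        if self.action not in ACTIONS:
            raise ValueError(f"unknown action {self.action!r}; expected one of {ACTIONS}")

    @property
    def point(self) -> tuple[float, float]:
        return (self.row, self.col)


@dataclass(frozen=True)
class CorrectionSet:
    """An ordered list of edits applying to one image."""

    image_id: str
    edits: tuple[Edit, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "edits", tuple(self.edits))

    def __len__(self) -> int:
        return len(self.edits)


@dataclass(frozen=True)
class CountResult:
    """Germination counts for one image.

    ``percent_germination`` is 100 * n_germinated / n_total, or ``None``
    (with ``undefined`` set) when the image contains no grains.
    """

    image_id: str
    n_total: int
    n_germinated: int

    @property
    def percent_germination(self) -> float | None:
        if self.n_total == 0:
            return None
        return 100.0 * self.n_germinated / self.n_total

    @property
    def undefined(self) -> bool:
        return self.n_total == 0


def _nearest(
    detections: list[Detection],
    point: tuple[float, float],
    radius: float,
    predicate=lambda d: True,
) -> int | None:
    """Index of the nearest eligible detection within ``radius``, or None.

    Equidistant candidates resolve to the smallest row, then smallest col.
    """
    best: tuple[float, float, float] | None = None
    best_idx: int | None = None
    for i, det in enumerate(detections):
        if not predicate(det):
            continue
        dist = math.hypot(det.point[0] - point[0], det.point[1] - point[1])
        if dist > radius:
            continue
        key = (dist, det.point[0], det.point[1])
        if best is None or key < best:
            best = key
            best_idx = i
    return best_idx


def apply_corrections(
    auto: list[Detection],
    corrections: CorrectionSet,
    match_radius: float = DEFAULT_MATCH_RADIUS,
) -> tuple[list[Detection], list[Edit]]:
    """Apply an ordered edit list to a detection set.

    Semantics per edit:

    * ``add total`` — append a manual total detection at the point.
    * ``remove total`` — delete the nearest detection within the radius
      (along with any germinated mark it carries).
    * ``add germinated`` — mark the nearest detection within the radius as
      germinated; if none is near enough, create a manual germinated grain
      at the point.
    * ``remove germinated`` — clear the germinated mark of the nearest
      germinated detection within the radius, keeping the grain.

    Returns the updated detections and the list of remove edits that
    matched nothing (reported, never raised).
    """
    if match_radius <= 0:
        raise ValueError("match_radius must be > 0")
    detections = list(auto)
    unmatched: list[Edit] = []
    for edit in corrections.edits:
        if edit.action == "add" and edit.category == "total":
            detections.append(
                Detection(point=edit.point, region_label=None, source="manual", category="total")
            )
        elif edit.action == "remove" and edit.category == "total":
            idx = _nearest(detections, edit.point, match_radius)
            if idx is None:
                unmatched.append(edit)
            else:
                del detections[idx]
        elif edit.action == "add" and edit.category == "germinated":
            idx = _nearest(detections, edit.point, match_radius)
            if idx is None:
                detections.append(
                    Detection(
                        point=edit.point, region_label=None, source="manual", category="germinated"
                    )
                )
            else:
                detections[idx] = detections[idx].as_germinated()
        else:  # remove germinated
            idx = _nearest(
                detections, edit.point, match_radius, predicate=lambda d: d.category == "germinated"
            )
            if idx is None:
                unmatched.append(edit)
            else:
                detections[idx] = detections[idx].as_total()
    return detections, unmatched


def count(detections: list[Detection], image_id: str = "") -> CountResult:
    """Tally total and germinated grains for one image.

    Every detection is a grain (total class); those carrying the germinated
    mark are additionally counted germinated.  The germination percentage is
    100 * n_germinated / n_total, undefined for an empty image.
    """
    n_total = len(detections)
    n_germ = sum(1 for d in detections if d.category == "germinated")
    return CountResult(image_id=image_id, n_total=n_total, n_germinated=n_germ)
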