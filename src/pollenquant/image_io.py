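"""Reading and writing micrographs, annotation files, and tabular results.

Micrographs come in as PNG/TIFF/JPEG and are normalised to 8-bit RGB
(greyscale promoted by channel replication, 16-bit rescaled by integer
division by 257 so the fixed grey-level threshold keeps its meaning).
Annotations are a diff-friendly CSV dialect, ``row,col,category,action``,
with 0-based pixel coordinates, row 0 at the top.  Overlays mirror the
conventional review rendering: a red X on every counted grain, a blue X on
the germinated ones, germinated drawn on top.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .corrections import ACTIONS, CATEGORIES, CorrectionSet, CountResult, Edit
from .detection import Detection, RegionShape
from .segmentation import BinaryMask, RgbImage

RED = (255, 0, 0)
BLUE = (0, 0, 255)


class ImageDecodeError(ValueError):
    """Raised when a file cannot be decoded into an 8-bit RGB raster."""


class AnnotationParseError(ValueError):
    """Raised on malformed annotation rows; carries the line number."""


def read_image(path: str | Path) -> RgbImage:
    """Load a micrograph as 8-bit RGB; the image id is the filename stem."""
    path = Path(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:  # imageio raises format-specific types
        raise ImageDecodeError(f"cannot decode image {path}: {exc}") from exc
    raw = np.asarray(raw)
    if raw.dtype == np.uint16:
        raw = (raw // 257).astype(np.uint8)
    elif raw.dtype == bool:
        raise ImageDecodeError(f"cannot decode image {path}: 1-bit images are not supported")
    elif raw.dtype != np.uint8:
        raise ImageDecodeError(f"cannot decode image {path}: unsupported dtype {raw.dtype}")
    if raw.ndim == 2:
        raw = np.repeat(raw[:, :, None], 3, axis=2)
    elif raw.ndim == 3 and raw.shape[2] == 4:
        raw = raw[:, :, :3]
    if raw.ndim != 3 or raw.shape[2] != 3:
        raise ImageDecodeError(f"cannot decode image {path}: unexpected shape {raw.shape}")
    return RgbImage(raw, path.stem)


def write_image(image: RgbImage, path: str | Path) -> None:
    iio.imwrite(Path(path), image.pixels)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a binary mask as an 8-bit PNG (foreground 255)."""
    iio.imwrite(Path(path), mask.pixels.astype(np.uint8) * 255)


ANNOTATION_HEADER = ["row", "col", "category", "action"]


def read_annotations(path: str | Path, image_id: str | None = None) -> CorrectionSet:
    """Parse a ``row,col,category,action`` CSV into an ordered correction set.

    The image id defaults to the filename stem.  Unknown category or action
    tokens and non-numeric coordinates raise
    :class:`AnnotationParseError` with the offending line number.
    """
    path = Path(path)
    if image_id is None:
        image_id = path.stem
    edits: list[Edit] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != ANNOTATION_HEADER:
            raise AnnotationParseError(
                f"{path}:1: expected header {','.join(ANNOTATION_HEADER)!r}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) != 4:
                raise AnnotationParseError(f"{path}:{lineno}: expected 4 fields, got {len(row)}")
            r_str, c_str, category, action = (cell.strip() for cell in row)
            try:
                r, c = float(r_str), float(c_str)
            except ValueError as exc:
                raise AnnotationParseError(f"{path}:{lineno}: bad coordinate: {exc}") from exc
            if r < 0 or c < 0:
                raise AnnotationParseError(f"{path}:{lineno}: negative coordinate ({r}, {c})")
            if category not in CATEGORIES:
                raise AnnotationParseError(
                    f"{path}:{lineno}: unknown category {category!r}; expected one of {CATEGORIES}"
                )
            if action not in ACTIONS:
                raise AnnotationParseError(
                    f"{path}:{lineno}: unknown action {action!r}; expected one of {ACTIONS}"
                )
            edits.append(Edit(row=r, col=c, category=category, action=action))
    return CorrectionSet(image_id=image_id, edits=tuple(edits))


def write_annotations(corrections: CorrectionSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(ANNOTATION_HEADER)
        for e in corrections.edits:
            writer.writerow([_fmt_coord(e.row), _fmt_coord(e.col), e.category, e.action])


def _fmt_coord(value: float) -> str:
    return str(int(value)) if float(value).is_integer() else repr(float(value))


def _draw_x(pixels: np.ndarray, point: tuple[float, float], color, arm: int = 6) -> None:
    h, w = pixels.shape[:2]
    r0, c0 = int(round(point[0])), int(round(point[1]))
    for d in range(-arm, arm + 1):
        for dr, dc in ((d, d), (d, -d)):
            r, c = r0 + dr, c0 + dc
            if 0 <= r < h and 0 <= c < w:
                pixels[r, c] = color


def write_overlay(image: RgbImage, detections: Iterable[Detection], path: str | Path) -> None:
    """Write a review overlay: red X per grain, blue X per germinated grain.

    Germinated grains receive both glyphs with the blue one rendered last
    (on top), matching the two-pass counting convention.
    """
    pixels = image.pixels.copy()
    dets = list(detections)
    for det in dets:
        _draw_x(pixels, det.point, RED)
    for det in dets:
        if det.category == "germinated":
            _draw_x(pixels, det.point, BLUE)
    iio.imwrite(Path(path), pixels)


def detections_to_frame(detections: Iterable[Detection]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "row": d.point[0],
                "col": d.point[1],
                "region_label": d.region_label if d.region_label is not None else "",
                "source": d.source,
                "category": d.category,
            }
            for d in detections
        ],
        columns=["row", "col", "region_label", "source", "category"],
    )


def detections_from_frame(frame: pd.DataFrame) -> list[Detection]:
    out = []
    for rec in frame.itertuples(index=False):
        label = rec.region_label
        label = None if label == "" or pd.isna(label) else int(label)
        out.append(
            Detection(
                point=(float(rec.row), float(rec.col)),
                region_label=label,
                source=str(rec.source),
                category=str(rec.category),
            )
        )
    return out


def regions_to_frame(regions: Iterable[RegionShape]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label": r.label,
                "area": r.area,
                "centroid_row": r.centroid[0],
                "centroid_col": r.centroid[1],
                "major_axis_length": r.major_axis_length,
                "minor_axis_length": r.minor_axis_length,
                "eccentricity": r.eccentricity,
                "equivalent_diameter": r.equivalent_diameter,
            }
            for r in regions
        ],
        columns=[
            "label",
            "area",
            "centroid_row",
            "centroid_col",
            "major_axis_length",
            "minor_axis_length",
            "eccentricity",
            "equivalent_diameter",
        ],
    )


def counts_to_frame(results: Iterable[CountResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "image_id": r.image_id,
                "n_total": r.n_total,
                "n_germinated": r.n_germinated,
                "percent_germination": (
                    r.percent_germination if r.percent_germination is not None else np.nan
                ),
                "undefined": r.undefined,
            }
            for r in results
        ],
        columns=["image_id", "n_total", "n_germinated", "percent_germination", "undefined"],
    )
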