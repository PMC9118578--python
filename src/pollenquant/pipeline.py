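"""End-to-end batch pipeline: images in, counts and statistics out.

The stages mirror the semi-automated counting workflow: segment each
micrograph, detect grain candidates by eccentricity, optionally score
germination automatically from tube skeleton length, merge any per-image
correction files, and aggregate counts into per-sample summaries and
pairwise Welch tests between conditions.  Every run writes its effective
configuration next to the outputs so results are reproducible from that
file plus the inputs alone.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import image_io
from .corrections import CorrectionSet, CountResult, apply_corrections, count
from .detection import (
    DEFAULT_ECCENTRICITY_MAX,
    Detection,
    detect_discs,
    label_regions,
    suppress_tubes,
)
from .germination import classify_germination, measure_tubes
from .segmentation import RgbImage, SegmentationConfig, segment
from .stats import EmptySampleError, summarize_sample, welch_t

logger = logging.getLogger(__name__)

IMAGE_SUFFIXES = (".png", ".tif", ".tiff", ".jpg", ".jpeg")


@dataclass(frozen=True)
class RunConfig:
    """Effective configuration of one pipeline run (round-trippable)."""

    channel: str = "blue"
    threshold: int = 150
    polarity: str = "dark_objects"
    min_object_area: int = 50
    fill_holes: bool = True
    eccentricity_max: float = DEFAULT_ECCENTRICITY_MAX
    match_radius: float = 15.0
    auto_germination: bool = True
    tube_opening_radius: int = 4
    seed: int = 0

    def segmentation(self) -> SegmentationConfig:
        return SegmentationConfig(
            channel=self.channel,
            threshold=self.threshold,
            polarity=self.polarity,
            min_object_area=self.min_object_area,
            fill_holes=self.fill_holes,
        )

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for key, value in asdict(self).items():
                fh.write(f"{key}={value}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kwargs = {}
        casts = {"int": int, "float": float, "str": str, "bool": lambda s: s == "True"}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, raw = line.partition("=")
                base = type(getattr(cls(), key)).__name__
                kwargs[key] = casts[base](raw)
        return cls(**kwargs)


@dataclass
class ImageResult:
    """Everything the pipeline derived from one micrograph."""

    image_id: str
    detections: list[Detection]
    counts: CountResult
    unmatched_edits: int = 0
    measurements: list = field(default_factory=list)


def process_image(
    image: RgbImage,
    config: RunConfig,
    corrections: Optional[CorrectionSet] = None,
) -> ImageResult:
    """Run segmentation, detection, scoring and correction on one image.

    With ``auto_germination`` on, disc detection runs on a tube-suppressed
    copy of the mask so grains that have extended a tube are still found,
    and each grain's tube is measured on the original mask.  With it off,
    detection follows the raw mask and germinated marks come only from
    correction edits.
    """
    mask = segment(image, config.segmentation())
    if config.auto_germination:
        grain_mask = suppress_tubes(mask, config.tube_opening_radius)
        regions = label_regions(grain_mask)
        detections = detect_discs(regions, config.eccentricity_max)
        detected = {d.region_label for d in detections}
        grains = [r for r in regions if r.label in detected]
        measurements = measure_tubes(mask, grains) if grains else []
        detections = classify_germination(detections, measurements)
    else:
        regions = label_regions(mask)
        detections = detect_discs(regions, config.eccentricity_max)
        measurements = []

    unmatched = 0
    if corrections is not None and len(corrections):
        detections, unmatched_edits = apply_corrections(
            detections, corrections, config.match_radius
        )
        unmatched = len(unmatched_edits)

    counts = count(detections, image.image_id)
    return ImageResult(
        image_id=image.image_id,
        detections=detections,
        counts=counts,
        unmatched_edits=unmatched,
        measurements=measurements,
    )


@dataclass
class RunReport:
    counts: pd.DataFrame
    samples: pd.DataFrame
    stats: pd.DataFrame
    n_failed: int


def run_pipeline(
    input_dir: str | Path,
    out_dir: str | Path,
    config: RunConfig | None = None,
    corrections_dir: str | Path | None = None,
    condition_map: str | Path | None = None,
    write_overlays: bool = True,
    write_masks: bool = False,
) -> RunReport:
    """Process every image in ``input_dir`` and write all result files.

    Per image: detections CSV, region-statistics CSV, optional mask and
    overlay PNGs.  Per run: ``counts.csv``, ``sample_summary.csv``,
    ``welch_tests.csv`` (when a condition map with >= 2 samples per
    condition is given), ``run_config.txt`` and ``run.log``.  Correction
    files are looked up as ``<image_id>.csv`` in ``corrections_dir``.
    Per-image failures are logged and skipped; the report carries the count.
    """
    config = config or RunConfig()
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    paths = sorted(p for p in input_dir.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES)
    if not paths:
        raise FileNotFoundError(f"no readable images ({'/'.join(IMAGE_SUFFIXES)}) in {input_dir}")
    out_dir.mkdir(parents=True, exist_ok=True)

    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    config.to_file(out_dir / "run_config.txt")

    results: list[ImageResult] = []
    n_failed = 0
    try:
        for path in paths:
            t0 = time.perf_counter()
            try:
                image = image_io.read_image(path)
                corrections = None
                if corrections_dir is not None:
                    cpath = Path(corrections_dir) / f"{path.stem}.csv"
                    if cpath.exists():
                        corrections = image_io.read_annotations(cpath, image_id=path.stem)
                result = process_image(image, config, corrections)
            except Exception:
                logger.exception("failed on %s", path.name)
                n_failed += 1
                continue
            results.append(result)
            image_io.detections_to_frame(result.detections).to_csv(
                out_dir / f"{result.image_id}_detections.csv", index=False
            )
            if write_overlays:
                image_io.write_overlay(
                    image, result.detections, out_dir / f"{result.image_id}_overlay.png"
                )
            if write_masks:
                image_io.write_mask(
                    segment(image, config.segmentation()), out_dir / f"{result.image_id}_mask.png"
                )
            logger.info(
                "%s: n_total=%d n_germinated=%d unmatched_edits=%d (%.2fs)",
                result.image_id,
                result.counts.n_total,
                result.counts.n_germinated,
                result.unmatched_edits,
                time.perf_counter() - t0,
            )
    finally:
        logger.removeHandler(handler)
        handler.close()

    counts_df = image_io.counts_to_frame([r.counts for r in results])
    counts_df.to_csv(out_dir / "counts.csv", index=False)

    samples_df, stats_df = aggregate(counts_df, condition_map)
    samples_df.to_csv(out_dir / "sample_summary.csv", index=False)
    stats_df.to_csv(out_dir / "welch_tests.csv", index=False)
    return RunReport(counts=counts_df, samples=samples_df, stats=stats_df, n_failed=n_failed)


def aggregate(
    counts: pd.DataFrame, condition_map: str | Path | pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fold per-image counts into per-sample means and pairwise Welch tests.

    The condition map is a table ``image_id,sample_id,condition``; without
    one, each image is its own sample in a single unnamed condition.  The
    test unit is the per-sample mean percentage.
    """
    if condition_map is None:
        cmap = pd.DataFrame(
            {
                "image_id": counts["image_id"],
                "sample_id": counts["image_id"],
                "condition": "all",
            }
        )
    elif isinstance(condition_map, pd.DataFrame):
        cmap = condition_map
    else:
        cmap = pd.read_csv(condition_map, dtype=str)

    merged = counts.merge(cmap, on="image_id", how="left")
    sample_rows = []
    for (sample_id, condition), grp in merged.groupby(["sample_id", "condition"], sort=True):
        image_results = [
            CountResult(
                image_id=rec.image_id,
                n_total=int(rec.n_total),
                n_germinated=int(rec.n_germinated),
            )
            for rec in grp.itertuples(index=False)
        ]
        try:
            summary = summarize_sample(image_results, sample_id)
        except EmptySampleError:
            sample_rows.append(
                {
                    "sample_id": sample_id,
                    "condition": condition,
                    "mean_percent": np.nan,
                    "n_images": 0,
                    "n_excluded": len(image_results),
                }
            )
            continue
        sample_rows.append(
            {
                "sample_id": sample_id,
                "condition": condition,
                "mean_percent": summary.mean_percent,
                "n_images": summary.n_images,
                "n_excluded": summary.n_excluded,
            }
        )
    samples_df = pd.DataFrame(
        sample_rows, columns=["sample_id", "condition", "mean_percent", "n_images", "n_excluded"]
    )

    stats_rows = []
    conditions = sorted(samples_df["condition"].dropna().unique())
    for i, cond_a in enumerate(conditions):
        for cond_b in conditions[i + 1 :]:
            a = samples_df.loc[samples_df["condition"] == cond_a, "mean_percent"].dropna()
            b = samples_df.loc[samples_df["condition"] == cond_b, "mean_percent"].dropna()
            if len(a) < 2 or len(b) < 2:
                continue
            res = welch_t(a.to_numpy(), b.to_numpy())
            stats_rows.append(
                {
                    "condition_a": cond_a,
                    "condition_b": cond_b,
                    "mean_a": res.group_means[0],
                    "mean_b": res.group_means[1],
                    "median_a": res.group_medians[0],
                    "median_b": res.group_medians[1],
                    "n_a": res.group_ns[0],
                    "n_b": res.group_ns[1],
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                }
            )
    stats_df = pd.DataFrame(
        stats_rows,
        columns=[
            "condition_a",
            "condition_b",
            "mean_a",
            "mean_b",
            "median_a",
            "median_b",
            "n_a",
            "n_b",
            "t",
            "df",
            "p",
        ],
    )
    return samples_df, stats_df
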