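"""Synthetic pollen-field micrographs with exact ground truth.

Emulates a 5x brightfield view of pollen spread on a germination-medium
droplet: a bright background carrying on the order of 50 dark, hard-edged
circular grains, a fraction of which bear a curved tube rendered as a
smooth random-walk stroke of known arc length.  Optional additive Gaussian
noise and a radial illumination gradient mimic camera noise and uneven
lighting.  Every stochastic draw flows from a single seeded generator, so
identical specs produce bit-identical images and ground truth.

Tube curvature is bounded, keeping strokes non-self-intersecting so that
skeleton length is a valid proxy for true arc length.  Drop-edge
aggregation gradients seen in real droplets are deliberately not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from skimage import morphology

from . import image_io
from .segmentation import RgbImage


class PlacementError(RuntimeError):
    """Raised when grains cannot be placed without overlap within the retry budget."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic field of view.

    Defaults describe the study conditions the generator emulates: a
    1040x1392 view holding a Poisson(50) number of grains of radius
    ~N(14, 2) px truncated at 8, grey objects (intensity 90) on a bright
    background (220) so the blue channel thresholds cleanly at 150, tubes
    3 px wide with per-grain length drawn as a uniform multiple of the
    grain diameter.  ``germinated_fraction`` is the fraction of grains
    bearing a tube; whether a tube-bearing grain counts as germinated in
    the ground truth follows the length rule (tube longer than diameter).
    ``n_grains=None`` means "draw from Poisson"; pass an integer for exact
    control.
    """

    field_size: tuple[int, int] = (1040, 1392)
    n_grains: Optional[int] = None
    mean_grains: float = 50.0
    grain_radius_mean: float = 14.0
    grain_radius_sd: float = 2.0
    grain_radius_min: float = 8.0
    germinated_fraction: float = 0.4
    tube_length_factor: tuple[float, float] = (0.5, 2.0)
    tube_width: float = 3.0
    tube_curvature: float = 0.05  # max heading change, radians per px step
    overlap_allowed: bool = False
    background_level: int = 220
    grain_level: int = 90
    noise_sd: float = 8.0
    illumination_gradient: float = 0.0  # fractional dimming at the field corners
    seed: int = 0
    min_gap: int = 4  # enforced blank margin between components, px

    def __post_init__(self) -> None:
        if not 0.0 <= self.germinated_fraction <= 1.0:
            raise ValueError("germinated_fraction must be in [0, 1]")
        lo, hi = self.tube_length_factor
        if lo > hi or lo < 0:
            raise ValueError("tube_length_factor must be a non-negative (lo, hi) interval")

    def with_(self, **kwargs) -> "SceneSpec":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class GrainTruth:
    center: tuple[float, float]  # (row, col)
    radius: float
    has_tube: bool
    tube_length: float  # true centreline arc length, px; 0 without a tube

    @property
    def germinated(self) -> bool:
        """A grain is germinated only when its tube exceeds its diameter."""
        return self.tube_length > 2.0 * self.radius


@dataclass(frozen=True)
class GroundTruth:
    """Exact per-grain and per-field truth for one synthetic image."""

    image_id: str
    grains: tuple[GrainTruth, ...]

    @property
    def n_grains(self) -> int:
        return len(self.grains)

    @property
    def n_germinated(self) -> int:
        return sum(1 for g in self.grains if g.germinated)

    @property
    def percent(self) -> float | None:
        if self.n_grains == 0:
            return None
        return 100.0 * self.n_germinated / self.n_grains


def _tube_path(
    start: tuple[float, float],
    heading: float,
    length: float,
    curvature: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-step random-walk centreline of a tube; rows of (row, col)."""
    n_steps = max(1, int(round(length)))
    turns = rng.uniform(-curvature, curvature, size=n_steps)
    headings = heading + np.cumsum(turns)
    steps = np.stack([np.sin(headings), np.cos(headings)], axis=1)
    return np.asarray(start)[None, :] + np.cumsum(steps, axis=0)


def _self_approaches(path: np.ndarray, min_sep: float, lag: int = 10) -> bool:
    """True when two points more than ``lag`` steps apart come within ``min_sep``."""
    diff = path[:, None, :] - path[None, :, :]
    d2 = (diff**2).sum(axis=2)
    idx = np.arange(len(path))
    far_apart = np.abs(idx[:, None] - idx[None, :]) > lag
    return bool((d2[far_apart] < min_sep**2).any())


def _stamp_crop(
    shape: tuple[int, int],
    discs: list[tuple[np.ndarray, float]],
    pad: int,
) -> tuple[np.ndarray, tuple[int, int]]:
    """Boolean union of hard-edged discs, as a padded bounding-box crop.

    ``discs`` is a list of (points, radius) pairs; returns the crop and its
    (row, col) offset within the full field.  Working on crops keeps
    placement cost proportional to grain size, not field size.
    """
    rmin = min(int(np.floor(p[:, 0].min() - r)) for p, r in discs) - pad - 1
    rmax = max(int(np.ceil(p[:, 0].max() + r)) for p, r in discs) + pad + 2
    cmin = min(int(np.floor(p[:, 1].min() - r)) for p, r in discs) - pad - 1
    cmax = max(int(np.ceil(p[:, 1].max() + r)) for p, r in discs) + pad + 2
    rmin, cmin = max(rmin, 0), max(cmin, 0)
    rmax, cmax = min(rmax, shape[0]), min(cmax, shape[1])
    rr, cc = np.mgrid[rmin:rmax, cmin:cmax]
    crop = np.zeros(rr.shape, dtype=bool)
    for points, radius in discs:
        for p in points:
            crop |= (rr - p[0]) ** 2 + (cc - p[1]) ** 2 <= radius**2
    return crop, (rmin, cmin)


def generate_field(spec: SceneSpec, image_id: str | None = None) -> tuple[RgbImage, GroundTruth]:
    """Render one field of view and its exact ground truth.

    Grains are placed by rejection sampling against an occupancy mask that
    keeps ``min_gap`` blank pixels between components (unless
    ``overlap_allowed``); grains whose tube would leave the field are
    re-drawn.  Raises :class:`PlacementError` when a grain cannot be placed
    after 200 attempts.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.field_size
    if image_id is None:
        image_id = f"synthetic_seed{spec.seed}"

    n = spec.n_grains if spec.n_grains is not None else int(rng.poisson(spec.mean_grains))

    occupancy = np.zeros((h, w), dtype=bool)
    blocked = np.zeros((h, w), dtype=bool)
    gap_footprint = morphology.disk(spec.min_gap) if spec.min_gap > 0 else None
    grains: list[GrainTruth] = []

    for _ in range(n):
        placed = False
        for _attempt in range(200):
            radius = rng.normal(spec.grain_radius_mean, spec.grain_radius_sd)
            if radius < spec.grain_radius_min:
                radius = spec.grain_radius_min
            has_tube = bool(rng.random() < spec.germinated_fraction)
            tube_len = 0.0
            pad = radius + spec.tube_width
            center = (rng.uniform(pad, h - pad), rng.uniform(pad, w - pad))

            discs = [(np.array([center]), radius)]
            if has_tube:
                factor = rng.uniform(*spec.tube_length_factor)
                tube_len = factor * 2.0 * radius
                heading = rng.uniform(0.0, 2.0 * math.pi)
                start = (
                    center[0] + radius * math.sin(heading),
                    center[1] + radius * math.cos(heading),
                )
                path = _tube_path(start, heading, tube_len, spec.tube_curvature, rng)
                half = spec.tube_width / 2.0
                if (
                    path[:, 0].min() < half + 1
                    or path[:, 0].max() > h - half - 2
                    or path[:, 1].min() < half + 1
                    or path[:, 1].max() > w - half - 2
                ):
                    continue  # tube would leave the field
                # a tube that curls back towards its own grain, or close
                # enough to itself that the stroke self-merges, breaks the
                # skeleton-length <-> arc-length correspondence; re-draw it
                dist = np.hypot(path[:, 0] - center[0], path[:, 1] - center[1])
                if dist.min() < radius - 0.5 or dist[8:].min() < radius + half + 2.5:
                    continue
                if _self_approaches(path, min_sep=spec.tube_width + 2.0):
                    continue
                discs.append((path, half))

            stamp, (roff, coff) = _stamp_crop((h, w), discs, pad=spec.min_gap)
            rs = slice(roff, roff + stamp.shape[0])
            cs = slice(coff, coff + stamp.shape[1])
            if not spec.overlap_allowed and (stamp & blocked[rs, cs]).any():
                continue
            occupancy[rs, cs] |= stamp
            if gap_footprint is not None:
                blocked[rs, cs] |= morphology.dilation(stamp, gap_footprint)
            else:
                blocked[rs, cs] |= stamp
            grains.append(
                GrainTruth(
                    center=center,
                    radius=float(radius),
                    has_tube=has_tube,
                    tube_length=float(tube_len),
                )
            )
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place grain {len(grains) + 1}/{n} after 200 attempts "
                f"(field {h}x{w}, overlap_allowed={spec.overlap_allowed})"
            )

    intensity = np.full((h, w), float(spec.background_level))
    intensity[occupancy] = float(spec.grain_level)

    if spec.illumination_gradient != 0.0:
        rr, cc = np.mgrid[0:h, 0:w]
        centre = ((h - 1) / 2.0, (w - 1) / 2.0)
        dist = np.hypot(rr - centre[0], cc - centre[1])
        intensity *= 1.0 - spec.illumination_gradient * dist / dist.max()

    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=(h, w))

    pixels = np.clip(np.rint(intensity), 0, 255).astype(np.uint8)
    image = RgbImage(np.repeat(pixels[:, :, None], 3, axis=2), image_id)
    return image, GroundTruth(image_id=image_id, grains=tuple(grains))


def generate_study(
    specs: Mapping[str, SceneSpec],
    n_fields: int,
    out_dir: str | Path,
) -> pd.DataFrame:
    """Write a study fixture: PNG fields plus ground-truth and condition maps.

    For each condition in ``specs``, renders ``n_fields`` views with seeds
    derived deterministically from the condition spec's seed.  Writes
    ``<condition>_f<i>.png`` images, ``ground_truth.csv`` (one row per
    image) and ``condition_map.csv`` (image -> sample -> condition; each
    image is its own sample).  Returns the ground-truth table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth_rows = []
    map_rows = []
    for condition, spec in specs.items():
        child_seeds = np.random.SeedSequence(spec.seed).generate_state(n_fields) % (2**31)
        for i in range(n_fields):
            img_id = f"{condition}_f{i}"
            image, truth = generate_field(spec.with_(seed=int(child_seeds[i])), image_id=img_id)
            image_io.write_image(image, out_dir / f"{img_id}.png")
            truth_rows.append(
                {
                    "image_id": img_id,
                    "condition": condition,
                    "n_grains": truth.n_grains,
                    "n_germinated": truth.n_germinated,
                    "percent_germination": truth.percent if truth.percent is not None else np.nan,
                }
            )
            map_rows.append({"image_id": img_id, "sample_id": img_id, "condition": condition})
    truth_df = pd.DataFrame(truth_rows)
    truth_df.to_csv(out_dir / "ground_truth.csv", index=False)
    pd.DataFrame(map_rows).to_csv(out_dir / "condition_map.csv", index=False)
    return truth_df
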