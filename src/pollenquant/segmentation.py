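"""Binary segmentation of pollen material from brightfield micrographs.

Pollen grains and tubes absorb more light than the surrounding germination
medium, so they appear dark on a bright background.  Segmentation is a fixed
intensity threshold on one colour channel (blue by default, threshold 150),
followed by hole filling and small-object removal to clean up specks and
internal reflections.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology

Channel = Literal["red", "green", "blue"]
Polarity = Literal["dark_objects", "bright_objects"]

_CHANNEL_INDEX = {"red": 0, "green": 1, "blue": 2}


@dataclass(frozen=True)
class RgbImage:
    """An 8-bit RGB micrograph with an identifier derived from its filename.

    ``pixels`` is an (H, W, 3) uint8 array in red/green/blue channel order,
    row 0 at the top of the image.
    """

    pixels: np.ndarray
    image_id: str

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"expected an (H, W, 3) pixel array, got shape {px.shape}")
        if px.dtype != np.uint8:
            raise ValueError(f"expected uint8 pixels, got {px.dtype}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass(frozen=True)
class BinaryMask:
    """A boolean foreground mask aligned with its source image."""

    pixels: np.ndarray
    source_image_id: str

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected an (H, W) boolean array, got shape {px.shape}")
        object.__setattr__(self, "pixels", px.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def area(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class SegmentationConfig:
    """Parameters of the fixed-threshold segmentation.

    Defaults follow the published counting workflow: threshold the blue
    channel at grey level 150 (objects darker than the background), fill
    enclosed holes, and drop connected components below 50 px.
    """

    channel: Channel = "blue"
    threshold: int = 150
    polarity: Polarity = "dark_objects"
    min_object_area: int = 50
    fill_holes: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 255:
            raise ValueError(f"threshold must be in [0, 255], got {self.threshold}")
        if self.min_object_area < 0:
            raise ValueError("min_object_area must be >= 0")
        if self.channel not in _CHANNEL_INDEX:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.polarity not in ("dark_objects", "bright_objects"):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    def with_(self, **kwargs) -> "SegmentationConfig":
        return replace(self, **kwargs)


def threshold_channel(image: RgbImage, config: SegmentationConfig | None = None) -> BinaryMask:
    """Threshold one colour channel into a foreground mask.

    With ``dark_objects`` polarity a pixel is foreground iff its channel
    intensity is strictly below the threshold; with ``bright_objects``,
    strictly above.  Pixels exactly at the threshold are background under
    both polarities.
    """
    config = config or SegmentationConfig()
    channel = image.pixels[:, :, _CHANNEL_INDEX[config.channel]]
    if config.polarity == "dark_objects":
        fg = channel < config.threshold
    else:
        fg = channel > config.threshold
    return BinaryMask(fg, image.image_id)


def fill_holes(mask: BinaryMask) -> BinaryMask:
    """Convert enclosed background regions to foreground.

    A hole is a 4-connected background region with no path to the image
    border; border-connected background is left untouched and foreground
    pixels are never removed.
    """
    filled = ndi.binary_fill_holes(mask.pixels)
    return BinaryMask(filled, mask.source_image_id)


def remove_small(mask: BinaryMask, min_object_area: int) -> BinaryMask:
    """Drop 8-connected foreground components with area < ``min_object_area``."""
    if min_object_area < 0:
        raise ValueError("min_object_area must be >= 0")
    if min_object_area <= 1:
        return BinaryMask(mask.pixels.copy(), mask.source_image_id)
    # remove area < min_object_area, i.e. area <= min_object_area - 1
    kept = morphology.remove_small_objects(
        mask.pixels, max_size=min_object_area - 1, connectivity=2
    )
    return BinaryMask(kept, mask.source_image_id)


def segment(image: RgbImage, config: SegmentationConfig | None = None) -> BinaryMask:
    """Full cleanup pipeline: threshold, optional hole filling, small-object removal."""
    config = config or SegmentationConfig()
    mask = threshold_channel(image, config)
    if config.fill_holes:
        mask = fill_holes(mask)
    return remove_small(mask, config.min_object_area)
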