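import numpy as np
import pytest
from skimage.draw import ellipse as _draw_ellipse

from pollenquant.segmentation import BinaryMask, RgbImage


def rasterize_ellipse(a: float, b: float, rotation: float = 0.0, pad: int = 8) -> BinaryMask:
    """Solid ellipse with semi-axes a >= b, as a binary mask."""
    size = int(2 * a) + 2 * pad
    img = np.zeros((size, size), dtype=bool)
    rr, cc = _draw_ellipse(size // 2, size // 2, a, b, rotation=rotation, shape=img.shape)
    img[rr, cc] = True
    return BinaryMask(img, "ellipse")


def image_from_mask(mask: BinaryMask, fg: int = 90, bg: int = 220) -> RgbImage:
    """Render a mask as a grey-on-bright RGB image (default segmentation recovers it)."""
    channel = np.where(mask.pixels, np.uint8(fg), np.uint8(bg))
    return RgbImage(np.repeat(channel[:, :, None], 3, axis=2), mask.source_image_id)


@pytest.fixture
def disc_mask() -> BinaryMask:
    """A solid disc of radius 20."""
    return rasterize_ellipse(20, 20)
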