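import numpy as np
import pytest

from radialpos import Image2D
from radialpos.segmentation import NucleusMask


def make_disk_mask(radius_px: int, pad: int = 4, spacing=(1.0, 1.0)) -> NucleusMask:
    """Solid disk mask: pixel centers within radius_px of the center."""
    n = 2 * radius_px + 2 * pad + 1
    c = n // 2
    yy, xx = np.mgrid[:n, :n]
    mask = (yy - c) ** 2 + (xx - c) ** 2 <= radius_px**2
    return NucleusMask(mask=mask, spacing=spacing)


def make_ellipse_mask(a_px: float, b_px: float, angle: float = 0.0,
                      pad: int = 4, spacing=(1.0, 1.0)) -> NucleusMask:
    """Solid ellipse mask with semi-axes (a, b) pixels rotated by angle."""
    ext = int(np.ceil(max(a_px, b_px))) + pad
    n = 2 * ext + 1
    c = n // 2
    yy, xx = np.mgrid[:n, :n]
    x, y = xx - c, yy - c
    xe = x * np.cos(angle) + y * np.sin(angle)
    ye = -x * np.sin(angle) + y * np.cos(angle)
    mask = (xe / a_px) ** 2 + (ye / b_px) ** 2 <= 1.0
    return NucleusMask(mask=mask, spacing=spacing)


def mask_to_image(mask: NucleusMask, level: float = 100.0) -> Image2D:
    """Render a mask as a flat-intensity image."""
    return Image2D(pixels=mask.mask.astype(float) * level,
                   pixel_size=mask.spacing[0])


@pytest.fixture
def disk50() -> NucleusMask:
    return make_disk_mask(50)
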