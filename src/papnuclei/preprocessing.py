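"""RGB-to-working-representation conversions.

Two representations feed the rest of the pipeline: a hue-gated binary
mask of the cytoplasmic cell clusters (background, blood and most
artifacts fall outside the cytoplasmic hue band) and an 8-bit grayscale
image.  Raster convention: 0-based (row, column), origin top-left.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.color import rgb2hsv
from skimage.morphology import closing, disk

__all__ = ["ClusterMask", "hue_gate", "to_grayscale", "downscale"]

#: BT.601 luma weights; fixed so grayscale output is bit-reproducible
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class ClusterMask:
    """Binary cell-cluster support with the hue limits that produced it."""

    pixels: np.ndarray
    hue_lo: float
    hue_hi: float


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB array")
    if image.shape[0] < 3 or image.shape[1] < 3:
        raise ValueError("image must be at least 3x3")
    return image


def hue_gate(
    image: np.ndarray,
    hue_lo: float = 0.2,
    hue_hi: float = 0.7,
    closing_radius: int = 5,
    fill_holes: bool = True,
) -> ClusterMask:
    """Mask of pixels whose HSV hue lies in the closed band [hue_lo, hue_hi].

    The hue band 0.2-0.7 captures cytoplasmic cell clusters while
    excluding the light background and most reddish blood/artifact
    pixels.  Morphological closing (disk of ``closing_radius``) and hole
    filling turn the raw gate into solid cluster blobs, so dark nuclei
    inside a cluster stay part of its support.  Gating uses the hue
    channel only; saturation and value are ignored.

    An all-false result is legal (no cells found) and only warns.
    """
    image = _check_rgb(image)
    if not (0.0 <= hue_lo < hue_hi <= 1.0):
        raise ValueError("require 0 <= hue_lo < hue_hi <= 1")
    hue = rgb2hsv(image)[..., 0]
    mask = (hue >= hue_lo) & (hue <= hue_hi)
    if closing_radius > 0:
        mask = closing(mask, disk(closing_radius))
    if fill_holes:
        mask = ndi.binary_fill_holes(mask)
    if not mask.any():
        warnings.warn("hue gate produced an empty mask (no cells found)",
                      stacklevel=2)
    return ClusterMask(pixels=mask, hue_lo=hue_lo, hue_hi=hue_hi)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """8-bit luma conversion, rounded half-up.

    Uses fixed weights 0.299/0.587/0.114 so the mapping is bit-exact and
    channel-identical inputs are fixed points.
    """
    image = _check_rgb(image)
    y = image.astype(np.float64) @ _LUMA
    return np.floor(y + 0.5).astype(np.uint8)


def downscale(image: np.ndarray, factor: float) -> np.ndarray:
    """Area-averaged down-sampling by ``factor`` in (0, 1].

    Output dimensions are ``round(dim * factor)``.  When ``1/factor`` is
    an integer that divides both dimensions, exact block averaging is
    used (so a 2560x1920 frame at factor 1/2 becomes 1280x960);
    otherwise an anti-aliased resize approximates the area average.
    """
    image = _check_rgb(image)
    if not (0.0 < factor <= 1.0):
        raise ValueError("factor must lie in (0, 1]")
    if factor == 1.0:
        return image.copy()
    h, w = image.shape[:2]
    out_h = int(round(h * factor))
    out_w = int(round(w * factor))
    if out_h < 2 or out_w < 2:
        raise ValueError("downscaled image would be smaller than 2x2")
    inv = 1.0 / factor
    block = int(round(inv))
    if abs(inv - block) < 1e-9 and h % block == 0 and w % block == 0:
        from skimage.transform import downscale_local_mean

        out = downscale_local_mean(image.astype(np.float64), (block, block, 1))
    else:
        from skimage.transform import resize

        out = resize(image.astype(np.float64), (out_h, out_w, 3),
                     anti_aliasing=True, preserve_range=True)
    return np.floor(out + 0.5).clip(0, 255).astype(np.uint8)
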