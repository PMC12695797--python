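"""Image preprocessing: denoising, grayscale conversion and RGB -> HSI.

The segmentation stage works in the HSI (hue / saturation / intensity) colour
space because hue isolates chromatic identity from brightness: a red apple
keeps roughly the same hue in morning sun and at dusk, while its RGB values
change dramatically.  Hue is computed with the circular (two-argument
arctangent) definition

    H = atan2(sqrt(3) * (G - B), 2R - G - B)   mapped to [0, 360)

which, unlike a single-quadrant arctan, distinguishes foliage green (~120 deg)
from sky blue (~240 deg).  Note that this circular hue differs from the
hexagonal HSV hue by up to ~1.12 deg between the primary/secondary axes; the
two agree exactly at multiples of 60 deg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "HsiImage",
    "denoise",
    "rgb_to_hsi",
    "to_gray",
    "hue_difference",
]

#: ITU-R BT.601 luminance weights used by :func:`to_gray`.
GRAY_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class HsiImage:
    """Per-pixel hue/saturation/intensity planes.

    ``h`` is in degrees in ``[0, 360)``; ``s`` and ``i`` are in ``[0, 1]``.
    Zero-chroma pixels (R = G = B) carry the sentinel hue 0 and saturation 0.
    """

    h: np.ndarray
    s: np.ndarray
    i: np.ndarray

    def __post_init__(self) -> None:
        if not (self.h.shape == self.s.shape == self.i.shape):
            raise ValueError("h, s and i planes must share a shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.h.shape


def _as_rgb(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB image, got shape {arr.shape}")
    return arr


def denoise(image: np.ndarray, gaussian_sigma: float = 1.0, median_kernel: int = 3) -> np.ndarray:
    """Gaussian smoothing followed by median filtering, per channel.

    Parameters
    ----------
    image:
        HxWx3 8-bit RGB image.
    gaussian_sigma:
        Standard deviation of the Gaussian kernel in pixels (0 disables it).
    median_kernel:
        Side of the square median window; must be odd (1 disables it).
    """
    arr = _as_rgb(image)
    if gaussian_sigma < 0:
        raise ValueError("gaussian_sigma must be >= 0")
    if median_kernel < 1 or median_kernel % 2 == 0:
        raise ValueError("median_kernel must be odd and >= 1")
    out = arr.astype(np.float64)
    if gaussian_sigma > 0:
        out = ndimage.gaussian_filter(out, sigma=(gaussian_sigma, gaussian_sigma, 0.0))
    if median_kernel > 1:
        out = ndimage.median_filter(out, size=(median_kernel, median_kernel, 1))
    out = np.clip(np.rint(out), 0, 255)
    return out.astype(arr.dtype if np.issubdtype(arr.dtype, np.integer) else np.uint8)


def rgb_to_hsi(image: np.ndarray) -> HsiImage:
    """Convert an 8-bit RGB image to HSI planes.

    Hue uses the circular atan2 definition (see module docstring); saturation
    is ``1 - min(R,G,B) / mean(R,G,B)`` and intensity ``mean(R,G,B) / 255``.
    """
    arr = _as_rgb(image).astype(np.float64)
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    num = np.sqrt(3.0) * (g - b)
    den = 2.0 * r - g - b
    h = np.degrees(np.arctan2(num, den)) % 360.0
    total = r + g + b
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(total > 0, 1.0 - 3.0 * np.minimum(np.minimum(r, g), b) / total, 0.0)
    s = np.clip(s, 0.0, 1.0)
    i = total / (3.0 * 255.0)
    # zero-chroma sentinel: atan2(0, 0) already yields 0, but enforce exactly
    achromatic = (r == g) & (g == b)
    h = np.where(achromatic, 0.0, h)
    return HsiImage(h=h, s=s, i=i)


def to_gray(image: np.ndarray) -> np.ndarray:
    """BT.601 luminance conversion, rounded to the nearest 8-bit level."""
    arr = _as_rgb(image).astype(np.float64)
    wr, wg, wb = GRAY_WEIGHTS
    gray = wr * arr[..., 0] + wg * arr[..., 1] + wb * arr[..., 2]
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def hue_difference(hue_deg, reference_deg):
    """Signed circular hue difference ``hue - reference`` in ``(-180, 180]``.

    Linearises hue around a reference so that e.g. red (which straddles the
    0/360 wrap) becomes a single cluster near 0.
    """
    return -(((reference_deg - hue_deg) + 180.0) % 360.0 - 180.0)
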