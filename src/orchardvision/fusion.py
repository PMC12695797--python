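"""Multi-feature apple recognition.

A segmented region is accepted as a fruit when the convex combination

    T = alpha1 * H + alpha2 * GLCM + alpha3 * Shape

of its colour, texture and morphology scores reaches a threshold.  Each
component lives in [0, 1]:

* ``H`` — closeness of the region's mean hue to the apple hue reference
  (circular distance, linear falloff over 60 deg by default);
* ``GLCM`` — a gray-level co-occurrence statistic (homogeneity by default)
  of the region's window: fruit surfaces are smooth and shaded, canopy is
  cluttered;
* ``Shape`` — circularity ``4*pi*area / perimeter**2``, 1 for a disc.

Accepted regions yield one :class:`Detection` with a hue-membership-weighted
centroid and a Kasa least-squares circle fit for the radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import morphology
from skimage.feature import graycomatrix, graycoprops

from .cluster import LabelMask, Region, regions_from_labels, split_instances
from .preprocess import HsiImage, hue_difference

__all__ = [
    "FusionWeights",
    "GlcmSpec",
    "Detection",
    "DegenerateCircleError",
    "glcm_score",
    "shape_score",
    "composite_score",
    "hue_membership",
    "weighted_centroid",
    "fit_circle",
    "fit_circle_region",
    "detect_apples",
]

GLCM_STATISTICS = ("energy", "contrast", "homogeneity")


class DegenerateCircleError(ValueError):
    """Raised when a circle fit is requested on (near-)collinear points."""


@dataclass(frozen=True)
class FusionWeights:
    """Colour / texture / morphology weights; normalized to sum to 1."""

    alpha_color: float = 0.5
    alpha_texture: float = 0.3
    alpha_shape: float = 0.2

    def __post_init__(self) -> None:
        a = np.array([self.alpha_color, self.alpha_texture, self.alpha_shape], dtype=float)
        if np.any(a < 0) or a.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
        a = a / a.sum()
        object.__setattr__(self, "alpha_color", float(a[0]))
        object.__setattr__(self, "alpha_texture", float(a[1]))
        object.__setattr__(self, "alpha_shape", float(a[2]))


@dataclass(frozen=True)
class GlcmSpec:
    """Gray-level co-occurrence configuration."""

    window: int = 21
    distance: int = 1
    angles: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    levels: int = 16
    statistic: str = "homogeneity"

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 1")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        if self.statistic not in GLCM_STATISTICS:
            raise ValueError(f"statistic must be one of {GLCM_STATISTICS}")


@dataclass
class Detection:
    """One recognized apple."""

    centroid: tuple[float, float]  # (row, col), sub-pixel
    radius: float
    score: float
    region_id: int
    position_3d: tuple[float, float, float] | None = None
    region: Region | None = field(default=None, repr=False, compare=False)


def glcm_score(gray_window: np.ndarray, spec: GlcmSpec = GlcmSpec()) -> float:
    """Texture statistic of a gray window, mapped to [0, 1].

    The window is quantized to ``spec.levels`` gray levels; the symmetric,
    normalized co-occurrence matrix is built at ``spec.distance`` for each
    angle and the chosen statistic is averaged over angles.  Contrast is
    normalized by its maximum attainable value ``(levels - 1)**2``; energy
    and homogeneity already lie in [0, 1].
    """
    win = np.asarray(gray_window)
    if win.ndim != 2:
        raise ValueError("gray_window must be 2-D")
    if min(win.shape) <= spec.distance:
        raise ValueError("window smaller than the co-occurrence distance")
    q = (win.astype(np.int64) * spec.levels) // 256
    q = np.clip(q, 0, spec.levels - 1).astype(np.uint8)
    glcm = graycomatrix(
        q,
        distances=[spec.distance],
        angles=list(np.deg2rad(spec.angles)),
        levels=spec.levels,
        symmetric=True,
        normed=True,
    )
    value = float(graycoprops(glcm, spec.statistic).mean())
    if spec.statistic == "contrast":
        value = value / float((spec.levels - 1) ** 2)
    return float(np.clip(value, 0.0, 1.0))


def shape_score(region: Region) -> float:
    """Circularity ``4*pi*area / perimeter**2`` clamped to [0, 1]."""
    if region.area <= 0 or region.perimeter <= 0:
        raise ValueError("region must have positive area and perimeter")
    return float(min(1.0, 4.0 * np.pi * region.area / region.perimeter**2))


def composite_score(h_score: float, glcm: float, shape: float, weights: FusionWeights) -> float:
    """Weighted fusion ``T = a1*H + a2*GLCM + a3*Shape`` in [0, 1]."""
    for name, v in (("h_score", h_score), ("glcm", glcm), ("shape", shape)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    return weights.alpha_color * h_score + weights.alpha_texture * glcm + weights.alpha_shape * shape


def hue_membership(hue_deg: np.ndarray, reference_deg: float, falloff_deg: float = 60.0):
    """Per-pixel colour score: 1 at the reference hue, 0 beyond ``falloff_deg``."""
    d = np.abs(hue_difference(hue_deg, reference_deg))
    return np.clip(1.0 - np.minimum(d, falloff_deg) / falloff_deg, 0.0, 1.0)


def weighted_centroid(region: Region, weight_plane: np.ndarray) -> tuple[float, float]:
    """Weight-averaged sub-pixel centroid of a region."""
    rs, cs = region.slices
    w = np.where(region.image, np.asarray(weight_plane, dtype=np.float64)[rs, cs], 0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight over the region must be > 0")
    rows, cols = np.nonzero(region.image)
    wsel = w[rows, cols]
    r = float(np.sum(wsel * rows) / total) + region.bbox[0]
    c = float(np.sum(wsel * cols) / total) + region.bbox[1]
    return (r, c)


def fit_circle(points: np.ndarray) -> tuple[tuple[float, float], float]:
    """Algebraic (Kasa) least-squares circle through ``points`` (N x 2, row/col).

    Solves ``2*r*a + 2*c*b + d = r^2 + c^2`` in the least-squares sense; the
    centre is (a, b) and the radius ``sqrt(d + a^2 + b^2)``.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise DegenerateCircleError("need at least 3 (row, col) points")
    a_mat = np.column_stack([2.0 * pts[:, 0], 2.0 * pts[:, 1], np.ones(len(pts))])
    b_vec = (pts**2).sum(axis=1)
    sol, _, rank, _ = np.linalg.lstsq(a_mat, b_vec, rcond=None)
    if rank < 3:
        raise DegenerateCircleError("collinear points admit no unique circle")
    r0, c0, d = sol
    r2 = d + r0**2 + c0**2
    if not np.isfinite(r2) or r2 <= 0:
        raise DegenerateCircleError("degenerate circle fit")
    return (float(r0), float(c0)), float(np.sqrt(r2))


def fit_circle_region(region: Region) -> tuple[tuple[float, float], float]:
    """Kasa circle fit to a region's boundary pixels (in full-image coords)."""
    padded = np.pad(region.image, 1)
    boundary = padded & ~morphology.erosion(padded, morphology.disk(1))
    rows, cols = np.nonzero(boundary)
    pts = np.column_stack([rows - 1 + region.bbox[0], cols - 1 + region.bbox[1]])
    return fit_circle(pts)


def _region_hue_score(region: Region, hsi: HsiImage, reference_deg: float, falloff_deg: float) -> float:
    rs, cs = region.slices
    d = hue_difference(hsi.h[rs, cs][region.image], reference_deg)
    mean_d = abs(float(np.mean(d)))
    return float(np.clip(1.0 - min(mean_d, falloff_deg) / falloff_deg, 0.0, 1.0))


def detect_apples(
    mask,
    hsi: HsiImage,
    gray: np.ndarray,
    weights: FusionWeights = FusionWeights(),
    spec: GlcmSpec = GlcmSpec(),
    threshold: float = 0.6,
    hue_reference: float = 0.0,
    min_area: float = 12.0,
    split_min_distance: int = 6,
    membership_falloff: float = 60.0,
) -> list[Detection]:
    """Score candidate regions and emit one :class:`Detection` per fruit.

    ``mask`` is a :class:`~orchardvision.cluster.LabelMask` (its foreground
    cluster is used) or a boolean foreground array.  Touching fruits are
    first separated by the distance-transform watershed; each surviving
    region is scored with the composite T and kept when ``T >= threshold``.
    An empty mask yields an empty list.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    fg = mask.foreground_mask() if isinstance(mask, LabelMask) else np.asarray(mask, dtype=bool)
    if not fg.any():
        return []
    labels = split_instances(fg, min_distance=split_min_distance, min_area=min_area)
    regions = regions_from_labels(labels, min_area=min_area)
    membership = hue_membership(hsi.h, hue_reference, membership_falloff)
    detections: list[Detection] = []
    for region in regions:
        h_score = _region_hue_score(region, hsi, hue_reference, membership_falloff)
        rs, cs = region.slices
        window = np.asarray(gray)[rs, cs]
        pad = max(0, spec.distance + 1 - min(window.shape))
        if pad:
            window = np.pad(window, pad, mode="edge")
        g_score = glcm_score(window, spec)
        s_score = shape_score(region)
        t = composite_score(h_score, g_score, s_score, weights)
        if t < threshold:
            continue
        try:
            centroid = weighted_centroid(region, membership)
        except ValueError:
            centroid = region.centroid
        try:
            _, radius = fit_circle_region(region)
        except DegenerateCircleError:
            radius = region.equivalent_radius
        req = region.equivalent_radius
        if not np.isfinite(radius) or not (0.3 * req <= radius <= 3.0 * req):
            radius = req
        detections.append(
            Detection(centroid=centroid, radius=float(radius), score=float(t), region_id=region.label, region=region)
        )
    return detections
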