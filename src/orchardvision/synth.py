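"""Synthetic stereo orchard scenes with exact ground truth.

Every downstream stage (segmentation, fusion scoring, disparity, depth,
metrics) is validated against scenes rendered here, emulating the conditions
of a red/green-apple orchard dataset: fruits as shaded, slightly elliptical
discs in the apple hue band over a textured green-foliage background,
overlap/occlusion up to a configurable fraction, day/night brightness, small
rotations, per-scene brightness jitter and additive Gaussian pixel noise.

Stereo pairs are generated pre-rectified: the right view re-renders each
apple shifted horizontally by its exact disparity ``d = f * B / Z``, so
``f * B / d`` recovers the assigned depth to machine precision.  Apples are
drawn far-to-near so nearer fruit occludes farther fruit consistently in
both views.  All randomness flows from one :class:`numpy.random.Generator`
(PCG64) seeded by ``SceneSpec.seed``: identical (spec, seed) pairs render
bit-identical scenes.

The generator emulates the *statistics* that stress a clustering pipeline
(hue proximity of green fruit to canopy, low night-time chroma, occlusion),
not photorealism: there is no leaf-level occluder geometry, no lens
distortion and no specular BRDF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq
from skimage.color import hsv2rgb

from .stereo import StereoRig

__all__ = [
    "SceneSpec",
    "AppleTruth",
    "SceneTruth",
    "PlacementError",
    "overlap_fraction",
    "render_scene",
    "APPLE_HUE",
    "FOLIAGE_HUE",
    "LIGHTING_SCALE",
]

#: Reference hue (degrees) of each fruit variety.
APPLE_HUE = {"red": 0.0, "green": 100.0}
#: Mean canopy hue (degrees).
FOLIAGE_HUE = 122.0
#: Global brightness multiplier per lighting condition.
LIGHTING_SCALE = {"day": 1.0, "noon": 1.1, "night": 0.45}


class PlacementError(RuntimeError):
    """Raised when apple placement cannot satisfy the overlap constraint."""


@dataclass(frozen=True)
class SceneSpec:
    """Declarative description of one synthetic stereo scene.

    ``n_apples`` may be an int or an inclusive ``(lo, hi)`` range sampled per
    scene.  ``max_overlap`` bounds the pairwise overlap fraction
    (lens area / smaller-disc area); ``cluster_fraction`` of the apples are
    deliberately placed overlapping an earlier apple so the generated overlap
    fractions span ``(0, max_overlap]``.  ``view_angle_deg`` foreshortens the
    fruit into ellipses (axis ratio ``cos(angle)``) to emulate oblique camera
    angles; ``rotation_jitter`` randomizes the ellipse orientation.
    """

    image_size: tuple[int, int] = (540, 960)
    n_apples: int | tuple[int, int] = (5, 15)
    apple_color: str = "red"
    radius_range: tuple[float, float] = (13.0, 30.0)
    depth_range: tuple[float, float] = (800.0, 1700.0)
    max_overlap: float = 0.4
    lighting: str = "day"
    brightness_jitter: float = 0.2
    rotation_jitter: float = 15.0
    noise_sigma: float = 4.0
    seed: int = 0
    view_angle_deg: float = 0.0
    axis_ratio_range: tuple[float, float] = (0.92, 1.0)
    cluster_fraction: float = 0.25
    rig: StereoRig | None = None

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 1 or w < 1:
            raise ValueError("image_size must be positive")
        if self.apple_color not in APPLE_HUE:
            raise ValueError(f"apple_color must be one of {sorted(APPLE_HUE)}")
        if self.lighting not in LIGHTING_SCALE:
            raise ValueError(f"lighting must be one of {sorted(LIGHTING_SCALE)}")
        for name, (lo, hi) in (("radius_range", self.radius_range), ("depth_range", self.depth_range)):
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive ordered interval")
        if not 0.0 <= self.max_overlap <= 1.0:
            raise ValueError("max_overlap must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if isinstance(self.n_apples, tuple) and self.n_apples[0] > self.n_apples[1]:
            raise ValueError("n_apples range must be ordered")

    def resolved_rig(self) -> StereoRig:
        return self.rig if self.rig is not None else StereoRig.centered(self.image_size)

    def with_seed(self, seed: int) -> "SceneSpec":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class AppleTruth:
    """Ground truth for one rendered apple (left-image coordinates)."""

    centroid: tuple[float, float]  # (row, col), sub-pixel
    radius: float  # equal-area disc radius, px
    depth_mm: float
    overlap_frac: float  # max pairwise overlap with any other apple


@dataclass(frozen=True)
class SceneTruth:
    """Ground truth for one scene."""

    apples: tuple[AppleTruth, ...]
    rig: StereoRig
    lighting: str
    image_size: tuple[int, int]
    apple_color: str = "red"

    def to_json(self) -> str:
        payload = {
            "image_size": list(self.image_size),
            "lighting": self.lighting,
            "apple_color": self.apple_color,
            "rig": self.rig.to_dict(),
            "apples": [
                {
                    "centroid": list(a.centroid),
                    "radius": a.radius,
                    "depth_mm": a.depth_mm,
                    "overlap": a.overlap_frac,
                }
                for a in self.apples
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SceneTruth":
        d = json.loads(text)
        return cls(
            apples=tuple(
                AppleTruth(
                    centroid=tuple(a["centroid"]),
                    radius=float(a["radius"]),
                    depth_mm=float(a["depth_mm"]),
                    overlap_frac=float(a["overlap"]),
                )
                for a in d["apples"]
            ),
            rig=StereoRig.from_dict(d["rig"]),
            lighting=d["lighting"],
            image_size=tuple(d["image_size"]),
            apple_color=d.get("apple_color", "red"),
        )


def overlap_fraction(center_a, radius_a: float, center_b, radius_b: float) -> float:
    """Disc-overlap fraction: lens area divided by the smaller disc's area."""
    if radius_a <= 0 or radius_b <= 0:
        raise ValueError("radii must be positive")
    d = float(np.hypot(center_a[0] - center_b[0], center_a[1] - center_b[1]))
    r1, r2 = float(radius_a), float(radius_b)
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return 1.0
    a1 = r1**2 * np.arccos((d**2 + r1**2 - r2**2) / (2 * d * r1))
    a2 = r2**2 * np.arccos((d**2 + r2**2 - r1**2) / (2 * d * r2))
    tri = 0.5 * np.sqrt(max(0.0, (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2)))
    lens = a1 + a2 - tri
    return float(min(1.0, lens / (np.pi * min(r1, r2) ** 2)))


def _distance_for_overlap(r1: float, r2: float, frac: float) -> float:
    """Centre distance giving a target overlap fraction (monotone bisection)."""
    lo, hi = abs(r1 - r2) + 1e-9, r1 + r2 - 1e-9
    f = lambda d: overlap_fraction((0, 0), r1, (0, d), r2) - frac
    if f(lo) < 0:  # even the closest admissible distance overlaps less
        return lo
    return float(brentq(f, lo, hi, xtol=1e-6))


@dataclass
class _Apple:
    center: tuple[float, float]
    radius: float
    depth: float
    a: float  # semi-major axis, px
    b: float  # semi-minor axis, px
    angle_deg: float
    disparity: float
    hue_jitter: float
    val_base: float
    light_dir: tuple[float, float]
    tex_seed: int
    overlap_frac: float = 0.0


def _place_apples(rng: np.random.Generator, spec: SceneSpec, rig: StereoRig) -> list[_Apple]:
    h, w = spec.image_size
    if isinstance(spec.n_apples, tuple):
        n = int(rng.integers(spec.n_apples[0], spec.n_apples[1] + 1))
    else:
        n = int(spec.n_apples)
    apples: list[_Apple] = []
    q_view = float(np.cos(np.deg2rad(spec.view_angle_deg)))
    for _ in range(n):
        for _attempt in range(400):
            radius = float(rng.uniform(*spec.radius_range))
            depth = float(rng.uniform(*spec.depth_range))
            q = q_view * float(rng.uniform(*spec.axis_ratio_range))
            a = radius / np.sqrt(q)
            b = radius * np.sqrt(q)
            angle = float(rng.uniform(-spec.rotation_jitter, spec.rotation_jitter))
            disp = float(rig.disparity_of(depth))
            margin = a + 2.0
            if apples and spec.max_overlap > 0.02 and rng.random() < spec.cluster_fraction:
                partner = apples[int(rng.integers(len(apples)))]
                target = float(rng.uniform(0.05, spec.max_overlap))
                dist = _distance_for_overlap(radius, partner.radius, target)
                theta = float(rng.uniform(0, 2 * np.pi))
                center = (
                    partner.center[0] + dist * np.sin(theta),
                    partner.center[1] + dist * np.cos(theta),
                )
            else:
                if margin >= h - margin or disp + margin >= w - margin:
                    continue
                center = (
                    float(rng.uniform(margin, h - margin)),
                    float(rng.uniform(disp + margin, w - margin)),
                )
            if not (margin <= center[0] <= h - margin and disp + margin <= center[1] <= w - margin):
                continue
            overlaps = [overlap_fraction(center, radius, o.center, o.radius) for o in apples]
            if any(f > spec.max_overlap + 1e-9 for f in overlaps):
                continue
            ld = rng.normal(size=2)
            ld = ld / max(float(np.hypot(*ld)), 1e-9)
            apples.append(
                _Apple(
                    center=center,
                    radius=radius,
                    depth=depth,
                    a=float(a),
                    b=float(b),
                    angle_deg=angle,
                    disparity=disp,
                    hue_jitter=float(rng.uniform(-4.0, 4.0)),
                    val_base=float(rng.uniform(0.68, 0.8)),
                    light_dir=(float(ld[0]), float(ld[1])),
                    tex_seed=int(rng.integers(0, 2**31 - 1)),
                    overlap_frac=0.0,
                )
            )
            break
        else:
            raise PlacementError(
                f"could not place apple {len(apples) + 1}/{n} under max_overlap={spec.max_overlap}"
            )
    # per-apple max pairwise overlap
    for i, ap in enumerate(apples):
        fr = 0.0
        for j, other in enumerate(apples):
            if i != j:
                fr = max(fr, overlap_fraction(ap.center, ap.radius, other.center, other.radius))
        ap.overlap_frac = fr
    # draw far first so nearer fruit occludes
    apples.sort(key=lambda ap: -ap.depth)
    return apples


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = f.std()
    return f / sd if sd > 0 else f


def _ellipse_coverage(h: int, w: int, center, a: float, b: float, angle_deg: float):
    """Anti-aliased ellipse coverage on its bounding window.

    Returns (row slice, col slice, coverage in [0,1], normalized radius rho).
    """
    cr, cc = center
    ext = max(a, b) + 2.0
    r0, r1 = max(0, int(np.floor(cr - ext))), min(h, int(np.ceil(cr + ext)) + 1)
    c0, c1 = max(0, int(np.floor(cc - ext))), min(w, int(np.ceil(cc + ext)) + 1)
    if r0 >= r1 or c0 >= c1:
        return slice(0, 0), slice(0, 0), np.zeros((0, 0)), np.zeros((0, 0))
    yy, xx = np.meshgrid(np.arange(r0, r1) - cr, np.arange(c0, c1) - cc, indexing="ij")
    th = np.deg2rad(angle_deg)
    u = xx * np.cos(th) + yy * np.sin(th)
    v = -xx * np.sin(th) + yy * np.cos(th)
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    sd = (1.0 - rho) * min(a, b)  # approximate signed distance to the edge
    cov = np.clip(sd + 0.5, 0.0, 1.0)
    return slice(r0, r1), slice(c0, c1), cov, rho


def _render_foliage(rng: np.random.Generator, h: int, w: int):
    hue = FOLIAGE_HUE + 3.0 * _smooth_field(rng, (h, w), 12.0)
    sat = np.clip(0.45 + 0.10 * _smooth_field(rng, (h, w), 18.0), 0.2, 0.75)
    val = np.clip(0.42 + 0.12 * _smooth_field(rng, (h, w), 10.0), 0.12, 0.85)
    n_leaves = max(20, (h * w) // 2500)
    for _ in range(n_leaves):
        center = (float(rng.uniform(0, h)), float(rng.uniform(0, w)))
        la = float(rng.uniform(6, 16))
        lb = float(rng.uniform(3, 8))
        ang = float(rng.uniform(0, 180))
        rs, cs, cov, _ = _ellipse_coverage(h, w, center, la, lb, ang)
        if cov.size == 0:
            continue
        dh = float(rng.uniform(-5, 5))
        dv = float(rng.uniform(-0.12, 0.18))
        ds = float(rng.uniform(-0.08, 0.08))
        hue[rs, cs] = hue[rs, cs] * (1 - cov) + (FOLIAGE_HUE + dh) * cov
        val[rs, cs] = np.clip(val[rs, cs] + dv * cov, 0.1, 0.9)
        sat[rs, cs] = np.clip(sat[rs, cs] + ds * cov, 0.15, 0.8)
    return hue, sat, val


def _draw_apple(hue, sat, val, ap: _Apple, base_hue: float, base_sat: float, col_shift: float) -> None:
    h, w = hue.shape
    center = (ap.center[0], ap.center[1] - col_shift)
    rs, cs, cov, rho = _ellipse_coverage(h, w, center, ap.a, ap.b, ap.angle_deg)
    if cov.size == 0:
        return
    yy, xx = np.meshgrid(
        np.arange(rs.start, rs.stop) - center[0],
        np.arange(cs.start, cs.stop) - center[1],
        indexing="ij",
    )
    ldr, ldc = ap.light_dir
    lin = (yy * ldr + xx * ldc) / max(ap.a, 1e-9)
    shading = np.clip(1.0 - 0.42 * rho**2 - 0.18 * lin, 0.25, 1.15)
    # deterministic surface speckle, sampled in apple-local coordinates so the
    # right view sees the same texture at its sub-pixel shifted position
    tex_rng = np.random.default_rng(ap.tex_seed)
    ext = int(np.ceil(max(ap.a, ap.b))) + 3
    patch = ndimage.gaussian_filter(tex_rng.standard_normal((2 * ext + 1, 2 * ext + 1)), 1.5)
    psd = patch.std()
    if psd > 0:
        patch /= psd
    tex = ndimage.map_coordinates(patch, [yy + ext, xx + ext], order=1, mode="nearest")
    value_apple = np.clip(ap.val_base * shading * (1.0 + 0.05 * tex), 0.05, 1.0)
    hue_apple = base_hue + ap.hue_jitter
    hue[rs, cs] = hue[rs, cs] * (1 - cov) + hue_apple * cov
    sat[rs, cs] = sat[rs, cs] * (1 - cov) + base_sat * cov
    val[rs, cs] = val[rs, cs] * (1 - cov) + value_apple * cov


def _compose(hue, sat, val, brightness: float, rng: np.random.Generator, noise_sigma: float) -> np.ndarray:
    hsv = np.stack([(hue % 360.0) / 360.0, np.clip(sat, 0, 1), np.clip(val * brightness, 0, 1)], axis=-1)
    rgb = hsv2rgb(hsv) * 255.0
    if noise_sigma > 0:
        rgb = rgb + rng.normal(0.0, noise_sigma, size=rgb.shape)
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray, SceneTruth]:
    """Render a rectified stereo pair and its ground truth.

    Returns ``(left, right, truth)`` where the images are HxWx3 uint8 RGB.
    The right image shifts every apple left by its disparity ``f*B/Z``;
    the foliage background is shared (disparity 0, i.e. far canopy).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    rig = spec.resolved_rig()
    apples = _place_apples(rng, spec, rig)
    hue, sat, val = _render_foliage(rng, h, w)
    hue_r, sat_r, val_r = hue.copy(), sat.copy(), val.copy()
    base_hue = APPLE_HUE[spec.apple_color]
    base_sat = 0.9 if spec.apple_color == "red" else 0.8
    for ap in apples:
        _draw_apple(hue, sat, val, ap, base_hue, base_sat, col_shift=0.0)
        _draw_apple(hue_r, sat_r, val_r, ap, base_hue, base_sat, col_shift=ap.disparity)
    brightness = LIGHTING_SCALE[spec.lighting] * (1.0 + spec.brightness_jitter * float(rng.uniform(-1, 1)))
    left = _compose(hue, sat, val, brightness, rng, spec.noise_sigma)
    right = _compose(hue_r, sat_r, val_r, brightness, rng, spec.noise_sigma)
    truth = SceneTruth(
        apples=tuple(
            AppleTruth(
                centroid=ap.center,
                radius=ap.radius,
                depth_mm=ap.depth,
                overlap_frac=ap.overlap_frac,
            )
            for ap in apples
        ),
        rig=rig,
        lighting=spec.lighting,
        image_size=(h, w),
        apple_color=spec.apple_color,
    )
    return left, right, truth
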