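"""End-to-end pipeline: preprocess -> cluster -> fusion -> (stereo) -> metrics.

Also hosts :class:`PipelineConfig` (YAML-loadable, unknown keys rejected) and
the batch experiment runners used for evaluation protocols: detection
batches, the CRR overlap sweep, the depth validation protocol and the
angle-stability study.  All evaluation protocols default to the package's
evaluation scale of 960x540 scenes with fruit radii 13-30 px, a half-scale
rendition of a 1920x1080 orchard camera; every reported metric (RA, CRR,
MCD%, relative depth error) is a scale-free ratio.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, fields, replace, asdict

import numpy as np
import pandas as pd
import yaml

from . import cluster as _cluster
from . import fusion as _fusion
from . import metrics as _metrics
from . import stereo as _stereo
from . import synth as _synth
from .preprocess import denoise, hue_difference, rgb_to_hsi, to_gray

__all__ = [
    "PreprocessParams",
    "ClusterParams",
    "FusionParams",
    "StereoParams",
    "MetricParams",
    "PipelineConfig",
    "SegmentationOutput",
    "PipelineResult",
    "segment_image",
    "detect_scene",
    "make_scene_spec",
    "run_detection_batch",
    "run_crr_sweep",
    "run_angle_stability",
    "BatchResult",
]

#: Reference frame for area-dependent defaults (a 1920x1080 orchard camera).
REFERENCE_AREA = 1920 * 1080


@dataclass(frozen=True)
class PreprocessParams:
    gaussian_sigma: float = 1.0
    median_kernel: int = 3


@dataclass(frozen=True)
class ClusterParams:
    k: int = 3
    tol: float = 1e-4
    max_iter: int = 100
    neighborhood_radius: int = 2
    density_epsilon: float = 1e-3
    min_separation: float = 20.0
    init_stride: int = 2  # subsampling stride for the density scoring pass
    selem_radius: int = 2
    min_area_ref: float = 50.0  # px^2 at 1920x1080; scaled by image area
    hue_gate: float = 10.0  # deg: centre must lie this close to the apple hue
    # saturation joins hue as a second clustering channel, scaled to
    # degree-equivalent units (fruit is far more saturated than canopy and
    # saturation is brightness-invariant, which stabilizes night scenes
    # where low chroma makes hue noisy); 0 restores hue-only clustering
    saturation_scale: float = 30.0

    def min_area(self, image_shape) -> float:
        h, w = image_shape[:2]
        return self.min_area_ref * (h * w) / REFERENCE_AREA


@dataclass(frozen=True)
class FusionParams:
    alpha_color: float = 0.5
    alpha_texture: float = 0.3
    alpha_shape: float = 0.2
    threshold: float = 0.6
    hue_reference: float = 0.0
    membership_falloff: float = 60.0
    glcm_window: int = 21
    glcm_distance: int = 1
    glcm_levels: int = 16
    glcm_statistic: str = "homogeneity"
    split_min_distance: int = 6
    min_radius: float = 8.0  # px: smallest plausible fruit radius at the working scale

    def weights(self) -> _fusion.FusionWeights:
        return _fusion.FusionWeights(self.alpha_color, self.alpha_texture, self.alpha_shape)

    def glcm_spec(self) -> _fusion.GlcmSpec:
        return _fusion.GlcmSpec(
            window=self.glcm_window,
            distance=self.glcm_distance,
            levels=self.glcm_levels,
            statistic=self.glcm_statistic,
        )


@dataclass(frozen=True)
class StereoParams:
    focal_length_px: float = 700.0
    baseline_mm: float = 60.0
    block: int = 11
    max_disparity: int = 64
    min_disparity: float = 16.0  # working-range prior (~2.6 m at f=700, B=60)
    texture_threshold: float = 1.0
    min_support_px: int = 12  # fewest clean disparity samples for a 3D fix

    def rig(self, image_shape) -> _stereo.StereoRig:
        return _stereo.StereoRig.centered(tuple(image_shape[:2]), self.focal_length_px, self.baseline_mm)


@dataclass(frozen=True)
class MetricParams:
    match_factor: float = 1.0
    iou_threshold: float = 0.5


_SECTIONS = {
    "preprocess": PreprocessParams,
    "cluster": ClusterParams,
    "fusion": FusionParams,
    "stereo": StereoParams,
    "metrics": MetricParams,
}


@dataclass(frozen=True)
class PipelineConfig:
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    fusion: FusionParams = field(default_factory=FusionParams)
    stereo: StereoParams = field(default_factory=StereoParams)
    metrics: MetricParams = field(default_factory=MetricParams)
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        kwargs = {}
        seed = data.pop("seed", 0)
        for name, section_cls in _SECTIONS.items():
            section = data.pop(name, {}) or {}
            known = {f.name for f in fields(section_cls)}
            unknown = set(section) - known
            if unknown:
                raise ValueError(f"unknown keys in config section '{name}': {sorted(unknown)}")
            kwargs[name] = section_cls(**section)
        if data:
            raise ValueError(f"unknown top-level config keys: {sorted(data)}")
        return cls(seed=int(seed), **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = {name: asdict(getattr(self, name)) for name in _SECTIONS}
        d["seed"] = self.seed
        return d

    def with_hue_reference(self, hue: float) -> "PipelineConfig":
        return replace(self, fusion=replace(self.fusion, hue_reference=float(hue)))

    def for_color(self, color: str) -> "PipelineConfig":
        return self.with_hue_reference(_synth.APPLE_HUE[color])


@dataclass
class SegmentationOutput:
    mask: np.ndarray  # cleaned boolean foreground
    label_mask: _cluster.LabelMask | None
    hsi: object
    gray: np.ndarray
    foreground_labels: tuple[int, ...]


@dataclass
class PipelineResult:
    detections: list[_fusion.Detection]
    segmentation: SegmentationOutput
    timings: dict


def segment_image(image: np.ndarray, cfg: PipelineConfig) -> SegmentationOutput:
    """Preprocess and segment one RGB frame into an apple foreground mask.

    Clustering runs on the hue plane re-centred on the configured apple hue
    reference (so the red 0/360 wrap is linear).  Foreground is the union of
    clusters whose centre lies within ``cluster.hue_gate`` degrees of the
    reference; if none qualifies the mask is empty (e.g. foliage-only frame).
    """
    den = denoise(image, cfg.preprocess.gaussian_sigma, cfg.preprocess.median_kernel)
    hsi = rgb_to_hsi(den)
    gray = to_gray(den)
    hue_plane = hue_difference(hsi.h, cfg.fusion.hue_reference)
    if cfg.cluster.saturation_scale > 0:
        feat = _cluster.FeatureSpace.from_planes(
            hue_plane, cfg.cluster.saturation_scale * hsi.s
        )
    else:
        feat = _cluster.FeatureSpace.from_planes(hue_plane)
    # density scoring on a strided subsample is ample for locating modes
    stride = max(1, cfg.cluster.init_stride)
    sub = _cluster.FeatureSpace(feat.values[::stride, ::stride], feat.weights)
    # guarantee one centre is seeded inside the target hue band (the P(i)
    # candidate restriction): the apple mode is a small population and plain
    # density peaks can all land in the canopy.  The seed is the per-channel
    # median of the gated pixels — when fruit is present those pixels are
    # dominated by fruit surface, so the median sits on the fruit mode and
    # is robust to the boundary/noise pixels that a single density peak can
    # land on
    gated = np.abs(sub.values[..., 0]) <= cfg.cluster.hue_gate
    seeds = None
    if gated.sum() >= 16:
        seeds = np.median(sub.values[gated], axis=0)[None, :]
    centers = None
    for k in range(cfg.cluster.k, 1, -1):
        try:
            centers = _cluster.select_initial_centers(
                sub,
                k,
                neighborhood_radius=cfg.cluster.neighborhood_radius,
                density_epsilon=cfg.cluster.density_epsilon,
                min_separation=cfg.cluster.min_separation,
                seeds=seeds,
            )
            break
        except _cluster.DegenerateImageError:
            continue  # fewer separable modes than k: retry smaller k
    if centers is None:
        empty = np.zeros(image.shape[:2], dtype=bool)
        return SegmentationOutput(mask=empty, label_mask=None, hsi=hsi, gray=gray, foreground_labels=())
    model = _cluster.ClusterModel(
        k=centers.shape[0],
        centers=centers,
        tol=cfg.cluster.tol,
        max_iter=cfg.cluster.max_iter,
        neighborhood_radius=cfg.cluster.neighborhood_radius,
        density_epsilon=cfg.cluster.density_epsilon,
        min_separation=cfg.cluster.min_separation,
    )
    label_mask = _cluster.kmeans_segment(feat, model)
    offsets = np.abs(label_mask.centers[:, 0])
    fg_labels = tuple(int(i) for i in np.flatnonzero(offsets <= cfg.cluster.hue_gate))
    if fg_labels:
        label_mask.foreground = int(min(fg_labels, key=lambda i: offsets[i]))
        raw = np.isin(label_mask.labels, fg_labels)
        mask = _cluster.morph_clean(raw, cfg.cluster.selem_radius, cfg.cluster.min_area(image.shape))
    else:
        mask = np.zeros(image.shape[:2], dtype=bool)
    return SegmentationOutput(mask=mask, label_mask=label_mask, hsi=hsi, gray=gray, foreground_labels=fg_labels)


def _deep_mode(sorted_disparities: np.ndarray, shallow_d: float, margin: float = 2.5) -> float | None:
    """Median of the coherent mode deeper than ``shallow_d`` by ``margin``.

    Requires the deep samples to be both numerous enough (>= 8 and >= 15%
    of all samples) and coherent (inter-quartile range below 2 px) to count
    as a real surface rather than mismatched fringe pixels.
    """
    d = sorted_disparities
    deep = d[d < shallow_d - margin]
    if deep.size < max(8, int(0.15 * d.size)):
        return None
    q1, q3 = np.percentile(deep, [25, 75])
    if q3 - q1 > 2.0:
        return None
    return float(np.median(deep))


def _localize_detections(
    detections: list[_fusion.Detection],
    seg: SegmentationOutput,
    right_gray: np.ndarray,
    cfg: PipelineConfig,
) -> None:
    """Attach 3D positions by block matching a strip around each detection.

    A fruit's disparity is the median of the valid (left-right consistent,
    in-band) per-pixel disparities over its *exclusive* surface: its
    instance region minus every other detection's fitted circle.  Watershed
    cells of occluded fruit overshoot into their (nearer) occluder, so
    pixels inside a neighbour's circle cannot be trusted as own surface.

    Two residual failure modes are reported as "no measurement"
    (``position_3d = None``) rather than a guess: fewer than
    ``stereo.min_support_px`` clean samples, and right-view occlusion —
    detected geometrically when two measured right-image footprints
    coincide, in which case the farther fruit is hidden in the right view
    and its measured disparity merely echoes the occluder's.
    """
    rig = cfg.stereo.rig(seg.gray.shape)
    h, w = seg.gray.shape
    pad = cfg.stereo.block + 4
    samples: dict[int, np.ndarray] = {}
    # exclusion map: pixels claimed by any detection's fitted circle
    claim = np.zeros((h, w), dtype=np.int16)
    guard = 2.0
    for det in detections:
        rr = det.radius + guard
        rows = slice(max(0, int(det.centroid[0] - rr)), min(h, int(det.centroid[0] + rr) + 1))
        cols = slice(max(0, int(det.centroid[1] - rr)), min(w, int(det.centroid[1] + rr) + 1))
        yy, xx = np.ogrid[rows, cols]
        disc = (yy - det.centroid[0]) ** 2 + (xx - det.centroid[1]) ** 2 <= rr**2
        claim[rows, cols] += disc
    measured: dict[int, float] = {}
    for idx, det in enumerate(detections):
        if det.region is None:
            continue
        r0, c0, r1, c1 = det.region.bbox
        rs0, rs1 = max(0, r0 - pad), min(h, r1 + pad)
        cs0, cs1 = max(0, c0 - cfg.stereo.max_disparity - pad), min(w, c1 + pad)
        left_strip = seg.gray[rs0:rs1, cs0:cs1].astype(np.float32)
        right_strip = right_gray[rs0:rs1, cs0:cs1].astype(np.float32)
        if min(left_strip.shape) <= cfg.stereo.block or cfg.stereo.max_disparity >= left_strip.shape[1]:
            continue
        dm = _stereo.block_match(
            left_strip,
            right_strip,
            block=cfg.stereo.block,
            max_disparity=cfg.stereo.max_disparity,
            texture_threshold=cfg.stereo.texture_threshold,
        )
        region_mask = np.zeros(left_strip.shape, dtype=bool)
        rr_idx, cc_idx = np.nonzero(det.region.image)
        region_mask[rr_idx + (r0 - rs0), cc_idx + (c0 - cs0)] = True
        # exclusive surface: inside own circle's claim only
        rows = slice(rs0, rs1)
        cols = slice(cs0, cs1)
        yy, xx = np.ogrid[rows, cols]
        own_disc = (yy - det.centroid[0]) ** 2 + (xx - det.centroid[1]) ** 2 <= (det.radius + guard) ** 2
        exclusive = region_mask & (claim[rows, cols] - own_disc.astype(np.int16) == 0)
        sel = exclusive & dm.valid
        d_sel = dm.disparity[sel]
        d_sel = d_sel[(d_sel >= cfg.stereo.min_disparity) & (d_sel <= cfg.stereo.max_disparity)]
        if d_sel.size < cfg.stereo.min_support_px:
            # fall back to the full region when the circle fit is off
            d_all = dm.disparity[region_mask & dm.valid]
            d_all = d_all[(d_all >= cfg.stereo.min_disparity) & (d_all <= cfg.stereo.max_disparity)]
            if d_all.size < cfg.stereo.min_support_px:
                continue
            d_sel = d_all
        samples[idx] = np.sort(d_sel)
        measured[idx] = float(np.median(d_sel))
    # Right-view occlusion: when a nearer fruit hides a farther one in the
    # right image, the farther fruit's pixels match the occluder's surface
    # and its measured disparity echoes the occluder's.  Signature: the two
    # fruits overlap in the left view yet report (nearly) the same
    # disparity, while the echo's samples keep a coherent deeper mode from
    # the partially visible true surface.  Re-estimate from that mode when
    # it exists; otherwise the depth is unmeasurable and stays unreported.
    items = sorted(measured.items())
    dropped: set[int] = set()
    resolved: set[int] = set()
    for a in range(len(items)):
        for b in range(a + 1, len(items)):
            ia, da = items[a]
            ib, db = items[b]
            det_a, det_b = detections[ia], detections[ib]
            gap_px = np.hypot(det_a.centroid[0] - det_b.centroid[0], det_a.centroid[1] - det_b.centroid[1])
            if gap_px >= det_a.radius + det_b.radius or abs(da - db) >= 2.5:
                continue
            deep_a = _deep_mode(samples[ia], min(da, db))
            deep_b = _deep_mode(samples[ib], min(da, db))

            def _hidden_behind(deep, det_self, det_other, d_other):
                # at its deep-mode depth, would this fruit sit under the
                # other's right-view footprint (i.e. truly hidden there)?
                dr = det_self.centroid[0] - det_other.centroid[0]
                dc = (det_self.centroid[1] - deep) - (det_other.centroid[1] - d_other)
                return bool(np.hypot(dr, dc) < 0.8 * det_other.radius)

            ok_a = deep_a is not None and _hidden_behind(deep_a, det_a, det_b, db)
            ok_b = deep_b is not None and _hidden_behind(deep_b, det_b, det_a, da)
            if ok_a and not ok_b:
                measured[ia] = deep_a
                resolved.add(ia)
            elif ok_b and not ok_a:
                measured[ib] = deep_b
                resolved.add(ib)
            elif ok_a and ok_b:
                dropped.add(ia if det_a.region.area <= det_b.region.area else ib)
            # otherwise: touching pair at similar depth, or third-fruit
            # contamination — leave both; the bimodality filter below
            # withholds any measurement that stays ambiguous
    for idx, disp in measured.items():
        if idx in dropped or disp <= 0:
            continue
        # a still-bimodal sample set marks an unresolved mixture (e.g. an
        # unsplit two-fruit cell): the depth is ambiguous, report none
        if idx not in resolved and _deep_mode(samples[idx], disp) is not None:
            continue
        det = detections[idx]
        z = _stereo.disparity_to_depth(disp, rig)
        p = _stereo.pixel_to_3d(det.centroid, z, rig)
        det.position_3d = (p.x, p.y, p.z)


def detect_scene(left: np.ndarray, right: np.ndarray | None, cfg: PipelineConfig) -> PipelineResult:
    """Run the full recognition pipeline on one frame or stereo pair."""
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    seg = segment_image(left, cfg)
    timings["segment_s"] = time.perf_counter() - t0
    t0 = time.perf_counter()
    detections = _fusion.detect_apples(
        seg.mask,
        seg.hsi,
        seg.gray,
        weights=cfg.fusion.weights(),
        spec=cfg.fusion.glcm_spec(),
        threshold=cfg.fusion.threshold,
        hue_reference=cfg.fusion.hue_reference,
        min_area=max(cfg.cluster.min_area(left.shape), np.pi * cfg.fusion.min_radius**2),
        split_min_distance=cfg.fusion.split_min_distance,
        membership_falloff=cfg.fusion.membership_falloff,
    )
    timings["fusion_s"] = time.perf_counter() - t0
    if right is not None:
        t0 = time.perf_counter()
        right_gray = to_gray(denoise(right, cfg.preprocess.gaussian_sigma, cfg.preprocess.median_kernel))
        _localize_detections(detections, seg, right_gray, cfg)
        timings["stereo_s"] = time.perf_counter() - t0
    total = sum(timings.values())
    timings["total_s"] = total
    timings["fps"] = 1.0 / total if total > 0 else float("inf")
    return PipelineResult(detections=detections, segmentation=seg, timings=timings)


# ---------------------------------------------------------------------------
# evaluation protocols
# ---------------------------------------------------------------------------


def make_scene_spec(
    seed: int,
    lighting: str = "day",
    color: str = "red",
    image_size=(540, 960),
    n_apples=(5, 15),
    radius_range=(13.0, 30.0),
    depth_range=(800.0, 1700.0),
    max_overlap: float = 0.4,
    brightness_jitter: float = 0.2,
    rotation_jitter: float = 15.0,
    noise_sigma: float = 4.0,
    view_angle_deg: float = 0.0,
) -> _synth.SceneSpec:
    """Scene specification at the package's standard evaluation scale."""
    return _synth.SceneSpec(
        image_size=tuple(image_size),
        n_apples=n_apples,
        apple_color=color,
        radius_range=tuple(radius_range),
        depth_range=tuple(depth_range),
        max_overlap=max_overlap,
        lighting=lighting,
        brightness_jitter=brightness_jitter,
        rotation_jitter=rotation_jitter,
        noise_sigma=noise_sigma,
        seed=int(seed),
        view_angle_deg=view_angle_deg,
    )


@dataclass
class BatchResult:
    """Aggregated outcome of a detection batch."""

    tp: int = 0
    fn: int = 0
    fp: int = 0
    deviations: list[tuple[str, float]] = field(default_factory=list)  # (lighting, px)
    rel_3d_errors: list[float] = field(default_factory=list)  # fraction, not %
    diagonal_px: float = 0.0
    per_scene: list[dict] = field(default_factory=list)

    def ra_pct(self) -> float:
        total = self.tp + self.fn
        return 100.0 * self.tp / total if total else float("nan")

    def mcd_pct(self, lighting: str | None = None) -> float:
        devs = [d for lt, d in self.deviations if lighting is None or lt == lighting]
        if not devs or self.diagonal_px <= 0:
            return float("nan")
        return 100.0 * float(np.mean(devs)) / self.diagonal_px

    def mean_rel_3d_err_pct(self) -> float:
        return 100.0 * float(np.mean(self.rel_3d_errors)) if self.rel_3d_errors else float("nan")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_scene)


def run_detection_batch(
    n_scenes: int,
    seed: int,
    cfg: PipelineConfig | None = None,
    stereo: bool = True,
    lightings=("day", "night"),
    colors=("red", "green"),
    **spec_overrides,
) -> BatchResult:
    """Render ``n_scenes`` scenes (alternating lighting/colour) and evaluate.

    Scene ``i`` uses seed ``seed + i``, lighting ``lightings[i % 2]`` and
    colour ``colors[(i // 2) % len(colors)]``; detection runs with the hue
    reference set to the scene's variety (the per-variety configuration a
    field deployment would use).
    """
    cfg = cfg or PipelineConfig()
    out = BatchResult()
    for i in range(n_scenes):
        lighting = lightings[i % len(lightings)]
        color = colors[(i // len(lightings)) % len(colors)]
        spec = make_scene_spec(seed=seed + i, lighting=lighting, color=color, **spec_overrides)
        left, right, truth = _synth.render_scene(spec)
        out.diagonal_px = float(np.hypot(*spec.image_size))
        scene_cfg = cfg.for_color(color)
        result = detect_scene(left, right if stereo else None, scene_cfg)
        m = _metrics.match_detections(result.detections, truth, scene_cfg.metrics.match_factor)
        out.tp += m.true_positives
        out.fn += m.false_negatives
        out.fp += m.false_positives
        for det_idx, truth_idx, dist in m.pairs:
            out.deviations.append((lighting, dist))
            det = result.detections[det_idx]
            apple = truth.apples[truth_idx]
            if stereo and det.position_3d is not None:
                rig = truth.rig
                p_true = _stereo.pixel_to_3d(apple.centroid, apple.depth_mm, rig).as_array()
                p_calc = np.asarray(det.position_3d, dtype=np.float64)
                norm = np.linalg.norm(p_true)
                if norm > 0:
                    out.rel_3d_errors.append(float(np.linalg.norm(p_calc - p_true) / norm))
        out.per_scene.append(
            {
                "scene": i,
                "lighting": lighting,
                "color": color,
                "n_truth": m.n_truth,
                "tp": m.true_positives,
                "fp": m.false_positives,
                "fn": m.false_negatives,
            }
        )
    return out


def run_crr_sweep(
    seed: int,
    overlap_bins=(0.1, 0.2, 0.3, 0.4, 0.5),
    scenes_per_bin: int = 40,
    cfg: PipelineConfig | None = None,
    **spec_overrides,
) -> dict[float, float]:
    """Segmentation CRR per fruit-overlap bin (preprocess -> cluster only)."""
    cfg = cfg or PipelineConfig()
    out: dict[float, float] = {}
    for b, max_overlap in enumerate(overlap_bins):
        recognized = 0
        total = 0
        for i in range(scenes_per_bin):
            lighting = ("day", "night")[i % 2]
            color = ("red", "green")[(i // 2) % 2]
            spec = make_scene_spec(
                seed=seed + b * scenes_per_bin + i,
                lighting=lighting,
                color=color,
                max_overlap=max_overlap,
                **spec_overrides,
            )
            left, _, truth = _synth.render_scene(spec)
            scene_cfg = cfg.for_color(color)
            seg = segment_image(left, scene_cfg)
            crr = _metrics.correct_recognition_rate(
                seg.mask,
                truth,
                iou_threshold=scene_cfg.metrics.iou_threshold,
                split_min_distance=scene_cfg.fusion.split_min_distance,
            )
            recognized += round(crr / 100.0 * len(truth.apples))
            total += len(truth.apples)
        out[float(max_overlap)] = 100.0 * recognized / total if total else float("nan")
    return out


def run_angle_stability(
    seed: int,
    angles=(0.0, 15.0, 30.0, 45.0),
    n_batches: int = 4,
    scenes_per_batch: int = 5,
    cfg: PipelineConfig | None = None,
    **spec_overrides,
) -> pd.DataFrame:
    """RA stability (sample std over replicate batches) per camera angle."""
    cfg = cfg or PipelineConfig()
    ra_by_angle: dict[float, list[float]] = {}
    for a, angle in enumerate(angles):
        ras = []
        for b in range(n_batches):
            batch_seed = seed + (a * n_batches + b) * scenes_per_batch
            batch = run_detection_batch(
                scenes_per_batch,
                batch_seed,
                cfg=cfg,
                stereo=False,
                view_angle_deg=angle,
                **spec_overrides,
            )
            ras.append(batch.ra_pct())
        ra_by_angle[float(angle)] = ras
    return _metrics.angle_stability(ra_by_angle)
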