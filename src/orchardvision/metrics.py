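"""Evaluation statistics for detection, segmentation and localization.

* **RA** (recognition accuracy): ``100 * TP / (TP + FN)`` — the fraction of
  ground-truth fruits recovered.
* **MCD** (mean coordinate deviation): mean centroid displacement of matched
  pairs, expressed as a percentage of the image diagonal so it is resolution
  independent.
* **CRR** (correct recognition rate): fraction of ground-truth fruits whose
  segmented instance reaches IoU >= a threshold against the true fruit disc.
* **Precision / recall / F1 / AP**: standard single-class detection metrics;
  AP uses the all-point interpolated precision-recall curve over the
  detection-score sweep.
* **Angle stability**: sample standard deviation of RA over replicate scene
  batches at each simulated camera angle.

A detection matches a ground-truth fruit when its centroid lies within
``max_dist_factor`` times the fruit's radius; assignment is greedy by
ascending distance (ties break toward the lower detection index) and each
truth fruit is matched at most once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import split_instances
from .fusion import Detection
from .synth import SceneTruth

__all__ = [
    "MatchResult",
    "EvalReport",
    "match_detections",
    "recognition_accuracy",
    "mean_coordinate_deviation",
    "correct_recognition_rate",
    "precision_recall_f1_map",
    "angle_stability",
]


@dataclass
class MatchResult:
    """Greedy centroid matching between detections and ground truth."""

    true_positives: int
    false_positives: int
    false_negatives: int
    pairs: list[tuple[int, int, float]] = field(default_factory=list)  # (det_idx, truth_idx, dist)
    n_detections: int = 0
    n_truth: int = 0

    def detection_is_tp(self) -> np.ndarray:
        flags = np.zeros(self.n_detections, dtype=bool)
        for det_idx, _, _ in self.pairs:
            flags[det_idx] = True
        return flags

    @property
    def deviations_px(self) -> np.ndarray:
        return np.array([d for _, _, d in self.pairs], dtype=np.float64)


def match_detections(detections: list[Detection], truth: SceneTruth, max_dist_factor: float = 1.0) -> MatchResult:
    """Greedy nearest-first assignment under the centroid-radius criterion."""
    if max_dist_factor <= 0:
        raise ValueError("max_dist_factor must be > 0")
    n_det, n_truth = len(detections), len(truth.apples)
    candidates = []
    for i, det in enumerate(detections):
        for j, apple in enumerate(truth.apples):
            dist = float(np.hypot(det.centroid[0] - apple.centroid[0], det.centroid[1] - apple.centroid[1]))
            if dist <= max_dist_factor * apple.radius:
                candidates.append((dist, i, j))
    candidates.sort()
    used_det: set[int] = set()
    used_truth: set[int] = set()
    pairs = []
    for dist, i, j in candidates:
        if i in used_det or j in used_truth:
            continue
        used_det.add(i)
        used_truth.add(j)
        pairs.append((i, j, dist))
    tp = len(pairs)
    return MatchResult(
        true_positives=tp,
        false_positives=n_det - tp,
        false_negatives=n_truth - tp,
        pairs=pairs,
        n_detections=n_det,
        n_truth=n_truth,
    )


def recognition_accuracy(m: MatchResult) -> float:
    """RA = 100 * TP / (TP + FN), in percent."""
    total = m.true_positives + m.false_negatives
    if total == 0:
        raise ValueError("RA undefined with no ground-truth fruits")
    return 100.0 * m.true_positives / total


def mean_coordinate_deviation(m: MatchResult, image_diagonal_px: float) -> float:
    """MCD = 100 * mean(centroid deviation) / image diagonal, in percent."""
    if image_diagonal_px <= 0:
        raise ValueError("image diagonal must be > 0")
    if not m.pairs:
        raise ValueError("MCD undefined with no matched pairs")
    return float(100.0 * m.deviations_px.mean() / image_diagonal_px)


def _disc_mask(shape: tuple[int, int], centroid, radius: float) -> tuple[slice, slice, np.ndarray]:
    h, w = shape
    r0 = max(0, int(np.floor(centroid[0] - radius)) - 1)
    r1 = min(h, int(np.ceil(centroid[0] + radius)) + 2)
    c0 = max(0, int(np.floor(centroid[1] - radius)) - 1)
    c1 = min(w, int(np.ceil(centroid[1] + radius)) + 2)
    yy, xx = np.meshgrid(np.arange(r0, r1) - centroid[0], np.arange(c0, c1) - centroid[1], indexing="ij")
    return slice(r0, r1), slice(c0, c1), (yy**2 + xx**2) <= radius**2


def correct_recognition_rate(
    segmentation: np.ndarray,
    truth: SceneTruth,
    iou_threshold: float = 0.5,
    split_min_distance: int = 6,
) -> float:
    """CRR: percent of truth fruits whose best instance IoU >= threshold.

    ``segmentation`` is the binary foreground mask (or an integer instance
    label image).  A binary mask is first separated into instances with the
    distance-transform watershed, since per-fruit IoU is only meaningful on
    instance masks.  IoU at exactly the threshold counts as recognized.
    """
    if not truth.apples:
        raise ValueError("CRR undefined with no ground-truth fruits")
    seg = np.asarray(segmentation)
    if seg.dtype == bool:
        labels = split_instances(seg, min_distance=split_min_distance)
    else:
        labels = seg.astype(np.int64)
    areas = np.bincount(labels.ravel())
    recognized = 0
    for apple in truth.apples:
        rs, cs, disc = _disc_mask(labels.shape, apple.centroid, apple.radius)
        disc_area = float(disc.sum())
        if disc_area == 0:
            continue
        window = labels[rs, cs]
        best = 0.0
        for lab in np.unique(window[disc]):
            if lab == 0:
                continue
            inter = float(np.count_nonzero((window == lab) & disc))
            union = disc_area + float(areas[lab]) - inter
            if union > 0:
                best = max(best, inter / union)
        if best >= iou_threshold:
            recognized += 1
    return 100.0 * recognized / len(truth.apples)


def precision_recall_f1_map(m: MatchResult, scores) -> tuple[float, float, float, float]:
    """Precision, recall, F1 and all-point-interpolated AP (single class).

    ``scores`` are the detection confidences aligned with the detection
    indices of ``m``; the PR curve sweeps the score threshold with the
    TP/FP identity of each detection fixed by the matching.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.shape[0] != m.n_detections:
        raise ValueError("scores must align with the matched detections")
    tp, fp, fn = m.true_positives, m.false_positives, m.false_negatives
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    if m.n_truth == 0:
        return precision, recall, f1, 0.0
    if m.n_detections == 0:
        return precision, recall, f1, 0.0
    order = np.argsort(-scores, kind="stable")
    is_tp = m.detection_is_tp()[order]
    cum_tp = np.cumsum(is_tp)
    cum_fp = np.cumsum(~is_tp)
    rec = cum_tp / m.n_truth
    prec = cum_tp / (cum_tp + cum_fp)
    # precision envelope (monotone non-increasing from the right)
    prec_env = np.maximum.accumulate(prec[::-1])[::-1]
    rec_prev = np.concatenate([[0.0], rec[:-1]])
    ap = float(np.sum((rec - rec_prev) * prec_env))
    return float(precision), float(recall), float(f1), ap


def angle_stability(ra_by_angle: dict) -> pd.DataFrame:
    """Sample std of RA across replicate batches per camera angle.

    ``ra_by_angle`` maps an angle (deg) to a sequence of per-batch RA values.
    Single-replicate angles report std 0.
    """
    rows = []
    for angle, values in sorted(ra_by_angle.items()):
        vals = np.asarray(list(values), dtype=np.float64)
        std = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        rows.append({"angle_deg": float(angle), "n": int(vals.size), "mean_ra": float(vals.mean()), "std_ra": std})
    return pd.DataFrame(rows)


@dataclass
class EvalReport:
    """Aggregate evaluation over a batch of scenes."""

    ra_pct: float
    mcd_pct: float | None
    crr_pct: float | None
    precision: float
    recall: float
    f1: float
    map: float
    mean_depth_rel_err_pct: float | None = None
    per_scene: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "ra_pct": self.ra_pct,
            "mcd_pct": self.mcd_pct,
            "crr_pct": self.crr_pct,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "map": self.map,
            "mean_depth_rel_err_pct": self.mean_depth_rel_err_pct,
        }
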