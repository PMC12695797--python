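"""Small I/O helpers: images, scene directories, detection tables."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .fusion import Detection
from .synth import SceneTruth

__all__ = [
    "read_image",
    "write_image",
    "write_scene",
    "read_scene",
    "detections_frame",
    "write_detections",
    "read_detections",
    "write_label_mask",
    "write_depth_map",
    "regions_frame",
]


def read_image(path) -> np.ndarray:
    """Read an image file as HxWx3 uint8 RGB."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return arr


def write_image(path, image: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(image))


def write_scene(directory, left, right, truth: SceneTruth) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_image(d / "left.png", left)
    write_image(d / "right.png", right)
    (d / "truth.json").write_text(truth.to_json(), encoding="utf-8")


def read_scene(directory):
    d = Path(directory)
    left = read_image(d / "left.png")
    right_path = d / "right.png"
    right = read_image(right_path) if right_path.exists() else None
    truth_path = d / "truth.json"
    truth = SceneTruth.from_json(truth_path.read_text(encoding="utf-8")) if truth_path.exists() else None
    return left, right, truth


def detections_frame(detections: list[Detection]) -> pd.DataFrame:
    rows = []
    for i, det in enumerate(detections):
        p = det.position_3d or (None, None, None)
        rows.append(
            {
                "id": i,
                "row": round(det.centroid[0], 3),
                "col": round(det.centroid[1], 3),
                "radius": round(det.radius, 3),
                "score": round(det.score, 4),
                "X_mm": None if p[0] is None else round(p[0], 2),
                "Y_mm": None if p[1] is None else round(p[1], 2),
                "Z_mm": None if p[2] is None else round(p[2], 2),
            }
        )
    return pd.DataFrame(
        rows, columns=["id", "row", "col", "radius", "score", "X_mm", "Y_mm", "Z_mm"]
    )


def write_detections(path, detections: list[Detection]) -> None:
    """Write detections as CSV or JSON depending on the suffix."""
    path = Path(path)
    frame = detections_frame(detections)
    if path.suffix == ".json":
        path.write_text(json.dumps(frame.to_dict(orient="records"), indent=2), encoding="utf-8")
    else:
        frame.to_csv(path, index=False)


def write_label_mask(path, labels: np.ndarray) -> None:
    """Write an integer/boolean label mask as an 8-bit PNG."""
    arr = np.asarray(labels)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    else:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    iio.imwrite(path, arr)


def write_depth_map(path, depth: np.ndarray) -> None:
    """Write a depth or disparity map as a 32-bit float TIFF."""
    iio.imwrite(path, np.asarray(depth, dtype=np.float32), extension=".tiff")


def regions_frame(regions) -> pd.DataFrame:
    """One row per connected region: label, area, perimeter, centroid, bbox."""
    return pd.DataFrame(
        [
            {
                "label": r.label,
                "area": r.area,
                "perimeter": round(r.perimeter, 3),
                "centroid_row": round(r.centroid[0], 3),
                "centroid_col": round(r.centroid[1], 3),
                "bbox_min_row": r.bbox[0],
                "bbox_min_col": r.bbox[1],
                "bbox_max_row": r.bbox[2],
                "bbox_max_col": r.bbox[3],
            }
            for r in regions
        ]
    )


def read_detections(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".json":
        return pd.DataFrame(json.loads(path.read_text(encoding="utf-8")))
    return pd.read_csv(path)
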