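"""Blob/pixel/image-level evaluation of the detection pipeline.

Counting follows the operational reading of the task: on images *with*
contaminants we count true positives (a ground-truth contaminant blob is
"detected" when at least one predicted contaminant pixel of any contaminant
class overlaps it -- the goal is flagging, not per-class identification);
on *clean* images every predicted contaminant pixel is a false positive, and
an image with at least one such pixel counts as a false-positive image.
Segmentation quality is reported as mIoU over the classes present in the
ground truth.  Blobs are 8-connected components.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .cube_io import Hypercube
from .postproc import PredictionMap, run_postprocessing
from .taxonomy import UNANNOTATED, ClassTaxonomy, default_taxonomy

_CONN8 = np.ones((3, 3), dtype=bool)

#: The four evaluation arms, as post-processing pipelines.
ARMS: dict[str, tuple[str, ...]] = {
    "raw": (),
    "erosion": ("erosion",),
    "rules": ("rules",),
    "rules+erosion": ("rules", "erosion"),
}


def count_blobs(labels: np.ndarray, classes, taxonomy: ClassTaxonomy | None = None) -> dict[str, int]:
    """Number of 8-connected components per selected class."""
    taxonomy = taxonomy or default_taxonomy()
    out = {}
    for cls in classes:
        idx = taxonomy.index_of(cls) if isinstance(cls, str) else int(cls)
        _, n = ndimage.label(labels == idx, structure=_CONN8)
        out[taxonomy.name_of(idx)] = int(n)
    return out


def confusion_and_miou(
    pred: np.ndarray, truth: np.ndarray, n_classes: int = 13
) -> tuple[np.ndarray, float]:
    """Confusion matrix (rows = truth, cols = prediction) and mIoU.

    Pixels labelled 255 in the ground truth are excluded.  IoU_c =
    TP_c / (TP_c + FP_c + FN_c); the mean runs over classes present in the
    ground truth.
    """
    pred = np.asarray(pred).reshape(-1).astype(np.int64)
    truth = np.asarray(truth).reshape(-1).astype(np.int64)
    if pred.shape != truth.shape:
        raise ValueError("prediction and ground truth must have the same shape")
    valid = truth != UNANNOTATED
    if not valid.any():
        raise ValueError("no labelled pixels to evaluate")
    pred, truth = pred[valid], truth[valid]
    cm = np.bincount(truth * n_classes + pred, minlength=n_classes * n_classes).reshape(
        n_classes, n_classes
    )
    tp = np.diag(cm).astype(np.float64)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    present = cm.sum(axis=1) > 0
    denom = tp + fp + fn
    iou = np.divide(tp, denom, out=np.zeros_like(tp), where=denom > 0)
    return cm, float(iou[present].mean())


def contaminant_mask(labels: np.ndarray, taxonomy: ClassTaxonomy) -> np.ndarray:
    lut = np.zeros(256, dtype=bool)
    for idx in taxonomy.contaminant_indices:
        lut[idx] = True
    return lut[labels]


@dataclass
class ImageResult:
    arm: str
    image_id: str
    clean: bool
    tp_blobs: int
    gt_blobs: int
    tp_pixels: int
    fp_image: bool
    fp_blobs: int
    fp_pixels: int
    miou: float


@dataclass
class EvalSummary:
    """Aggregated counts per arm, plus per-image rows."""

    per_arm: dict[str, dict] = field(default_factory=dict)
    rows: list[ImageResult] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])


def _gt_blob_stats(
    final: np.ndarray, mask: np.ndarray, taxonomy: ClassTaxonomy
) -> tuple[int, int, int]:
    """(detected blobs, total GT blobs, TP pixel count) on one image."""
    pred_pos = contaminant_mask(final, taxonomy)
    gt_pos = contaminant_mask(mask, taxonomy)
    blob_ids, n_blobs = ndimage.label(gt_pos, structure=_CONN8)
    detected = 0
    for blob in range(1, n_blobs + 1):
        if np.any(pred_pos & (blob_ids == blob)):
            detected += 1
    tp_pixels = int(np.sum(pred_pos & gt_pos))
    return detected, n_blobs, tp_pixels


def evaluate_predictions(
    samples,
    arms: dict[str, tuple[str, ...]] | None = None,
    taxonomy: ClassTaxonomy | None = None,
) -> EvalSummary:
    """Score raw predictions under several post-processing arms.

    ``samples`` yields ``(image_id, raw_pred: PredictionMap, cube, mask)``;
    the raw model prediction is computed once per image and each arm only
    re-runs its post-processing stages.  Clean images (no contaminant pixel
    in the mask) feed the false-positive counts; contaminated images feed
    the true-positive counts.
    """
    arms = arms if arms is not None else dict(ARMS)
    taxonomy = taxonomy or default_taxonomy()
    summary = EvalSummary()
    fp_class_pixels: dict[str, np.ndarray] = {a: np.zeros(taxonomy.n_classes, dtype=np.int64) for a in arms}
    for image_id, raw_pred, cube, mask in samples:
        clean = not contaminant_mask(mask, taxonomy).any()
        for arm, pipeline in arms.items():
            final = run_postprocessing(raw_pred, cube, pipeline=pipeline, taxonomy=taxonomy).labels
            _, miou = confusion_and_miou(final, mask, n_classes=taxonomy.n_classes)
            if clean:
                fp_pos = contaminant_mask(final, taxonomy)
                _, fp_blobs = ndimage.label(fp_pos, structure=_CONN8)
                fp_pixels = int(fp_pos.sum())
                fp_class_pixels[arm] += np.bincount(
                    final[fp_pos].reshape(-1), minlength=taxonomy.n_classes
                )
                row = ImageResult(arm, image_id, True, 0, 0, 0, fp_pixels > 0, int(fp_blobs), fp_pixels, miou)
            else:
                detected, n_blobs, tp_pixels = _gt_blob_stats(final, mask, taxonomy)
                row = ImageResult(arm, image_id, False, detected, n_blobs, tp_pixels, False, 0, 0, miou)
            summary.rows.append(row)
    for arm in arms:
        rows = [r for r in summary.rows if r.arm == arm]
        clean_rows = [r for r in rows if r.clean]
        dirty_rows = [r for r in rows if not r.clean]
        dist = fp_class_pixels[arm]
        summary.per_arm[arm] = {
            "n_clean_images": len(clean_rows),
            "n_contaminated_images": len(dirty_rows),
            "fp_images": sum(r.fp_image for r in clean_rows),
            "fp_blobs": sum(r.fp_blobs for r in clean_rows),
            "fp_pixels": sum(r.fp_pixels for r in clean_rows),
            "fp_class_distribution": {
                taxonomy.name_of(i): int(dist[i]) for i in range(taxonomy.n_classes) if dist[i] > 0
            },
            "tp_blobs": sum(r.tp_blobs for r in dirty_rows),
            "gt_blobs": sum(r.gt_blobs for r in dirty_rows),
            "tp_pixels": sum(r.tp_pixels for r in dirty_rows),
            "mean_miou": float(np.mean([r.miou for r in rows])) if rows else float("nan"),
        }
    return summary


def predict_cube(params, cube: Hypercube, model_cfg, batch: int = 80) -> PredictionMap:
    """Raw model prediction for a whole cube via disjoint tiles.

    Tiles are batched through the network and stitched by logit averaging
    (overlaps only occur at clamped border tiles).
    """
    from .tiler import TileGrid, extract_tiles, stitch_predictions
    from .vitseg import forward

    tiles = extract_tiles(cube, grid=TileGrid())
    placed = []
    for start in range(0, len(tiles), batch):
        chunk = tiles[start : start + batch]
        data = np.stack([t.data for t in chunk])
        logits, _ = forward(params, data, model_cfg)
        placed.extend((t.origin, logits[j]) for j, t in enumerate(chunk))
    labels = stitch_predictions(placed, cube.shape[:2])
    return PredictionMap(labels=labels, stage="raw_model")


def throughput_report(params, cubes, model_cfg) -> float:
    """Log-only images/second figure; hardware-dependent, never a target."""
    start = time.perf_counter()
    n = 0
    for cube in cubes:
        predict_cube(params, cube, model_cfg)
        n += 1
    if n == 0:
        raise ValueError("need at least one cube")
    fps = n / (time.perf_counter() - start)
    import logging

    logging.getLogger(__name__).info("throughput: %.3f images/s over %d cube(s)", fps, n)
    return fps
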