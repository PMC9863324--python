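"""Overlap and boundary metrics between predicted and ground-truth masks.

Dice, IoU, precision and recall are computed from the TP/FP/FN pixel counts;
the Hausdorff distance is the true (100th-percentile) symmetric boundary
distance in millimetres, with each image axis scaled by its own pixel
spacing. Aggregates are per-image means +/- sample standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion
from scipy.spatial.distance import directed_hausdorff

__all__ = [
    "dice_coefficient",
    "iou",
    "precision_recall",
    "hausdorff_mm",
    "SegmentationMetrics",
    "evaluate_masks",
]

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def _counts(pred: np.ndarray, gt: np.ndarray) -> tuple[int, int, int]:
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    return tp, fp, fn


def dice_coefficient(pred: np.ndarray, gt: np.ndarray) -> float:
    """Dice overlap 2TP / (2TP + FP + FN); two empty masks agree (1.0)."""
    tp, fp, fn = _counts(pred, gt)
    denom = 2 * tp + fp + fn
    return 1.0 if denom == 0 else 2 * tp / denom


def iou(pred: np.ndarray, gt: np.ndarray) -> float:
    """Intersection over union TP / (TP + FP + FN); two empty masks give 1.0."""
    tp, fp, fn = _counts(pred, gt)
    denom = tp + fp + fn
    return 1.0 if denom == 0 else tp / denom


def precision_recall(pred: np.ndarray, gt: np.ndarray) -> tuple[float, float]:
    """Pixelwise (precision, recall).

    Empty-denominator convention: an empty prediction has precision 1.0 when
    the truth is also empty, else 0.0 (and symmetrically for recall).
    """
    tp, fp, fn = _counts(pred, gt)
    if tp + fp == 0:
        precision = 1.0 if fn == 0 else 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall = 1.0 if fp == 0 else 0.0
    else:
        recall = tp / (tp + fn)
    return precision, recall


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Coordinates (row, col) of mask pixels with at least one background 4-neighbour."""
    mask = np.asarray(mask).astype(bool)
    inner = binary_erosion(mask, structure=_CROSS, border_value=0)
    return np.argwhere(mask & ~inner)


def hausdorff_mm(
    pred: np.ndarray, gt: np.ndarray, spacing: tuple[float, float] | float
) -> float:
    """Symmetric Hausdorff distance between mask boundaries, in mm.

    Boundary pixel sets are scaled per-axis by the pixel spacing before the
    max of the two directed distances is taken. Undefined (raises) when either
    mask is empty.
    """
    if np.isscalar(spacing):
        spacing = (float(spacing), float(spacing))
    pred_b = boundary_pixels(pred).astype(float) * np.asarray(spacing)
    gt_b = boundary_pixels(gt).astype(float) * np.asarray(spacing)
    if len(pred_b) == 0 or len(gt_b) == 0:
        raise ValueError("Hausdorff distance undefined for an empty mask")
    d_pg = directed_hausdorff(pred_b, gt_b)[0]
    d_gp = directed_hausdorff(gt_b, pred_b)[0]
    return max(d_pg, d_gp)


@dataclass
class SegmentationMetrics:
    """Per-image metric table plus mean +/- SD aggregates.

    ``per_image`` has one row per frame with columns
    ``dice, iou, precision, recall, hausdorff_mm`` (Hausdorff is NaN for
    frames where either mask is empty).
    """

    per_image: pd.DataFrame
    mean: dict[str, float] = field(init=False)
    std: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.mean = self.per_image.mean(numeric_only=True).to_dict()
        # sample SD (ddof=1), as cohort tables report
        self.std = self.per_image.std(ddof=1, numeric_only=True).to_dict()

    def summary(self) -> dict[str, dict[str, float]]:
        return {k: {"mean": self.mean[k], "std": self.std[k]} for k in self.mean}

    def to_json_dict(self) -> dict:
        return {
            "aggregate": self.summary(),
            "n_images": int(len(self.per_image)),
        }


def evaluate_masks(
    pred_frames: np.ndarray,
    gt_frames: np.ndarray,
    spacing: tuple[float, float] | float,
    exam_id: str = "",
) -> SegmentationMetrics:
    """Evaluate a stack of predicted masks against ground truth, frame by frame."""
    pred_frames = np.asarray(pred_frames).astype(bool)
    gt_frames = np.asarray(gt_frames).astype(bool)
    if pred_frames.shape != gt_frames.shape:
        raise ValueError(f"shape mismatch: {pred_frames.shape} vs {gt_frames.shape}")
    rows = []
    for i, (p, g) in enumerate(zip(pred_frames, gt_frames)):
        prec, rec = precision_recall(p, g)
        try:
            hd = hausdorff_mm(p, g, spacing)
        except ValueError:
            hd = np.nan
        rows.append(
            {
                "exam_id": exam_id,
                "frame": i,
                "dice": dice_coefficient(p, g),
                "iou": iou(p, g),
                "precision": prec,
                "recall": rec,
                "hausdorff_mm": hd,
            }
        )
    return SegmentationMetrics(per_image=pd.DataFrame(rows))
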