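"""Blended sliding-window inference and segmentation metrics.

Orthomosaics are scanned with overlapping tile x tile windows on a
boundary-flushed stride grid; per-pixel class probabilities are the
arithmetic mean of every window prediction covering the pixel (soft
blending), and the final label map is the per-pixel argmax.  Metrics are
derived from the K x K confusion matrix: per-class IoU, mean IoU over
all classes, foreground IoU (mean over the non-soil classes), and Dice
via the identity D = 2 IoU / (1 + IoU).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from cropstress.fpde import FPDEConfig, fpde_refine
from cropstress.masks import LabelMask, MIX5, IGNORE_LABEL
from cropstress.model import WFUNetPP
from cropstress.patches import window_origins
from cropstress.scene import MultispectralScene

FOREGROUND_SET = (1, 2, 3, 4)  # all non-soil classes


def sliding_window_predict(
    model: WFUNetPP,
    scene: MultispectralScene,
    tile: int = 224,
    stride: int = 96,
    fpde_config: FPDEConfig | None = None,
    batch_size: int = 8,
) -> np.ndarray:
    """Average overlapping window predictions into an H x W x K probability map.

    When ``fpde_config`` is given each window's probability map is FPDE-
    refined before blending.  Scenes smaller than the tile are edge-padded
    and the output cropped back.
    """
    h, w = scene.shape
    pad_h = max(0, tile - h)
    pad_w = max(0, tile - w)
    bands = scene.bands.astype(np.float64)
    bands[~scene.valid_mask] = 0.0
    if pad_h or pad_w:
        bands = np.pad(bands, ((0, pad_h), (0, pad_w), (0, 0)), mode="edge")
    hh, ww = bands.shape[:2]
    K = model.config.num_classes
    acc = np.zeros((hh, ww, K))
    cover = np.zeros((hh, ww, 1))
    origins = window_origins(hh, ww, tile, stride, flush=True)
    model.eval()
    for start in range(0, len(origins), batch_size):
        chunk = origins[start : start + batch_size]
        x = np.stack(
            [np.moveaxis(bands[r : r + tile, c : c + tile], -1, 0) for (r, c) in chunk]
        )
        probs = model(x).probs.data  # N, K, t, t
        for (r, c), p in zip(chunk, probs):
            pm = np.moveaxis(p, 0, -1)
            if fpde_config is not None and fpde_config.iters > 0:
                pm = fpde_refine(pm, fpde_config)
            acc[r : r + tile, c : c + tile] += pm
            cover[r : r + tile, c : c + tile] += 1.0
    blended = acc / cover
    return blended[:h, :w]


def argmax_labels(probs: np.ndarray, valid_mask: np.ndarray | None = None) -> LabelMask:
    """Per-pixel argmax; ties resolve to the smaller class index."""
    labels = np.argmax(probs, axis=-1).astype(np.uint8)
    if valid_mask is not None:
        labels = labels.copy()
        labels[~valid_mask] = IGNORE_LABEL
    return LabelMask(labels, MIX5, valid_mask=valid_mask)


def confusion_matrix_counts(pred: np.ndarray, gt: np.ndarray, num_classes: int = 5) -> np.ndarray:
    """Entry (i, j) counts pixels with ground truth i predicted as j."""
    pred = np.asarray(pred).ravel()
    gt = np.asarray(gt).ravel()
    if pred.shape != gt.shape:
        raise ValueError("prediction and ground truth shapes differ")
    keep = (gt != IGNORE_LABEL) & (pred != IGNORE_LABEL)
    idx = gt[keep].astype(np.int64) * num_classes + pred[keep].astype(np.int64)
    return np.bincount(idx, minlength=num_classes**2).reshape(num_classes, num_classes)


@dataclass
class MetricsReport:
    confusion: np.ndarray
    iou_per_class: np.ndarray
    miou: float
    fg_iou: float
    mean_dice: float
    f1_per_class: np.ndarray
    absent_classes: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "iou_per_class": [None if np.isnan(v) else float(v) for v in self.iou_per_class],
            "miou": float(self.miou),
            "fg_iou": float(self.fg_iou),
            "mean_dice": float(self.mean_dice),
            "f1_per_class": [None if np.isnan(v) else float(v) for v in self.f1_per_class],
            "absent_classes": list(self.absent_classes),
        }


def iou_to_dice(iou):
    """Dice/F1 from IoU: D = 2 I / (1 + I)."""
    iou = np.asarray(iou, dtype=np.float64)
    return 2.0 * iou / (1.0 + iou)


def aggregate_iou(iou_per_class, foreground: tuple = FOREGROUND_SET) -> dict:
    """Mean IoU, foreground IoU, and macro Dice from per-class IoUs.

    Classes with NaN IoU (absent from both prediction and ground truth)
    are excluded from every mean.
    """
    iou = np.asarray(iou_per_class, dtype=np.float64)
    present = ~np.isnan(iou)
    fg = np.zeros_like(present)
    fg[[k for k in foreground if k < iou.size]] = True
    fg &= present
    dice = iou_to_dice(iou)
    return {
        "miou": float(np.mean(iou[present])),
        "fg_iou": float(np.mean(iou[fg])) if fg.any() else float("nan"),
        "mean_dice": float(np.mean(dice[present])),
    }


def metrics_from_confusion(confusion: np.ndarray) -> MetricsReport:
    confusion = np.asarray(confusion, dtype=np.int64)
    K = confusion.shape[0]
    tp = np.diag(confusion).astype(np.float64)
    fp = confusion.sum(axis=0) - tp
    fn = confusion.sum(axis=1) - tp
    denom = tp + fp + fn
    iou = np.full(K, np.nan)
    nonzero = denom > 0
    iou[nonzero] = tp[nonzero] / denom[nonzero]
    agg = aggregate_iou(iou)
    return MetricsReport(
        confusion=confusion,
        iou_per_class=iou,
        miou=agg["miou"],
        fg_iou=agg["fg_iou"],
        mean_dice=agg["mean_dice"],
        f1_per_class=iou_to_dice(iou),
        absent_classes=[int(k) for k in np.flatnonzero(~nonzero)],
    )


def count_components(mask: LabelMask, classes: tuple | None = None) -> int:
    """Total 8-connected component count over the given classes.

    A fragmentation measure: spatially coherent predictions have fewer
    components for the same support.
    """
    labels = mask.labels
    if classes is None:
        classes = [k for k in np.unique(labels) if k != IGNORE_LABEL]
    structure = np.ones((3, 3), dtype=bool)
    total = 0
    for k in classes:
        _, n = ndimage.label(labels == k, structure=structure)
        total += int(n)
    return total
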