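"""Segmentation quality metrics and annotator/model consistency."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .io_formats import LabelVolume
from .segmentation import ConfusionCounts

__all__ = ["SegMetrics", "confusion", "seg_metrics", "iou3d", "pairwise_consistency"]


@dataclass
class SegMetrics:
    """Recall, precision, F1 (Dice) and 3D IoU (Jaccard) for one prediction.

    ``undefined`` flags metrics that hit a 0/0 with a nonempty counterpart
    (e.g. recall with an empty ground truth but a nonempty prediction);
    such metrics are reported as 0 rather than silently inflated.
    """

    recall: float
    precision: float
    f1: float
    iou3d: float
    undefined: tuple[str, ...] = ()


def _as_binary(vol: LabelVolume | np.ndarray, positive_class: int) -> np.ndarray:
    data = vol.data if isinstance(vol, LabelVolume) else np.asarray(vol)
    return data == positive_class


def confusion(
    gt: LabelVolume | np.ndarray,
    pred: LabelVolume | np.ndarray,
    positive_class: int = 1,
) -> ConfusionCounts:
    """Two-class voxel confusion counts (index 0 background, 1 positive class)."""
    g = _as_binary(gt, positive_class)
    p = _as_binary(pred, positive_class)
    if g.shape != p.shape:
        raise ValueError(f"shape mismatch: {g.shape} vs {p.shape}")
    tp_fg = int(np.count_nonzero(g & p))
    fp_fg = int(np.count_nonzero(~g & p))
    fn_fg = int(np.count_nonzero(g & ~p))
    tn_fg = int(g.size - tp_fg - fp_fg - fn_fg)
    # background counts are the mirror image of the foreground counts
    return ConfusionCounts(
        tp=np.array([tn_fg, tp_fg]),
        fp=np.array([fn_fg, fp_fg]),
        fn=np.array([fp_fg, fn_fg]),
        tn=np.array([tp_fg, tn_fg]),
    )


def seg_metrics(counts: ConfusionCounts, positive_class: int = 1) -> SegMetrics:
    """Recall, precision, F1 and 3D IoU from confusion counts.

    Conventions for 0/0: empty ground truth and empty prediction -> 1;
    an empty side with a nonempty counterpart -> 0, flagged in
    ``undefined``.
    """
    tp = float(counts.tp[positive_class])
    fp = float(counts.fp[positive_class])
    fn = float(counts.fn[positive_class])
    undefined = []

    if tp + fn + fp == 0:  # both sets empty
        return SegMetrics(recall=1.0, precision=1.0, f1=1.0, iou3d=1.0)

    if tp + fn == 0:
        recall = 0.0
        undefined.append("recall")
    else:
        recall = tp / (tp + fn)
    if tp + fp == 0:
        precision = 0.0
        undefined.append("precision")
    else:
        precision = tp / (tp + fp)
    f1 = 0.0 if precision + recall == 0 else 2.0 * precision * recall / (precision + recall)
    iou = tp / (tp + fp + fn)
    return SegMetrics(
        recall=recall, precision=precision, f1=f1, iou3d=iou, undefined=tuple(undefined)
    )


def iou3d(a: LabelVolume | np.ndarray, b: LabelVolume | np.ndarray, positive_class: int = 1) -> float:
    """Voxel Jaccard index ``|A ∩ B| / |A ∪ B|``; both empty -> 1."""
    ga = _as_binary(a, positive_class)
    gb = _as_binary(b, positive_class)
    if ga.shape != gb.shape:
        raise ValueError(f"shape mismatch: {ga.shape} vs {gb.shape}")
    union = int(np.count_nonzero(ga | gb))
    if union == 0:
        return 1.0
    return float(np.count_nonzero(ga & gb) / union)


def pairwise_consistency(masks: list[LabelVolume | np.ndarray], positive_class: int = 1) -> float:
    """Mean 3D IoU over all unordered pairs of aligned masks."""
    if len(masks) < 2:
        raise ValueError(f"need at least 2 masks, got {len(masks)}")
    scores = [iou3d(a, b, positive_class) for a, b in combinations(masks, 2)]
    return float(np.mean(scores))
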