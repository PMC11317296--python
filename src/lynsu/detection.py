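"""Stage 1: trainable ROI detection on Z-projections, with mAP scoring.

The detector is a compact anchor-free, single-scale convolutional network
trained from scratch on the numpy backend: a four-stage conv/pool backbone
maps the (resized) projection to a G x G grid; each cell carries per-class
scores and a class-agnostic box regression (sigmoid in-cell centre offsets
plus log-scaled width/height).  Inference applies a confidence threshold,
greedy NMS, and keeps the top-scoring box per class per bilateral side.

Evaluation implements average precision with confidence-sorted greedy
matching and all-point PR interpolation, averaged over classes (mAP@0.5)
and over IoU thresholds 0.5:0.05:0.95 (mAP@0.5:0.95), plus the
coverage-success criterion (a detection succeeds only if the box contains
every ground-truth mask pixel).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from ._nn import Adam, Conv2d, MaxPool2d, Param, ReLU, clip_grad_norm
from .io_formats import ROI_CLASSES, BoundingBox2D
from .projection import Projection2D

__all__ = [
    "DetectorConfig",
    "DetectorModel",
    "DetectionEval",
    "IOU_THRESHOLDS",
    "box_iou",
    "train_detector",
    "detect_rois",
    "detect_rois_merged",
    "coverage_success",
    "evaluate_map",
]

#: Detection IoU thresholds for mAP@0.5:0.95 (0.5 to 0.95 in steps of 0.05).
IOU_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


@dataclass
class DetectorConfig:
    input_size: int = 256
    classes: tuple[str, ...] = ROI_CLASSES
    epochs: int = 30
    learning_rate: float = 1e-3
    confidence_threshold: float = 0.25
    nms_iou: float = 0.5
    seed: int = 0
    base_channels: int = 8
    positive_weight: float = 64.0  # BCE weight of object cells vs background cells
    # regression targets are dilated so detections err on the side of full
    # coverage (the success criterion requires the box to contain the mask)
    target_dilation_frac: float = 0.08
    target_dilation_px: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.confidence_threshold <= 1.0):
            raise ValueError("confidence_threshold must be in (0, 1]")
        if not (0.0 < self.nms_iou < 1.0):
            raise ValueError("nms_iou must be in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.input_size % 16 != 0:
            raise ValueError("input_size must be divisible by 16")


@dataclass
class DetectionEval:
    map50: float
    map50_95: float
    per_class_ap: dict[str, list[float]] = field(default_factory=dict)


def box_iou(a: BoundingBox2D, b: BoundingBox2D) -> float:
    """Intersection over union of two half-open pixel boxes."""
    ix = max(0.0, min(a.x1, b.x1) - max(a.x0, b.x0))
    iy = max(0.0, min(a.y1, b.y1) - max(a.y0, b.y0))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


# ---------------------------------------------------------------------------
# Model


class DetectorModel:
    """Single-scale grid detector on the numpy backend.

    The backbone downsamples by 16x; cell stride in input space is
    ``input_size / grid``.  Two normalized coordinate channels accompany the
    intensity input so ROI classes can be separated by anatomical position
    as well as appearance.  ``trained`` is set by :func:`train_detector`.
    """

    def __init__(self, cfg: DetectorConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        c = cfg.base_channels
        self.grid = cfg.input_size // 16
        self.stride = 16  # input pixels per cell
        ncls = len(cfg.classes)
        s = cfg.input_size
        yy, xx = np.meshgrid(
            np.linspace(0.0, 1.0, s, dtype=np.float32),
            np.linspace(0.0, 1.0, s, dtype=np.float32),
            indexing="ij",
        )
        self._coords = np.stack([yy, xx])
        self.layers = [
            Conv2d(3, c, 3, rng), ReLU(), MaxPool2d(),
            Conv2d(c, 2 * c, 3, rng), ReLU(), MaxPool2d(),
            Conv2d(2 * c, 2 * c, 3, rng), ReLU(), MaxPool2d(),
            Conv2d(2 * c, 4 * c, 3, rng), ReLU(), MaxPool2d(),
        ]
        self.cls_head = Conv2d(4 * c, ncls, 1, rng)
        self.box_head = Conv2d(4 * c, 4, 1, rng)
        self.trained = False

    @property
    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers + [self.cls_head, self.box_head]:
            out.extend(layer.params)
        return out

    def forward(self, img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """``img``: (S, S) float in [0, 1] -> class logits (C, G, G), box raw (4, G, G)."""
        x = np.concatenate([img[None].astype(np.float32), self._coords])
        for layer in self.layers:
            x = layer.forward(x)
        self._feat = x
        return self.cls_head.forward(x), self.box_head.forward(x)

    def backward(self, g_cls: np.ndarray, g_box: np.ndarray) -> None:
        gx = self.cls_head.backward(g_cls) + self.box_head.backward(g_box)
        for layer in reversed(self.layers):
            gx = layer.backward(gx)

    def prepare(self, proj: Projection2D) -> np.ndarray:
        """Resize a projection to the model input and normalize to [0, 1]."""
        s = self.cfg.input_size
        img = resize(
            proj.data.astype(np.float32), (s, s), order=1, anti_aliasing=False, preserve_range=True
        )
        return (img / 255.0).astype(np.float32)

    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.params, state):
            p.value[...] = v


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _targets(
    boxes: list[BoundingBox2D],
    scale: tuple[float, float],
    cfg: DetectorConfig,
    grid: int,
    stride: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Grid targets: class map (C,G,G), box targets (4,G,G), positive mask (G,G)."""
    ncls = len(cfg.classes)
    cls_t = np.zeros((ncls, grid, grid), dtype=np.float32)
    box_t = np.zeros((4, grid, grid), dtype=np.float32)
    pos = np.zeros((grid, grid), dtype=bool)
    sy, sx = scale
    for b in boxes:
        cx, cy = b.center
        dw = 2.0 * (cfg.target_dilation_frac * b.width + cfg.target_dilation_px)
        dh = 2.0 * (cfg.target_dilation_frac * b.height + cfg.target_dilation_px)
        cx, cy = cx * sx, cy * sy
        w, h = (b.width + dw) * sx, (b.height + dh) * sy
        gx = min(int(cx / stride), grid - 1)
        gy = min(int(cy / stride), grid - 1)
        ci = cfg.classes.index(b.roi_class)
        cls_t[ci, gy, gx] = 1.0
        box_t[0, gy, gx] = cx / stride - gx  # in-cell offset, [0, 1)
        box_t[1, gy, gx] = cy / stride - gy
        box_t[2, gy, gx] = np.log(max(w, 1e-3) / stride)
        box_t[3, gy, gx] = np.log(max(h, 1e-3) / stride)
        pos[gy, gx] = True
    return cls_t, box_t, pos


def train_detector(
    train_set: list[tuple[tuple[Projection2D, Projection2D], list[BoundingBox2D]]],
    cfg: DetectorConfig,
) -> DetectorModel:
    """Train the grid detector from scratch; reproducible for a fixed seed.

    Each brain contributes both of its projections (max and mean) as
    separate training images sharing the same boxes.
    """
    if not train_set:
        raise ValueError("empty training set")
    model = DetectorModel(cfg)
    images: list[tuple[np.ndarray, list[BoundingBox2D], tuple[int, int]]] = []
    for projs, boxes in train_set:
        if not boxes:
            raise ValueError("every training image must have at least one box")
        for proj in projs:
            h, w = proj.shape
            for b in boxes:
                if b.x1 > w or b.y1 > h or b.x0 < 0 or b.y0 < 0:
                    raise ValueError(f"box {b} lies outside its {h}x{w} image")
            images.append((model.prepare(proj), boxes, proj.shape))

    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.params, lr=cfg.learning_rate)
    grid, stride, s = model.grid, model.stride, cfg.input_size
    ncells = grid * grid * len(cfg.classes)

    for _epoch in range(cfg.epochs):
        order = rng.permutation(len(images))
        for idx in order:
            img, boxes, (h, w) = images[idx]
            cls_t, box_t, pos = _targets(boxes, (s / h, s / w), cfg, grid, stride)
            cls_logits, box_raw = model.forward(img)

            p = _sigmoid(cls_logits)
            weight = np.where(cls_t > 0, cfg.positive_weight, 1.0)
            g_cls = (weight * (p - cls_t) / ncells).astype(np.float32)

            g_box = np.zeros_like(box_raw)
            npos = max(int(pos.sum()), 1)
            sxy = _sigmoid(box_raw[:2])
            g_box[:2] = np.sign(sxy - box_t[:2]) * sxy * (1.0 - sxy)
            g_box[2:] = np.sign(box_raw[2:] - box_t[2:])
            g_box *= pos[None] / (4.0 * npos)
            g_box = g_box.astype(np.float32)

            opt.zero_grad()
            model.backward(g_cls, g_box)
            clip_grad_norm(model.params, 5.0)
            opt.step()

    model.trained = True
    return model


def _nms(boxes: list[BoundingBox2D], iou_thr: float) -> list[BoundingBox2D]:
    """Greedy per-class non-maximum suppression."""
    kept: list[BoundingBox2D] = []
    for b in sorted(boxes, key=lambda b: -b.confidence):
        if all(
            box_iou(b, k) < iou_thr or b.roi_class != k.roi_class for k in kept
        ):
            kept.append(b)
    return kept


def _top_per_side(boxes: list[BoundingBox2D], image_width: int) -> list[BoundingBox2D]:
    """Keep the highest-confidence box per (class, hemisphere side)."""
    best: dict[tuple[str, bool], BoundingBox2D] = {}
    for b in boxes:
        key = (b.roi_class, b.center[0] < image_width / 2.0)
        if key not in best or b.confidence > best[key].confidence:
            best[key] = b
    return sorted(best.values(), key=lambda b: (b.roi_class, b.x0))


def _decode(
    model: DetectorModel,
    cls_logits: np.ndarray,
    box_raw: np.ndarray,
    image_shape: tuple[int, int],
    threshold: float,
) -> list[BoundingBox2D]:
    h, w = image_shape
    s = model.cfg.input_size
    scores = _sigmoid(cls_logits)
    stride = model.stride
    out: list[BoundingBox2D] = []
    for ci, gy, gx in zip(*np.nonzero(scores >= threshold)):
        cx = (gx + _sigmoid(box_raw[0:1, gy, gx])[0]) * stride * (w / s)
        cy = (gy + _sigmoid(box_raw[1:2, gy, gx])[0]) * stride * (h / s)
        bw = float(np.exp(box_raw[2, gy, gx])) * stride * (w / s)
        bh = float(np.exp(box_raw[3, gy, gx])) * stride * (h / s)
        x0, x1 = cx - bw / 2.0, cx + bw / 2.0
        y0, y1 = cy - bh / 2.0, cy + bh / 2.0
        x0, x1 = max(0.0, x0), min(float(w), x1)
        y0, y1 = max(0.0, y0), min(float(h), y1)
        if x1 - x0 < 1.0 or y1 - y0 < 1.0:
            continue
        out.append(
            BoundingBox2D(
                roi_class=model.cfg.classes[ci],
                x0=x0, y0=y0, x1=x1, y1=y1,
                confidence=float(scores[ci, gy, gx]),
            )
        )
    return out


def detect_rois(
    model: DetectorModel, proj: Projection2D, cfg: DetectorConfig | None = None
) -> list[BoundingBox2D]:
    """Detect ROI boxes on one projection (threshold, NMS, one box per class/side)."""
    cfg = cfg or model.cfg
    cls_logits, box_raw = model.forward(model.prepare(proj))
    raw = _decode(model, cls_logits, box_raw, proj.shape, cfg.confidence_threshold)
    return _top_per_side(_nms(raw, cfg.nms_iou), proj.shape[1])


def detect_rois_merged(
    model: DetectorModel,
    projections: tuple[Projection2D, Projection2D],
    cfg: DetectorConfig | None = None,
) -> list[BoundingBox2D]:
    """Detect on both projection modes of one brain and merge the boxes by NMS."""
    cfg = cfg or model.cfg
    raw: list[BoundingBox2D] = []
    shape = projections[0].shape
    for proj in projections:
        if proj.shape != shape:
            raise ValueError("projection pair has mismatched shapes")
        cls_logits, box_raw = model.forward(model.prepare(proj))
        raw.extend(_decode(model, cls_logits, box_raw, proj.shape, cfg.confidence_threshold))
    return _top_per_side(_nms(raw, cfg.nms_iou), shape[1])


# ---------------------------------------------------------------------------
# Evaluation


def coverage_success(box: BoundingBox2D, gt_mask_projection: np.ndarray) -> bool:
    """True iff the box contains every nonzero pixel of the mask projection."""
    ys, xs = np.nonzero(np.asarray(gt_mask_projection))
    if ys.size == 0:
        raise ValueError("empty ground-truth mask")
    return bool(
        ys.min() >= box.y0
        and ys.max() < box.y1
        and xs.min() >= box.x0
        and xs.max() < box.x1
    )


def _average_precision(
    preds: list[tuple[int, BoundingBox2D]],
    gts: list[list[BoundingBox2D]],
    iou_thr: float,
) -> float:
    """AP for one class: confidence-sorted greedy matching, all-point interpolation."""
    n_gt = sum(len(g) for g in gts)
    if n_gt == 0:
        return float("nan")
    order = sorted(range(len(preds)), key=lambda i: (-preds[i][1].confidence, preds[i][0], i))
    matched: list[set[int]] = [set() for _ in gts]
    tp = np.zeros(len(order))
    for rank, i in enumerate(order):
        img, box = preds[i]
        best_iou, best_j = 0.0, -1
        for j, gt in enumerate(gts[img]):
            if j in matched[img]:
                continue
            iou = box_iou(box, gt)
            if iou >= iou_thr and iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0:
            matched[img].add(best_j)
            tp[rank] = 1.0
    if len(order) == 0:
        return 0.0
    cum_tp = np.cumsum(tp)
    precision = cum_tp / np.arange(1, len(order) + 1)
    recall = cum_tp / n_gt
    # all-point interpolation: running max of precision from the right
    p_interp = np.maximum.accumulate(precision[::-1])[::-1]
    ap = 0.0
    prev_r = 0.0
    for r, p in zip(recall, p_interp):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


def evaluate_map(
    preds: list[list[BoundingBox2D]],
    gts: list[list[BoundingBox2D]],
    classes: tuple[str, ...] = ROI_CLASSES,
) -> DetectionEval:
    """mAP@0.5 and mAP@0.5:0.95 over aligned per-image box lists.

    AP is averaged over the classes present in the ground truth, then over
    IoU thresholds.
    """
    if len(preds) != len(gts):
        raise ValueError(f"preds has {len(preds)} images but gts has {len(gts)}")
    per_class_ap: dict[str, list[float]] = {}
    for cls in classes:
        cls_preds = [
            (i, b) for i, boxes in enumerate(preds) for b in boxes if b.roi_class == cls
        ]
        cls_gts = [[b for b in boxes if b.roi_class == cls] for boxes in gts]
        aps = [_average_precision(cls_preds, cls_gts, thr) for thr in IOU_THRESHOLDS]
        if not all(np.isnan(a) for a in aps):
            per_class_ap[cls] = aps
    if not per_class_ap:
        raise ValueError("no ground-truth boxes for any class")
    ap_matrix = np.array([per_class_ap[c] for c in per_class_ap])
    map_per_thr = ap_matrix.mean(axis=0)
    return DetectionEval(
        map50=float(map_per_thr[0]),
        map50_95=float(map_per_thr.mean()),
        per_class_ap=per_class_ap,
    )


# ---------------------------------------------------------------------------
# Checkpointing


def save_detector(model: DetectorModel, path: str) -> None:
    """Serialize config and weights to an ``.npz`` checkpoint."""
    import json

    cfg = model.cfg
    meta = json.dumps(
        {
            "input_size": cfg.input_size,
            "classes": list(cfg.classes),
            "epochs": cfg.epochs,
            "learning_rate": cfg.learning_rate,
            "confidence_threshold": cfg.confidence_threshold,
            "nms_iou": cfg.nms_iou,
            "seed": cfg.seed,
            "base_channels": cfg.base_channels,
            "positive_weight": cfg.positive_weight,
            "trained": model.trained,
        }
    )
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.params)}
    np.savez(path, meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_detector(path: str) -> DetectorModel:
    import json

    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta"]).decode())
        trained = meta.pop("trained")
        meta["classes"] = tuple(meta["classes"])
        model = DetectorModel(DetectorConfig(**meta))
        model.load_state([npz[f"param_{i}"] for i in range(len(model.params))])
    model.trained = trained
    return model
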