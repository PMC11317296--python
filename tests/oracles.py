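"""Independent brute-force oracles shared by the test modules."""

import numpy as np

from lynsu.detection import box_iou


def ap_oracle(preds, gts, thr):
    """Brute-force average precision.

    Re-runs greedy matching from scratch at every confidence cut and
    integrates the PR curve with an explicit all-point max search —
    structurally independent of the implementation under test.
    """
    n_gt = sum(len(g) for g in gts)
    if n_gt == 0:
        return float("nan")
    order = sorted(range(len(preds)), key=lambda i: (-preds[i][1].confidence, preds[i][0], i))
    points = []
    for k in range(1, len(order) + 1):
        matched = [set() for _ in gts]
        tp = 0
        for i in order[:k]:
            img, box = preds[i]
            best_iou, best_j = 0.0, -1
            for j, gt in enumerate(gts[img]):
                if j in matched[img]:
                    continue
                iou = box_iou(box, gt)
                if iou >= thr and iou > best_iou:
                    best_iou, best_j = iou, j
            if best_j >= 0:
                matched[img].add(best_j)
                tp += 1
        points.append((tp / n_gt, tp / k))
    ap = 0.0
    prev_r = 0.0
    for r, _ in points:
        if r <= prev_r:
            continue
        p_best = max(p2 for r2, p2 in points if r2 >= r)
        ap += (r - prev_r) * p_best
        prev_r = r
    return ap


def random_detection_scenario(rng, n_images=2, max_boxes=5):
    """Random toy detection scenario with distinct confidences."""
    from lynsu.io_formats import BoundingBox2D

    classes = ["AL", "MB_CAL", "CX"]
    gts, preds = [], []
    for _ in range(n_images):
        g, p = [], []
        for _ in range(int(rng.integers(1, max_boxes + 1))):
            x0, y0 = rng.integers(0, 40, size=2)
            w, h = rng.integers(5, 25, size=2)
            g.append(BoundingBox2D(classes[int(rng.integers(0, 3))], x0, y0, x0 + w, y0 + h))
        for _ in range(int(rng.integers(0, max_boxes + 1))):
            x0, y0 = rng.integers(0, 40, size=2)
            w, h = rng.integers(5, 25, size=2)
            p.append(
                BoundingBox2D(
                    classes[int(rng.integers(0, 3))],
                    x0, y0, x0 + w, y0 + h,
                    confidence=round(float(rng.random()), 6),
                )
            )
        gts.append(g)
        preds.append(p)
    return preds, gts
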