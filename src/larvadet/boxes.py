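"""Axis-aligned boxes: containers, IoU, delta coding, NMS, scale classes.

Internal convention everywhere: 0-based, half-open pixel coordinates
(x1 <= x < x2), so width = x2 - x1 and area = (x2-x1)*(y2-y1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# COCO-style size bins: small < 32², medium up to 96² (inclusive), large above.
MEDIUM_MIN_AREA = 32 * 32      # 1024
MEDIUM_MAX_AREA = 96 * 96      # 9216


@dataclass
class BoxSet:
    """A set of boxes with class labels and optional detection scores."""

    boxes: np.ndarray                      # (n, 4) float, x1 y1 x2 y2
    labels: np.ndarray                     # (n,) int class ids (1-based)
    scores: np.ndarray | None = None       # (n,) float in [0, 1], or None

    def __post_init__(self):
        self.boxes = np.asarray(self.boxes, dtype=np.float64).reshape(-1, 4)
        self.labels = np.asarray(self.labels, dtype=np.int64).reshape(-1)
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=np.float64).reshape(-1)
        if len(self.labels) != len(self.boxes):
            raise ValueError("labels and boxes disagree in length")
        if self.scores is not None and len(self.scores) != len(self.boxes):
            raise ValueError("scores and boxes disagree in length")

    def __len__(self):
        return len(self.boxes)

    @staticmethod
    def empty() -> "BoxSet":
        return BoxSet(np.zeros((0, 4)), np.zeros(0, dtype=np.int64))

    def select(self, idx) -> "BoxSet":
        return BoxSet(self.boxes[idx], self.labels[idx],
                      None if self.scores is None else self.scores[idx])


def box_area(boxes: np.ndarray) -> np.ndarray:
    boxes = np.atleast_2d(np.asarray(boxes, dtype=np.float64))
    return (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])


def scale_of_box(box) -> str:
    """COCO-style size class of a box: 'small', 'medium' or 'large'.

    Boundaries are inclusive to medium: area in [32², 96²] is medium.
    """
    a = float(box_area(box)[0])
    if a <= 0:
        raise ValueError("box has non-positive area")
    if a < MEDIUM_MIN_AREA:
        return "small"
    if a <= MEDIUM_MAX_AREA:
        return "medium"
    return "large"


def iou(a, b) -> float:
    """Intersection over union of two boxes."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a[2] <= a[0] or a[3] <= a[1] or b[2] <= b[0] or b[3] <= b[1]:
        raise ValueError("degenerate box in iou")
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    union = box_area(a)[0] + box_area(b)[0] - inter
    return float(inter / union)


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (n,4) and (m,4) box arrays."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    if len(a) == 0 or len(b) == 0:
        return np.zeros((len(a), len(b)))
    ix = np.clip(np.minimum(a[:, None, 2], b[None, :, 2]) -
                 np.maximum(a[:, None, 0], b[None, :, 0]), 0, None)
    iy = np.clip(np.minimum(a[:, None, 3], b[None, :, 3]) -
                 np.maximum(a[:, None, 1], b[None, :, 1]), 0, None)
    inter = ix * iy
    union = box_area(a)[:, None] + box_area(b)[None, :] - inter
    return inter / np.maximum(union, 1e-12)


# ---------------------------------------------------------------------------
# delta coding (dx, dy, dw, dh) relative to an anchor/proposal
# ---------------------------------------------------------------------------

def encode_boxes(boxes: np.ndarray, anchors: np.ndarray,
                 stds=(1.0, 1.0, 1.0, 1.0)) -> np.ndarray:
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    anchors = np.asarray(anchors, dtype=np.float64).reshape(-1, 4)
    if np.any(boxes[:, 2:] <= boxes[:, :2]) or np.any(anchors[:, 2:] <= anchors[:, :2]):
        raise ValueError("non-positive box extent in encode_boxes")
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    ax = anchors[:, 0] + 0.5 * aw
    ay = anchors[:, 1] + 0.5 * ah
    bw = boxes[:, 2] - boxes[:, 0]
    bh = boxes[:, 3] - boxes[:, 1]
    bx = boxes[:, 0] + 0.5 * bw
    by = boxes[:, 1] + 0.5 * bh
    d = np.stack([(bx - ax) / aw, (by - ay) / ah,
                  np.log(bw / aw), np.log(bh / ah)], axis=1)
    return d / np.asarray(stds, dtype=np.float64)


def decode_boxes(deltas: np.ndarray, anchors: np.ndarray,
                 stds=(1.0, 1.0, 1.0, 1.0), max_wh_log: float = 8.0) -> np.ndarray:
    deltas = np.asarray(deltas, dtype=np.float64).reshape(-1, 4) * \
        np.asarray(stds, dtype=np.float64)
    anchors = np.asarray(anchors, dtype=np.float64).reshape(-1, 4)
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    ax = anchors[:, 0] + 0.5 * aw
    ay = anchors[:, 1] + 0.5 * ah
    cx = ax + deltas[:, 0] * aw
    cy = ay + deltas[:, 1] * ah
    w = aw * np.exp(np.clip(deltas[:, 2], -max_wh_log, max_wh_log))
    h = ah * np.exp(np.clip(deltas[:, 3], -max_wh_log, max_wh_log))
    return np.stack([cx - 0.5 * w, cy - 0.5 * h,
                     cx + 0.5 * w, cy + 0.5 * h], axis=1)


def clip_boxes(boxes: np.ndarray, width: int, height: int) -> np.ndarray:
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4).copy()
    boxes[:, 0::2] = np.clip(boxes[:, 0::2], 0, width)
    boxes[:, 1::2] = np.clip(boxes[:, 1::2], 0, height)
    return boxes


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float) -> np.ndarray:
    """Greedy NMS; returns kept indices.

    Order is by descending score with index as the deterministic tie-break;
    a box is suppressed when its IoU with any kept box exceeds ``iou_thr``.
    """
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    scores = np.asarray(scores, dtype=np.float64).reshape(-1)
    n = len(boxes)
    if n == 0:
        return np.zeros(0, dtype=np.intp)
    order = np.lexsort((np.arange(n), -scores))
    areas = box_area(boxes)
    kept: list[int] = []
    suppressed = np.zeros(n, dtype=bool)
    for oi in order:
        if suppressed[oi]:
            continue
        kept.append(oi)
        rest = order[~suppressed[order]]
        ix = np.clip(np.minimum(boxes[rest, 2], boxes[oi, 2]) -
                     np.maximum(boxes[rest, 0], boxes[oi, 0]), 0, None)
        iy = np.clip(np.minimum(boxes[rest, 3], boxes[oi, 3]) -
                     np.maximum(boxes[rest, 1], boxes[oi, 1]), 0, None)
        inter = ix * iy
        ovr = inter / np.maximum(areas[rest] + areas[oi] - inter, 1e-12)
        suppressed[rest[ovr > iou_thr]] = True
        suppressed[oi] = True  # keep it out of future comparisons
    return np.asarray(kept, dtype=np.intp)
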