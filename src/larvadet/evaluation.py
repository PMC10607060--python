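"""Detection metrics: precision/recall, 101-point AP, mAP and mRecall over
IoU thresholds 0.50:0.05:0.95, per-scale AP, and a confusion matrix.

Matching is greedy by descending score within each (image, class): a
detection is a true positive when its best-IoU *unmatched* ground truth
reaches the threshold (that ground truth is then consumed), otherwise a
false positive; leftover ground truths are false negatives.  AP uses the
101-point interpolation (precision at recall r is the maximum precision at
any recall ≥ r, sampled at r = 0.00, 0.01, …, 1.00).  mAP averages AP over
classes and the ten IoU thresholds; mRecall averages the maximum achieved
recall the same way, with at most 100 detections kept per image.  Per-scale
AP restricts ground truths to a size bin; detections matching out-of-bin
ground truths, or unmatched detections whose own box falls outside the bin,
are ignored rather than counted as false positives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boxes import (MEDIUM_MAX_AREA, MEDIUM_MIN_AREA, BoxSet, box_area, iou,
                    iou_matrix, scale_of_box)

IOU_THRESHOLDS = np.round(np.arange(0.50, 0.96, 0.05), 2)

_SCALE_RANGES = {
    "all": (0.0, np.inf),
    "small": (0.0, MEDIUM_MIN_AREA),
    "medium": (MEDIUM_MIN_AREA, MEDIUM_MAX_AREA + 1e-9),
    "large": (MEDIUM_MAX_AREA + 1e-9, np.inf),
}


@dataclass
class PRCurve:
    """Ranked detection outcomes for one class at one IoU threshold."""

    scores: np.ndarray      # descending
    tp: np.ndarray          # bool flags aligned with scores
    n_gts: int

    @property
    def precision(self) -> np.ndarray:
        ctp = np.cumsum(self.tp)
        return ctp / np.arange(1, len(self.tp) + 1)

    @property
    def recall(self) -> np.ndarray:
        if self.n_gts == 0:
            return np.zeros(len(self.tp))
        return np.cumsum(self.tp) / self.n_gts


@dataclass
class MetricReport:
    class_names: list[str]
    ap_per_class: dict[str, float]          # averaged over IoU thresholds, %
    ap50_per_class: dict[str, float]
    recall_per_class: dict[str, float]
    map: float                              # %
    map50: float
    ap_medium: float | None
    ap_large: float | None
    mrecall: float
    confusion: np.ndarray                   # (K+1, K+1) row-normalised %

    def as_dict(self) -> dict:
        return {
            "mAP": self.map, "mAP50": self.map50,
            "AP_M": self.ap_medium, "AP_L": self.ap_large,
            "mRecall": self.mrecall,
            "AP_per_class": self.ap_per_class,
            "AP50_per_class": self.ap50_per_class,
            "recall_per_class": self.recall_per_class,
            "confusion_pct": self.confusion.tolist(),
        }

    def table(self) -> str:
        lines = [f"{'class':<12}{'AP':>8}{'AP50':>8}{'recall':>8}"]
        for name in self.class_names:
            lines.append(f"{name:<12}{self.ap_per_class[name]:>8.1f}"
                         f"{self.ap50_per_class[name]:>8.1f}"
                         f"{self.recall_per_class[name]:>8.1f}")
        apm = "-" if self.ap_medium is None else f"{self.ap_medium:.1f}"
        apl = "-" if self.ap_large is None else f"{self.ap_large:.1f}"
        lines.append(f"mAP {self.map:.1f}  mAP50 {self.map50:.1f}  "
                     f"AP_M {apm}  AP_L {apl}  mRecall {self.mrecall:.1f}")
        return "\n".join(lines)


def match_detections(dets: BoxSet, gts: BoxSet, iou_thr: float):
    """Greedy matching within one image and one class.

    Returns (scores, tp flags, fn count, matched gt index per det or -1).
    """
    n_det, n_gt = len(dets), len(gts)
    order = np.lexsort((np.arange(n_det),
                        -(dets.scores if dets.scores is not None
                          else np.ones(n_det))))
    tp = np.zeros(n_det, dtype=bool)
    matched_gt = np.full(n_det, -1, dtype=int)
    taken = np.zeros(n_gt, dtype=bool)
    ious = iou_matrix(dets.boxes, gts.boxes) if n_det and n_gt else None
    for rank, d in enumerate(order):
        if n_gt == 0:
            break
        free = ~taken
        if not np.any(free):
            break
        cand = np.where(free, ious[d], -1.0)
        g = int(cand.argmax())
        if cand[g] >= iou_thr:
            tp[rank] = True
            matched_gt[rank] = g
            taken[g] = True
    scores = (dets.scores if dets.scores is not None
              else np.ones(n_det))[order]
    return scores, tp, int(n_gt - taken.sum()), matched_gt, order


def average_precision(curve: PRCurve) -> float:
    """101-point interpolated area under the precision-recall curve."""
    if curve.n_gts == 0:
        raise ValueError("AP undefined for a class with no ground truths")
    if len(curve.tp) == 0:
        return 0.0
    rec = curve.recall
    prec = curve.precision
    # max precision at recall >= r
    prec_mono = np.maximum.accumulate(prec[::-1])[::-1]
    grid = np.linspace(0.0, 1.0, 101)
    idx = np.searchsorted(rec, grid, side="left")
    interp = np.where(idx < len(prec_mono), prec_mono[np.minimum(idx, len(prec_mono) - 1)], 0.0)
    return float(interp.mean())


def _class_curve(dets_by_img: dict, gts_by_img: dict, cls: int,
                 iou_thr: float, area_range=( 0.0, np.inf),
                 max_dets: int = 100):
    """Pooled ranked TP flags for one class over all images.

    ``area_range`` implements per-scale AP with ignore semantics.
    """
    lo, hi = area_range
    all_scores, all_tp, all_ignore = [], [], []
    n_gts = 0
    for img_id, gts in gts_by_img.items():
        g_idx = np.flatnonzero(gts.labels == cls)
        g = gts.select(g_idx)
        g_area = box_area(g.boxes) if len(g) else np.zeros(0)
        g_ignored = ~((g_area >= lo) & (g_area < hi)) if len(g) else \
            np.zeros(0, dtype=bool)
        n_gts += int((~g_ignored).sum())
        dets = dets_by_img.get(img_id, BoxSet.empty())
        d_idx = np.flatnonzero(dets.labels == cls)
        d = dets.select(d_idx)
        if len(d) > max_dets:
            order = np.lexsort((np.arange(len(d)), -d.scores))
            d = d.select(np.sort(order[:max_dets]))
        if len(d) == 0:
            continue
        scores, tp, _fn, matched, order = match_detections(d, g, iou_thr)
        ignore = np.zeros(len(d), dtype=bool)
        for r in range(len(d)):
            if matched[r] >= 0 and g_ignored[matched[r]]:
                ignore[r] = True        # matched an out-of-bin gt
                tp[r] = False
            elif not tp[r]:
                a = float(box_area(d.boxes[order[r]])[0])
                if not (lo <= a < hi):
                    ignore[r] = True    # stray detection outside the bin
        keep = ~ignore
        all_scores.append(scores[keep])
        all_tp.append(tp[keep])
    if all_scores:
        scores = np.concatenate(all_scores)
        tp = np.concatenate(all_tp)
        order = np.argsort(-scores, kind="stable")
        scores, tp = scores[order], tp[order]
    else:
        scores, tp = np.zeros(0), np.zeros(0, dtype=bool)
    return PRCurve(scores, tp, n_gts)


def summarize(dets_by_img: dict, gts_by_img: dict,
              class_names: list[str]) -> MetricReport:
    """Full metric report over a test set.

    ``dets_by_img`` / ``gts_by_img`` map image id → BoxSet.  All percentages
    are on a 0–100 scale.
    """
    K = len(class_names)
    total_gts = sum(len(g) for g in gts_by_img.values())
    if total_gts == 0:
        raise ValueError("cannot evaluate against an empty ground-truth set")

    ap_pc, ap50_pc, rec_pc = {}, {}, {}
    scale_aps = {"medium": [], "large": []}
    for k in range(1, K + 1):
        name = class_names[k - 1]
        cls_gts = sum(int((g.labels == k).sum()) for g in gts_by_img.values())
        if cls_gts == 0:
            continue  # AP undefined; excluded from the means
        aps, recs = [], []
        for thr in IOU_THRESHOLDS:
            curve = _class_curve(dets_by_img, gts_by_img, k, thr)
            aps.append(average_precision(curve))
            recs.append(curve.recall[-1] if len(curve.tp) else 0.0)
        ap_pc[name] = 100.0 * float(np.mean(aps))
        ap50_pc[name] = 100.0 * aps[0]
        rec_pc[name] = 100.0 * float(np.mean(recs))
        for scale in ("medium", "large"):
            s_aps = []
            for thr in IOU_THRESHOLDS:
                curve = _class_curve(dets_by_img, gts_by_img, k, thr,
                                     area_range=_SCALE_RANGES[scale])
                if curve.n_gts > 0:
                    s_aps.append(average_precision(curve))
            if s_aps:
                scale_aps[scale].append(float(np.mean(s_aps)))

    if not ap_pc:
        raise ValueError("no class has ground truths")
    return MetricReport(
        class_names=class_names,
        ap_per_class=ap_pc,
        ap50_per_class=ap50_pc,
        recall_per_class=rec_pc,
        map=float(np.mean(list(ap_pc.values()))),
        map50=float(np.mean(list(ap50_pc.values()))),
        ap_medium=100.0 * float(np.mean(scale_aps["medium"]))
        if scale_aps["medium"] else None,
        ap_large=100.0 * float(np.mean(scale_aps["large"]))
        if scale_aps["large"] else None,
        mrecall=float(np.mean(list(rec_pc.values()))),
        confusion=confusion_matrix(dets_by_img, gts_by_img, K),
    )


def confusion_matrix(dets_by_img: dict, gts_by_img: dict, n_classes: int,
                     conf: float = 0.5, iou_thr: float = 0.5) -> np.ndarray:
    """(K+1)×(K+1) row-normalised confusion matrix in percent.

    Rows are ground-truth classes (last row = background), columns predicted
    classes (last column = background).  Detections below ``conf`` are
    discarded; matching is class-agnostic and greedy by score, so a
    detection of the wrong species lands in an off-diagonal cell, a ground
    truth nobody claimed lands in the background column, and an unmatched
    detection charges the background row.
    """
    K = n_classes
    counts = np.zeros((K + 1, K + 1))
    for img_id, gts in gts_by_img.items():
        dets = dets_by_img.get(img_id, BoxSet.empty())
        if dets.scores is not None:
            dets = dets.select(np.flatnonzero(dets.scores >= conf))
        n_det, n_gt = len(dets), len(gts)
        taken = np.zeros(n_gt, dtype=bool)
        matched_det = np.zeros(n_det, dtype=bool)
        if n_det and n_gt:
            ious = iou_matrix(dets.boxes, gts.boxes)
            order = np.lexsort((np.arange(n_det), -dets.scores)) \
                if dets.scores is not None else np.arange(n_det)
            for d in order:
                cand = np.where(taken, -1.0, ious[d])
                g = int(cand.argmax())
                if cand[g] >= iou_thr:
                    taken[g] = True
                    matched_det[d] = True
                    counts[gts.labels[g] - 1, dets.labels[d] - 1] += 1
        for g in np.flatnonzero(~taken):
            counts[gts.labels[g] - 1, K] += 1       # missed: "background"
        for d in np.flatnonzero(~matched_det):
            counts[K, dets.labels[d] - 1] += 1      # ghost detection
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(row_sums > 0, 100.0 * counts / row_sums, 0.0)
    return pct
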