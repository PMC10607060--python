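"""Evaluator against brute-force oracles and its conservation properties."""

import numpy as np
import pytest

from larvadet.boxes import BoxSet
from larvadet.evaluation import (IOU_THRESHOLDS, PRCurve, average_precision,
                                 confusion_matrix, match_detections,
                                 summarize)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def ap_oracle(tp_flags, n_gts):
    """Enumerate every ranking prefix; AP = mean over the 101-point recall
    grid of the best precision at recall >= r."""
    if n_gts == 0 or len(tp_flags) == 0:
        return 0.0
    prec, rec = [], []
    tp = 0
    for i, f in enumerate(tp_flags, start=1):
        tp += bool(f)
        prec.append(tp / i)
        rec.append(tp / n_gts)
    total = 0.0
    for r in np.linspace(0, 1, 101):
        cands = [p for p, rr in zip(prec, rec) if rr >= r]
        total += max(cands) if cands else 0.0
    return total / 101


def greedy_match_oracle(det_boxes, det_scores, gt_boxes, thr):
    """Plain-loop greedy matcher."""
    from larvadet.boxes import iou
    order = sorted(range(len(det_boxes)), key=lambda i: (-det_scores[i], i))
    taken = set()
    flags = []
    for d in order:
        best, best_iou = None, -1.0
        for g in range(len(gt_boxes)):
            if g in taken:
                continue
            v = iou(det_boxes[d], gt_boxes[g])
            if v > best_iou:
                best, best_iou = g, v
        if best is not None and best_iou >= thr:
            taken.add(best)
            flags.append(True)
        else:
            flags.append(False)
    return flags, len(gt_boxes) - len(taken)


def random_instance(rng, n_det, n_gt):
    gt = rng.uniform(0, 80, size=(n_gt, 2))
    gt = np.hstack([gt, gt + rng.uniform(5, 30, size=(n_gt, 2))])
    # detections: jittered gts plus noise boxes
    dets = []
    for g in gt:
        if rng.random() < 0.8:
            dets.append(g + rng.normal(0, 3, size=4))
    while len(dets) < n_det:
        xy = rng.uniform(0, 80, size=2)
        dets.append(np.concatenate([xy, xy + rng.uniform(5, 30, size=2)]))
    dets = np.abs(np.array(dets)[:n_det])
    dets[:, 2:] = np.maximum(dets[:, 2:], dets[:, :2] + 1.0)
    scores = np.round(rng.uniform(0, 1, size=n_det), 3)
    return dets, scores, gt


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def test_match_detections_examples():
    gt = BoxSet(np.array([[0, 0, 10, 10.0]]), np.array([1]))
    # two detections on one gt: higher-scored wins, other is FP
    d = BoxSet(np.array([[0, 0, 10, 10], [1, 1, 10, 10.0]]), np.array([1, 1]),
               np.array([0.4, 0.9]))
    scores, tp, fn, _, _ = match_detections(d, gt, 0.5)
    assert list(scores) == [0.9, 0.4]
    assert list(tp) == [True, False] and fn == 0

    # perfect one-to-one
    d2 = BoxSet(gt.boxes.copy(), gt.labels.copy(), np.array([0.8]))
    _, tp2, fn2, _, _ = match_detections(d2, gt, 0.5)
    assert tp2.all() and fn2 == 0


def test_match_conservation(rng):
    """TP + FN = #gts and TP + FP = #detections."""
    for _ in range(20):
        dets, scores, gt = random_instance(rng, 8, 5)
        d = BoxSet(dets, np.ones(len(dets), dtype=int), scores)
        g = BoxSet(gt, np.ones(len(gt), dtype=int))
        _, tp, fn, _, _ = match_detections(d, g, 0.5)
        assert tp.sum() + fn == len(g)
        assert tp.sum() + (~tp).sum() == len(d)


def test_match_agrees_with_loop_oracle(rng):
    for _ in range(25):
        dets, scores, gt = random_instance(rng, 10, 6)
        d = BoxSet(dets, np.ones(10, dtype=int), scores)
        g = BoxSet(gt, np.ones(6, dtype=int))
        for thr in (0.3, 0.5, 0.75):
            _, tp, fn, _, _ = match_detections(d, g, thr)
            ref_flags, ref_fn = greedy_match_oracle(dets, scores, gt, thr)
            assert list(tp) == ref_flags and fn == ref_fn


def test_average_precision_hand_example():
    """2 gts, ranked flags (TP, FP, TP) -> (51*1 + 50*(2/3))/101."""
    curve = PRCurve(np.array([0.9, 0.8, 0.7]),
                    np.array([True, False, True]), n_gts=2)
    expected = (51 * 1.0 + 50 * (2 / 3)) / 101
    assert average_precision(curve) == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(0.8350, abs=5e-5)


def test_average_precision_extremes():
    perfect = PRCurve(np.array([0.9, 0.8]), np.array([True, True]), 2)
    assert average_precision(perfect) == 1.0
    none = PRCurve(np.zeros(0), np.zeros(0, dtype=bool), 3)
    assert average_precision(none) == 0.0
    with pytest.raises(ValueError):
        average_precision(PRCurve(np.zeros(0), np.zeros(0, dtype=bool), 0))


def test_average_precision_matches_enumeration_oracle(rng):
    """Random rankings of <= 20 boxes agree with the brute-force oracle to
    1e-9."""
    for _ in range(50):
        n = int(rng.integers(1, 21))
        n_gts = int(rng.integers(1, 12))
        flags = rng.random(n) < 0.5
        flags[np.cumsum(flags) > n_gts] = False  # cannot match more than gts
        scores = np.sort(rng.random(n))[::-1]
        curve = PRCurve(scores, flags, n_gts)
        assert abs(average_precision(curve) - ap_oracle(flags, n_gts)) < 1e-9


def test_ap_monotonicity(rng):
    """Appending a false positive never raises AP; prepending a true
    positive never lowers it."""
    for _ in range(20):
        n = int(rng.integers(1, 15))
        n_gts = 10
        flags = list(rng.random(n) < 0.6)
        scores = np.sort(rng.random(n))[::-1]
        base = average_precision(PRCurve(scores, np.array(flags), n_gts))
        worse = average_precision(PRCurve(
            np.concatenate([scores, [scores[-1] * 0.5]]),
            np.array(flags + [False]), n_gts))
        assert worse <= base + 1e-12
        if sum(flags) < n_gts:
            better = average_precision(PRCurve(
                np.concatenate([[1.0], scores]),
                np.array([True] + flags), n_gts))
            assert better >= base - 1e-12


def make_sets(gts_spec, dets_spec):
    gts = {k: BoxSet(np.array(v["boxes"], dtype=float).reshape(-1, 4),
                     np.array(v["labels"], dtype=int))
           for k, v in gts_spec.items()}
    dets = {k: BoxSet(np.array(v["boxes"], dtype=float).reshape(-1, 4),
                      np.array(v["labels"], dtype=int),
                      np.array(v["scores"], dtype=float))
            for k, v in dets_spec.items()}
    return dets, gts


def test_summarize_perfect_detections():
    gts_spec = {"a": {"boxes": [[0, 0, 50, 50], [60, 60, 100, 100]],
                      "labels": [1, 2]},
                "b": {"boxes": [[10, 10, 55, 60]], "labels": [1]}}
    dets_spec = {k: {**v, "scores": [0.9] * len(v["labels"])}
                 for k, v in gts_spec.items()}
    dets, gts = make_sets(gts_spec, dets_spec)
    rep = summarize(dets, gts, ["c1", "c2"])
    assert rep.map == pytest.approx(100.0)
    assert rep.mrecall == pytest.approx(100.0)
    assert rep.ap_medium == pytest.approx(100.0)
    assert rep.ap_large is None          # no large gts -> excluded
    assert np.allclose(np.diag(rep.confusion)[:2], 100.0)


def test_summarize_matches_independent_reference(rng):
    """Planted-error benchmark: the pipeline agrees with a from-scratch
    reference evaluator on mAP."""
    images = {}
    dets = {}
    for i in range(6):
        det_b, scores, gt_b = random_instance(rng, 7, 4)
        labels_g = rng.integers(1, 3, size=len(gt_b))
        labels_d = labels_g[rng.integers(0, len(gt_b), size=len(det_b))]
        images[f"im{i}"] = BoxSet(gt_b, labels_g)
        dets[f"im{i}"] = BoxSet(det_b, labels_d, scores)
    rep = summarize(dets, images, ["c1", "c2"])

    # reference: pool flags per class/threshold with the loop matcher
    ref_aps = []
    for cls in (1, 2):
        cls_aps = []
        for thr in IOU_THRESHOLDS:
            pooled = []
            n_gts = 0
            for key in images:
                g = images[key].boxes[images[key].labels == cls]
                n_gts += len(g)
                sel = dets[key].labels == cls
                d = dets[key].boxes[sel]
                s = dets[key].scores[sel]
                flags, _ = greedy_match_oracle(d, s, g, thr)
                pooled.extend(zip(sorted(s, reverse=True), flags))
            pooled.sort(key=lambda t: -t[0])
            cls_aps.append(ap_oracle([f for _, f in pooled], n_gts))
        ref_aps.append(100 * np.mean(cls_aps))
    assert rep.map == pytest.approx(np.mean(ref_aps), abs=1e-9)


def test_summarize_invariant_to_image_order(rng):
    det_b, scores, gt_b = random_instance(rng, 6, 3)
    items = {f"im{i}": (BoxSet(det_b + i, np.ones(6, dtype=int), scores),
                        BoxSet(gt_b + i, np.ones(3, dtype=int)))
             for i in range(4)}
    keys = list(items)
    rep1 = summarize({k: items[k][0] for k in keys},
                     {k: items[k][1] for k in keys}, ["c1"])
    rev = keys[::-1]
    rep2 = summarize({k: items[k][0] for k in rev},
                     {k: items[k][1] for k in rev}, ["c1"])
    assert rep1.map == pytest.approx(rep2.map, abs=1e-12)
    assert rep1.mrecall == pytest.approx(rep2.mrecall, abs=1e-12)


def test_summarize_requires_ground_truth():
    with pytest.raises(ValueError):
        summarize({}, {"a": BoxSet.empty()}, ["c1"])


def test_confusion_matrix_cases():
    gt = {"a": BoxSet(np.array([[0, 0, 40, 40.0]]), np.array([1]))}
    # wrong class detection on the class-1 gt -> cell (1, 2)
    dets = {"a": BoxSet(np.array([[1, 1, 40, 40.0]]), np.array([2]),
                        np.array([0.9]))}
    m = confusion_matrix(dets, gt, n_classes=2)
    assert m[0, 1] == 100.0

    # no detection above confidence 0.5 -> gt counted as background
    weak = {"a": BoxSet(np.array([[1, 1, 40, 40.0]]), np.array([1]),
                        np.array([0.2]))}
    m2 = confusion_matrix(weak, gt, n_classes=2)
    assert m2[0, 2] == 100.0

    # perfect -> 100 % diagonal; rows sum to 100
    perfect = {"a": BoxSet(np.array([[0, 0, 40, 40.0]]), np.array([1]),
                           np.array([0.9]))}
    m3 = confusion_matrix(perfect, gt, n_classes=2)
    assert m3[0, 0] == 100.0
    rows = m3.sum(axis=1)
    assert all(r == pytest.approx(100.0) or r == 0.0 for r in rows)

    # unmatched extra detection charges the background row
    ghost = {"a": BoxSet(np.array([[0, 0, 40, 40], [200, 200, 240, 240.0]]),
                         np.array([1, 2]), np.array([0.9, 0.8]))}
    m4 = confusion_matrix(ghost, gt, n_classes=2)
    assert m4[2, 1] == 100.0
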