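"""Detector assembly: FPN, proposals, assignment, training, inference."""

import numpy as np
import pytest

from larvadet import nn
from larvadet.boxes import BoxSet, decode_boxes, iou_matrix, nms
from larvadet.config import tiny_config
from larvadet.detector import (ABLATION_ROWS, FPN, Detector, ablation_grid,
                               assign_and_sample, level_anchors,
                               load_checkpoint, save_checkpoint, train)
from larvadet.nn import functional as F


# ---------------------------------------------------------------------------
# FPN
# ---------------------------------------------------------------------------

def make_levels(rng, channels=4, sizes=(16, 8, 4, 2), zero_from=None):
    ms = []
    for i, s in enumerate(sizes):
        data = rng.normal(size=(1, channels, s, s))
        if zero_from is not None and i >= zero_from:
            data = np.zeros_like(data)
        ms.append(nn.Tensor(data))
    return ms


def test_fpn_zero_upper_levels_reduce_to_lateral_path(rng):
    fpn = FPN(4, rng=rng)
    ms = make_levels(rng, zero_from=1)     # only M2 nonzero
    ps = fpn(ms)
    direct = fpn.smooth[0](ms[0]).data
    np.testing.assert_allclose(ps[0].data, direct, atol=1e-12)


def test_fpn_constant_levels_stay_constant(rng):
    fpn = FPN(3, rng=rng)
    # make smoothing convs averaging-like so constants map to constants
    for c in fpn.smooth:
        c.weight.data[:] = 0.0
        for o in range(3):
            c.weight.data[o, o] = 1.0 / 9.0
        c.bias.data[:] = 0.0
    ms = [nn.Tensor(np.full((1, 3, s, s), 2.0)) for s in (16, 8, 4, 2)]
    ps = fpn(ms)
    # interior cells see the full 3x3 support: value = sum of the two added
    # constants at each level of the top-down path
    expect = [8.0, 6.0, 4.0, 2.0]
    for p, e in zip(ps[:4], expect):
        np.testing.assert_allclose(p.data[0, :, 1:-1, 1:-1], e, atol=1e-12)


def test_fpn_matches_topdown_recursion_oracle(rng):
    fpn = FPN(4, rng=rng)
    ms = make_levels(rng)
    ps = fpn(ms)

    def conv3_oracle(x, conv):
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
        out = np.zeros_like(x)
        C = x.shape[0]
        for o in range(C):
            for y in range(x.shape[1]):
                for xx in range(x.shape[2]):
                    out[o, y, xx] = conv.bias.data[o] + (
                        conv.weight.data[o] * xp[:, y:y + 3, xx:xx + 3]).sum()
        return out

    t = [None] * 4
    t[3] = ms[3].data[0]
    for i in (2, 1, 0):
        up = t[i + 1].repeat(2, axis=1).repeat(2, axis=2)
        t[i] = ms[i].data[0] + up
    for i in range(4):
        np.testing.assert_allclose(ps[i].data[0], conv3_oracle(t[i], fpn.smooth[i]),
                                   atol=1e-10)
    # P6 is the stride-2 subsample of P5
    np.testing.assert_allclose(ps[4].data, ps[3].data[:, :, ::2, ::2], atol=1e-12)


def test_fpn_wrong_level_count(rng):
    with pytest.raises(ValueError):
        FPN(4, rng=rng)(make_levels(rng)[:3])


# ---------------------------------------------------------------------------
# proposals
# ---------------------------------------------------------------------------

def test_zero_delta_head_returns_anchors(tiny_cfg):
    det = Detector(tiny_cfg)
    det.rpn.delta.weight.data[:] = 0.0
    det.rpn.delta.bias.data[:] = 0.0
    img = np.random.default_rng(0).uniform(size=(128, 128, 3))
    pyr = det.features(img)
    proposals, rpn_t = det.propose(pyr, (128, 128), training=False)
    anchors = np.concatenate(rpn_t["anchors"])
    from larvadet.boxes import clip_boxes
    clipped = clip_boxes(anchors, 128, 128)
    # every proposal is exactly one of the clipped anchors
    d = np.abs(proposals[:, None, :] - clipped[None, :, :]).sum(axis=2)
    assert np.all(d.min(axis=1) < 1e-9)


def test_propose_matches_decode_sort_nms_oracle(tiny_cfg):
    det = Detector(tiny_cfg)
    # non-trivial deltas and scores
    rng = np.random.default_rng(3)
    det.rpn.delta.weight.data = rng.normal(0, 0.05,
                                           size=det.rpn.delta.weight.shape)
    det.rpn.obj.weight.data = rng.normal(0, 0.5, size=det.rpn.obj.weight.shape)
    img = rng.uniform(size=(128, 128, 3))
    pyr = det.features(img)
    proposals, rpn_t = det.propose(pyr, (128, 128), training=False)

    # brute-force reference from the same RPN tensors
    from larvadet.boxes import clip_boxes
    boxes_all, scores_all = [], []
    for logits, dtens, anchors in zip(rpn_t["logits"], rpn_t["deltas"],
                                      rpn_t["anchors"]):
        scores = logits.data
        deltas = dtens.data.transpose(0, 2, 3, 1).reshape(-1, 4)
        k = min(tiny_cfg.rpn_pre_nms_topk, len(scores))
        top = np.argsort(-scores)[:k]
        bx = clip_boxes(decode_boxes(deltas[top], anchors[top]), 128, 128)
        ok = (bx[:, 2] - bx[:, 0] >= 1) & (bx[:, 3] - bx[:, 1] >= 1)
        boxes_all.append(bx[ok])
        scores_all.append(scores[top][ok])
    bx = np.concatenate(boxes_all)
    sc = np.concatenate(scores_all)
    keep = nms(bx, sc, tiny_cfg.rpn_nms_thr)[:tiny_cfg.max_proposals_test]
    np.testing.assert_allclose(proposals, bx[keep], atol=1e-9)


def test_dominant_objectness_ranks_first(tiny_cfg):
    det = Detector(tiny_cfg)
    img = np.random.default_rng(1).uniform(size=(128, 128, 3))
    pyr = det.features(img)
    _, rpn_t = det.propose(pyr, (128, 128), training=False)
    # plant one dominant logit and re-rank
    scores = np.concatenate([l.data for l in rpn_t["logits"]])
    anchors = np.concatenate(rpn_t["anchors"])
    j = 1234
    scores = scores.copy()
    scores[j] = scores.max() + 10.0
    order = np.argsort(-scores)
    assert order[0] == j
    np.testing.assert_array_equal(anchors[order[0]], anchors[j])


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

def test_assign_gt_proposal_is_positive_with_zero_target(tiny_cfg, rng):
    gt = BoxSet(np.array([[10.0, 10.0, 60.0, 70.0]]), np.array([2]))
    props = np.array([[10.0, 10.0, 60.0, 70.0], [90.0, 90.0, 120.0, 120.0]])
    boxes, labels, targets, pos = assign_and_sample(props, gt, tiny_cfg, rng)
    i = np.flatnonzero(labels == 2)
    assert len(i) == 1
    np.testing.assert_allclose(targets[i], 0.0, atol=1e-12)
    # the IoU ~0 proposal is background
    assert (labels == 0).sum() == 1


def test_low_iou_proposal_is_background(tiny_cfg, rng):
    gt = BoxSet(np.array([[0.0, 0.0, 40.0, 40.0]]), np.array([1]))
    prop = np.array([[0.0, 0.0, 40.0, 12.0]])   # IoU = 0.3
    _, labels, _, _ = assign_and_sample(prop, gt, tiny_cfg, rng)
    assert labels[0] == 0


def test_assignment_matches_exhaustive_oracle(tiny_cfg, rng):
    for _ in range(10):
        gt_xy = rng.uniform(0, 80, size=(3, 2))
        gts = BoxSet(np.hstack([gt_xy, gt_xy + rng.uniform(20, 50, size=(3, 2))]),
                     rng.integers(1, 3, size=3))
        p_xy = rng.uniform(0, 80, size=(30, 2))
        props = np.hstack([p_xy, p_xy + rng.uniform(10, 60, size=(30, 2))])
        boxes, labels, _, pos = assign_and_sample(props, gts, tiny_cfg, rng)
        M = iou_matrix(boxes, gts.boxes)
        for i in range(len(boxes)):
            best = M[i].argmax()
            if M[i, best] >= tiny_cfg.head_fg_iou:
                assert labels[i] == gts.labels[best]
            else:
                assert labels[i] == 0
        assert (labels > 0).sum() <= int(tiny_cfg.roi_batch *
                                         tiny_cfg.roi_pos_fraction)


def test_no_gts_all_background(tiny_cfg, rng):
    props = np.array([[0.0, 0.0, 30.0, 30.0], [5.0, 5.0, 50.0, 60.0]])
    _, labels, _, pos = assign_and_sample(props, BoxSet.empty(), tiny_cfg, rng)
    assert (labels == 0).all() and not pos.any()


# ---------------------------------------------------------------------------
# training / inference
# ---------------------------------------------------------------------------

def test_training_is_deterministic(tiny_cfg, tiny_dataset):
    _, log1 = train(tiny_cfg, tiny_dataset[:4], max_iters=3)
    _, log2 = train(tiny_cfg, tiny_dataset[:4], max_iters=3)
    assert [r["total"] for r in log1] == [r["total"] for r in log2]


def test_lr_schedule_decays_at_milestones(tiny_dataset):
    cfg = tiny_config(seed=0)
    from dataclasses import replace
    cfg = replace(cfg, epochs=3, lr_decay_epochs=(1, 2), batch_size=2,
                  roi_batch=16, rpn_batch=16, max_proposals_train=50,
                  rpn_pre_nms_topk=50)
    _, log = train(cfg, tiny_dataset[:4])
    lrs = [r["lr"] for r in log]
    ipe = len(lrs) // 3
    assert lrs[0] == pytest.approx(cfg.lr)
    assert lrs[ipe] == pytest.approx(cfg.lr * 0.1)
    assert lrs[2 * ipe] == pytest.approx(cfg.lr * 0.01)


def test_train_rejects_empty_dataset(tiny_cfg):
    with pytest.raises(ValueError):
        train(tiny_cfg, [])


def test_detection_output_hygiene(tiny_cfg):
    """Untrained detector on a blank image: bounded count, valid scores,
    boxes inside the image, scores sorted descending."""
    det = Detector(tiny_cfg)
    out = det.detect(np.full((128, 128, 3), 0.4))
    assert len(out) <= tiny_cfg.max_detections
    if len(out):
        assert np.all(out.scores >= 0) and np.all(out.scores <= 1)
        assert np.all(out.boxes[:, 0] >= 0) and np.all(out.boxes[:, 2] <= 128)
        assert np.all(out.boxes[:, 1] >= 0) and np.all(out.boxes[:, 3] <= 128)
        assert np.all(np.diff(out.scores) <= 1e-12)


def test_oversized_input_is_capped(tiny_cfg):
    det = Detector(tiny_cfg)
    big = np.random.default_rng(0).uniform(size=(900, 1500, 3))
    out = det.detect(big)    # must not raise; boxes live in the capped frame
    if len(out):
        assert out.boxes[:, 2].max() <= 1333


def test_checkpoint_roundtrip(tmp_path, tiny_cfg, tiny_dataset):
    det, _ = train(tiny_cfg, tiny_dataset[:2], max_iters=1)
    p = tmp_path / "ckpt.npz"
    save_checkpoint(det, p)
    det2 = load_checkpoint(p)
    img = tiny_dataset[0][1]
    out1, out2 = det.detect(img), det2.detect(img)
    np.testing.assert_allclose(out1.boxes, out2.boxes)
    np.testing.assert_allclose(out1.scores, out2.scores)


def test_parameter_count_grows_with_modules(tiny_cfg):
    base = Detector(tiny_cfg.with_toggles(False, False, False)).num_parameters()
    with_cfem = Detector(tiny_cfg.with_toggles(True, False, False)).num_parameters()
    with_rffm = Detector(tiny_cfg.with_toggles(False, True, False)).num_parameters()
    full = Detector(tiny_cfg.with_toggles(True, True, True)).num_parameters()
    assert with_cfem > base
    assert with_rffm > base
    assert full > with_cfem and full > with_rffm


def test_table6_source_pairings_all_run(tiny_cfg, tiny_dataset):
    """All four (classification source, localization source) pairings build
    and produce finite losses."""
    from dataclasses import replace
    rng = np.random.default_rng(0)
    for cls_src in ("P", "M"):
        for loc_src in ("P", "M"):
            cfg = replace(tiny_cfg, cls_source=cls_src, loc_source=loc_src,
                          roi_batch=16, rpn_batch=16, rpn_pre_nms_topk=50,
                          max_proposals_train=30)
            det = Detector(cfg)
            _, img, gts = tiny_dataset[0]
            losses = det.training_losses(img, gts, rng)
            for k in ("rpn_cls", "rpn_loc", "cls", "loc"):
                assert np.isfinite(losses[k].item())


def test_ablation_grid_runs_all_six_rows(tiny_cfg, tiny_dataset):
    from dataclasses import replace
    cfg = replace(tiny_cfg, roi_batch=16, rpn_batch=16, rpn_pre_nms_topk=50,
                  max_proposals_train=30, max_proposals_test=30)
    rows = ablation_grid(cfg, tiny_dataset[:2], train_iters=1)
    assert len(rows) == len(ABLATION_ROWS) == 6
    params = {(r["cfem"], r["rffm"], r["tsm"]): r["params"] for r in rows}
    assert params[(True, False, False)] > params[(False, False, False)]
    assert params[(False, True, False)] > params[(False, False, False)]
    assert params[(True, True, True)] > params[(True, True, False)]
    for r in rows:
        assert np.isfinite(r["final_loss"])
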