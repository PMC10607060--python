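"""Two-stage detector: backbone → enhancement → FPN → proposals → fused RoI
heads.

The pipeline mirrors the classic region-proposal design: a small
four-stage CNN produces C2..C5 (strides 4/8/16/32); per-level projection
(optionally with context attention) yields the lateral pyramid M2..M5; a
top-down pathway produces P2..P5 plus a stride-2 subsampled P6 used only for
proposal generation.  Proposals are pooled from all levels and adaptively
fused, then classified and localised by (optionally task-separated) heads.

Any module exposing ``__call__(image) -> [C2, C3, C4, C5]`` can replace the
built-in backbone.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
from PIL import Image

from . import nn
from .annotation import DatasetManifest, read_voc_xml
from .boxes import (BoxSet, clip_boxes, decode_boxes, encode_boxes,
                    iou_matrix, nms)
from .cfem import CFEM
from .config import DetectorConfig
from .heads import HeadOutput, SeparatedHead, SharedHead, head_losses
from .nn import functional as F
from .rffm import RFFM, pool_roi

STRIDES = (4, 8, 16, 32)          # C2..C5 / M2..M5 / P2..P5
RPN_STRIDES = (4, 8, 16, 32, 64)  # P2..P6

CHECKPOINT_VERSION = "larvadet-ckpt-1"


# ---------------------------------------------------------------------------
# backbone
# ---------------------------------------------------------------------------

class TinyBackbone(nn.Module):
    """Four-stage CNN emitting C2..C5 at strides 4/8/16/32."""

    def __init__(self, widths=(32, 64, 128, 256), *, rng: np.random.Generator):
        w1, w2, w3, w4 = widths
        self.widths = tuple(widths)
        self.stem_a = nn.Conv2d(3, w1, 3, stride=2, padding=1, rng=rng)
        self.stem_b = nn.Conv2d(w1, w1, 3, stride=2, padding=1, rng=rng)
        self.s2 = nn.Conv2d(w1, w1, 3, padding=1, rng=rng)
        self.d3 = nn.Conv2d(w1, w2, 3, stride=2, padding=1, rng=rng)
        self.s3 = nn.Conv2d(w2, w2, 3, padding=1, rng=rng)
        self.d4 = nn.Conv2d(w2, w3, 3, stride=2, padding=1, rng=rng)
        self.s4 = nn.Conv2d(w3, w3, 3, padding=1, rng=rng)
        self.d5 = nn.Conv2d(w3, w4, 3, stride=2, padding=1, rng=rng)
        self.s5 = nn.Conv2d(w4, w4, 3, padding=1, rng=rng)

    def __call__(self, x: nn.Tensor) -> list[nn.Tensor]:
        h = F.relu(self.stem_b(F.relu(self.stem_a(x))))
        c2 = F.relu(self.s2(h))
        h = F.relu(self.d3(c2))
        c3 = F.relu(self.s3(h))
        h = F.relu(self.d4(c3))
        c4 = F.relu(self.s4(h))
        h = F.relu(self.d5(c4))
        c5 = F.relu(self.s5(h))
        return [c2, c3, c4, c5]


# ---------------------------------------------------------------------------
# feature pyramid (top-down pathway over the lateral pyramid M2..M5)
# ---------------------------------------------------------------------------

class FPN(nn.Module):
    def __init__(self, channels: int, *, rng: np.random.Generator):
        self.smooth = [nn.Conv2d(channels, channels, 3, padding=1, rng=rng)
                       for _ in range(4)]

    def __call__(self, ms: list[nn.Tensor]) -> list[nn.Tensor]:
        if len(ms) != 4:
            raise ValueError("expected four lateral levels M2..M5")
        tops = [ms[3]]
        for m in reversed(ms[:3]):
            up = F.resize_nearest(tops[0], m.shape[2:])
            tops.insert(0, F.add(m, up))
        ps = [self.smooth[i](t) for i, t in enumerate(tops)]
        p6 = F.subsample2(ps[3])
        return ps + [p6]


# ---------------------------------------------------------------------------
# region proposal network
# ---------------------------------------------------------------------------

class RPN(nn.Module):
    def __init__(self, channels: int, n_anchors: int, *, rng: np.random.Generator):
        self.n_anchors = n_anchors
        self.conv = nn.Conv2d(channels, channels, 3, padding=1, rng=rng)
        self.obj = nn.Conv2d(channels, n_anchors, 1, rng=rng,
                             init="normal", init_std=0.01)
        self.delta = nn.Conv2d(channels, 4 * n_anchors, 1, rng=rng,
                               init="normal", init_std=0.01)

    def __call__(self, p: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        h = F.relu(self.conv(p))
        return self.obj(h), self.delta(h)


def level_anchors(hw: tuple[int, int], stride: int, size: float,
                  ratios) -> np.ndarray:
    """Anchor grid for one level, ordered anchor-major then row-major, to
    match the (A, H, W) layout of the objectness map."""
    H, W = hw
    ratios = np.asarray(ratios, dtype=np.float64)
    ws = size / np.sqrt(ratios)
    hs = size * np.sqrt(ratios)
    cx = (np.arange(W) + 0.5) * stride
    cy = (np.arange(H) + 0.5) * stride
    CX, CY = np.meshgrid(cx, cy)                    # (H, W)
    out = np.empty((len(ratios), H, W, 4))
    for a in range(len(ratios)):
        out[a, :, :, 0] = CX - ws[a] / 2
        out[a, :, :, 1] = CY - hs[a] / 2
        out[a, :, :, 2] = CX + ws[a] / 2
        out[a, :, :, 3] = CY + hs[a] / 2
    return out.reshape(-1, 4)


# ---------------------------------------------------------------------------
# target assignment and sampling
# ---------------------------------------------------------------------------

def assign_rpn_targets(anchors: np.ndarray, gts: BoxSet, cfg: DetectorConfig,
                       rng: np.random.Generator):
    """Anchor labels: 1 positive, 0 negative, -1 ignored; sampled subset."""
    n = len(anchors)
    labels = np.full(n, -1, dtype=np.int64)
    deltas = np.zeros((n, 4))
    if len(gts) == 0:
        labels[:] = 0
    else:
        ious = iou_matrix(anchors, gts.boxes)
        best_gt = ious.argmax(axis=1)
        best_iou = ious[np.arange(n), best_gt]
        labels[best_iou < cfg.rpn_neg_iou] = 0
        labels[best_iou >= cfg.rpn_pos_iou] = 1
        # each gt claims its best-overlapping anchor(s) so none goes unmatched
        gt_best = ious.max(axis=0)
        for g in range(len(gts)):
            if gt_best[g] > 0:
                labels[np.flatnonzero(ious[:, g] >= gt_best[g] - 1e-9)] = 1
        pos = labels == 1
        if np.any(pos):
            deltas[pos] = encode_boxes(gts.boxes[best_gt[pos]], anchors[pos])
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    n_pos = min(len(pos_idx), int(cfg.rpn_batch * cfg.rpn_pos_fraction))
    if len(pos_idx) > n_pos:
        pos_idx = rng.choice(pos_idx, size=n_pos, replace=False)
    n_neg = min(len(neg_idx), cfg.rpn_batch - n_pos)
    if len(neg_idx) > n_neg:
        neg_idx = rng.choice(neg_idx, size=n_neg, replace=False)
    return pos_idx, neg_idx, deltas


def assign_and_sample(proposals: np.ndarray, gts: BoxSet,
                      cfg: DetectorConfig, rng: np.random.Generator):
    """Label proposals (max-IoU rule at ``head_fg_iou``), sample a fixed-size
    minibatch with the configured positive fraction, and build normalised
    regression targets for the positives."""
    n = len(proposals)
    labels = np.zeros(n, dtype=np.int64)
    targets = np.zeros((n, 4))
    if len(gts) > 0 and n > 0:
        ious = iou_matrix(proposals, gts.boxes)
        best_gt = ious.argmax(axis=1)
        best_iou = ious[np.arange(n), best_gt]
        fg = best_iou >= cfg.head_fg_iou
        labels[fg] = gts.labels[best_gt[fg]]
        if np.any(fg):
            targets[fg] = encode_boxes(gts.boxes[best_gt[fg]], proposals[fg],
                                       stds=cfg.bbox_reg_stds)
    pos_idx = np.flatnonzero(labels > 0)
    neg_idx = np.flatnonzero(labels == 0)
    n_pos = min(len(pos_idx), int(cfg.roi_batch * cfg.roi_pos_fraction))
    if len(pos_idx) > n_pos:
        pos_idx = rng.choice(pos_idx, size=n_pos, replace=False)
    n_neg = min(len(neg_idx), cfg.roi_batch - n_pos)
    if len(neg_idx) > n_neg:
        neg_idx = rng.choice(neg_idx, size=n_neg, replace=False)
    keep = np.concatenate([pos_idx, neg_idx]).astype(np.intp)
    return (proposals[keep], labels[keep], targets[keep],
            labels[keep] > 0)


def single_level_index(boxes: np.ndarray) -> np.ndarray:
    """Canonical FPN level assignment by box size (k0 = 4 at scale 224)."""
    area = (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])
    k = np.floor(4 + np.log2(np.sqrt(np.maximum(area, 1e-6)) / 224.0))
    return np.clip(k, 2, 5).astype(int) - 2


# ---------------------------------------------------------------------------
# the detector
# ---------------------------------------------------------------------------

class Detector(nn.Module):
    def __init__(self, cfg: DetectorConfig, backbone: nn.Module | None = None):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.backbone = backbone or TinyBackbone(cfg.backbone_widths, rng=rng)
        self.cfem = CFEM(list(self.backbone.widths), cfg.channels,
                         cfg.cfem_rate, rng=rng, enabled=cfg.cfem_enabled,
                         image_pool=cfg.cfem_image_pool)
        self.fpn = FPN(cfg.channels, rng=rng)
        self.rpn = RPN(cfg.channels, len(cfg.anchor_ratios), rng=rng)
        if cfg.rffm_enabled:
            self.rffm_cls = RFFM(4, cfg.channels, cfg.roi_size, rng=rng)
            self.rffm_loc = RFFM(4, cfg.channels, cfg.roi_size, rng=rng) \
                if cfg.tsm_enabled else None
        else:
            self.rffm_cls = self.rffm_loc = None
        head_cls = SeparatedHead if cfg.tsm_enabled else SharedHead
        self.head = head_cls(cfg.n_classes, cfg.channels, cfg.roi_size,
                             cfg.head_width, rng=rng)

    # -- feature extraction ------------------------------------------------
    def features(self, image: np.ndarray):
        """image: (H, W, 3) float in [0,1] → pyramids dict with M and P lists."""
        x = nn.Tensor(np.ascontiguousarray(
            image.transpose(2, 0, 1))[None] - 0.5)
        cs = self.backbone(x)
        ms = self.cfem(cs)
        ps = self.fpn(ms)          # P2..P5 + P6
        return {"M": ms, "P": ps[:4], "P_rpn": ps}

    # -- proposal stage ----------------------------------------------------
    def propose(self, pyr, image_hw, *, training: bool):
        cfg = self.cfg
        H, W = image_hw
        rpn_outs = [self.rpn(p) for p in pyr["P_rpn"]]
        all_boxes, all_scores, all_logits, all_anchors, all_dtens = [], [], [], [], []
        for (obj, dlt), stride, size in zip(rpn_outs, RPN_STRIDES,
                                            cfg.anchor_sizes):
            A = self.rpn.n_anchors
            hl, wl = obj.shape[2:]
            anchors = level_anchors((hl, wl), stride, size, cfg.anchor_ratios)
            logits = F.reshape(obj, (-1,))
            dtens = F.reshape(dlt, (A, 4, hl, wl))
            scores = logits.data
            deltas = dtens.data.transpose(0, 2, 3, 1).reshape(-1, 4)
            k = min(cfg.rpn_pre_nms_topk, len(scores))
            top = np.argpartition(-scores, k - 1)[:k] if k < len(scores) \
                else np.arange(len(scores))
            boxes = clip_boxes(decode_boxes(deltas[top], anchors[top]), W, H)
            wh_ok = (boxes[:, 2] - boxes[:, 0] >= 1) & \
                    (boxes[:, 3] - boxes[:, 1] >= 1)
            all_boxes.append(boxes[wh_ok])
            all_scores.append(scores[top][wh_ok])
            all_logits.append(logits)
            all_anchors.append(anchors)
            all_dtens.append(dtens)
        boxes = np.concatenate(all_boxes)
        scores = np.concatenate(all_scores)
        keep = nms(boxes, scores, cfg.rpn_nms_thr)
        limit = cfg.max_proposals_train if training else cfg.max_proposals_test
        keep = keep[:limit]
        proposals = boxes[keep]
        rpn_tensors = {"logits": all_logits, "deltas": all_dtens,
                       "anchors": all_anchors}
        return proposals, rpn_tensors

    def rpn_loss(self, rpn_tensors, gts: BoxSet, rng: np.random.Generator):
        anchors = np.concatenate(rpn_tensors["anchors"])
        pos_idx, neg_idx, targets = assign_rpn_targets(anchors, gts,
                                                       self.cfg, rng)
        sampled = np.concatenate([pos_idx, neg_idx]).astype(np.intp)
        if len(sampled) == 0:
            return nn.Tensor(0.0), nn.Tensor(0.0)
        logits_flat = F.concat(rpn_tensors["logits"], axis=0)
        # per-level delta tensors flattened to (n,4) in anchor order
        dparts = [F.reshape(_to_anchor_major(d), (-1, 4))
                  for d in rpn_tensors["deltas"]]
        deltas_flat = F.concat(dparts, axis=0)
        tlabels = np.zeros(len(sampled))
        tlabels[:len(pos_idx)] = 1.0
        sel_logits = F.take_rows(F.reshape(logits_flat, (-1, 1)), sampled)
        cls = F.bce_with_logits(F.reshape(sel_logits, (-1,)), tlabels)
        if len(pos_idx) == 0:
            return cls, nn.Tensor(0.0)
        pos_deltas = F.take_rows(deltas_flat, pos_idx.astype(np.intp))
        loc = F.smooth_l1_loss(pos_deltas, targets[pos_idx],
                               normalizer=float(len(sampled)))
        return cls, loc

    # -- RoI features --------------------------------------------------
    def _roi_features(self, pyr, boxes: np.ndarray, source: str,
                      fusion: RFFM | None):
        levels = pyr[source]
        if self.cfg.rffm_enabled and fusion is not None:
            stack = pool_roi(levels, list(STRIDES), boxes, self.cfg.roi_size)
            return fusion(stack)
        # single-level fallback: pool each box from its size-matched level
        lvl_idx = single_level_index(boxes)
        pooled_parts, order = [], []
        for li in range(4):
            sel = np.flatnonzero(lvl_idx == li)
            if len(sel) == 0:
                continue
            pooled = F.roi_align(levels[li], boxes[sel],
                                 spatial_scale=1.0 / STRIDES[li],
                                 out_size=self.cfg.roi_size)
            pooled_parts.append(F.reshape(pooled, (len(sel), -1)))
            order.append(sel)
        flat = F.concat(pooled_parts, axis=0)
        inv = np.argsort(np.concatenate(order))
        return F.reshape(F.take_rows(flat, inv),
                         (len(boxes), self.cfg.channels,
                          self.cfg.roi_size, self.cfg.roi_size))

    def head_outputs(self, pyr, boxes: np.ndarray) -> HeadOutput:
        cfg = self.cfg
        if cfg.tsm_enabled:
            f_cls = self._roi_features(pyr, boxes, cfg.cls_source, self.rffm_cls)
            f_loc = self._roi_features(pyr, boxes, cfg.loc_source, self.rffm_loc)
            return self.head(f_cls, f_loc)
        f = self._roi_features(pyr, boxes, "P", self.rffm_cls)
        return self.head(f)

    # -- full training / inference passes -----------------------------
    def training_losses(self, image: np.ndarray, gts: BoxSet,
                        rng: np.random.Generator) -> dict:
        cfg = self.cfg
        H, W = image.shape[:2]
        pyr = self.features(image)
        proposals, rpn_tensors = self.propose(pyr, (H, W), training=True)
        rpn_cls, rpn_loc = self.rpn_loss(rpn_tensors, gts, rng)
        if cfg.add_gt_proposals and len(gts) > 0:
            proposals = np.concatenate([proposals, gts.boxes])
        boxes, labels, targets, pos_mask = assign_and_sample(
            proposals, gts, cfg, rng)
        if len(boxes) == 0:
            zero = nn.Tensor(0.0)
            return {"rpn_cls": rpn_cls, "rpn_loc": rpn_loc,
                    "cls": zero, "loc": zero, "sampled": False}
        out = self.head_outputs(pyr, boxes)
        cls, loc, sampled = head_losses(out, labels, targets, pos_mask)
        return {"rpn_cls": rpn_cls, "rpn_loc": rpn_loc,
                "cls": cls, "loc": loc, "sampled": sampled}

    def detect(self, image: np.ndarray) -> BoxSet:
        """Run inference on one (H, W, 3) image in [0, 1]."""
        cfg = self.cfg
        image = _cap_size(image, cfg.max_image_size)
        H, W = image.shape[:2]
        pyr = self.features(image)
        proposals, _ = self.propose(pyr, (H, W), training=False)
        if len(proposals) == 0:
            return BoxSet.empty()
        out = self.head_outputs(pyr, proposals)
        logits = out.cls_logits.data
        z = logits - logits.max(axis=1, keepdims=True)
        probs = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        deltas = out.box_deltas.data
        all_boxes, all_scores, all_labels = [], [], []
        for k in range(1, cfg.n_classes + 1):
            sc = probs[:, k]
            dk = deltas[:, (k - 1) * 4:k * 4]
            bx = clip_boxes(decode_boxes(dk, proposals, stds=cfg.bbox_reg_stds),
                            W, H)
            ok = (sc >= cfg.score_thr) & (bx[:, 2] - bx[:, 0] >= 1) & \
                 (bx[:, 3] - bx[:, 1] >= 1)
            if not np.any(ok):
                continue
            keep = nms(bx[ok], sc[ok], cfg.test_nms_thr)
            all_boxes.append(bx[ok][keep])
            all_scores.append(sc[ok][keep])
            all_labels.append(np.full(len(keep), k))
        if not all_boxes:
            return BoxSet.empty()
        boxes = np.concatenate(all_boxes)
        scores = np.concatenate(all_scores)
        labels = np.concatenate(all_labels)
        order = np.lexsort((np.arange(len(scores)), -scores))
        order = order[:cfg.max_detections]
        return BoxSet(boxes[order], labels[order], scores[order])


def _to_anchor_major(dtens):
    """(A,4,H,W) delta tensor → (A,H,W,4), matching the anchor-grid order."""
    return F.transpose(dtens, (0, 2, 3, 1))


def _cap_size(image: np.ndarray, cap: tuple[int, int]) -> np.ndarray:
    """Proportionally shrink images whose sides exceed the configured cap."""
    long_cap, short_cap = max(cap), min(cap)
    H, W = image.shape[:2]
    long_side, short_side = max(H, W), min(H, W)
    scale = min(1.0, long_cap / long_side, short_cap / short_side)
    if scale >= 1.0:
        return image
    new_w, new_h = int(round(W * scale)), int(round(H * scale))
    pil = Image.fromarray((np.clip(image, 0, 1) * 255).astype(np.uint8))
    return np.asarray(pil.resize((new_w, new_h), Image.BILINEAR),
                      dtype=np.float64) / 255.0


# ---------------------------------------------------------------------------
# data loading, training loop, checkpoints
# ---------------------------------------------------------------------------

def load_manifest_dataset(manifest: DatasetManifest, split: str | None = None):
    """Materialise (image_id, image array in [0,1], BoxSet) triples."""
    out = []
    for e in manifest.paths(split):
        img = np.asarray(Image.open(e.image_path).convert("RGB"),
                         dtype=np.float64) / 255.0
        _, boxes = read_voc_xml(e.xml_path, manifest.class_names)
        out.append((Path(e.image_path).stem, img, boxes))
    return out


def train(cfg: DetectorConfig, dataset, *, max_iters: int | None = None,
          detector: Detector | None = None, log_every: int = 10):
    """Train a detector with SGD; returns (detector, per-iteration log).

    ``dataset`` is a list of (image_id, image, BoxSet).  When ``max_iters``
    is given it overrides the epoch count (constant learning rate);
    otherwise the epoch schedule with its decay milestones applies.
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    det = detector or Detector(cfg)
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 7])
    opt = nn.SGD(det.parameters(), lr=cfg.lr, momentum=cfg.momentum,
                 weight_decay=cfg.weight_decay)
    n = len(dataset)
    iters_per_epoch = max(1, n // cfg.batch_size)
    total_iters = max_iters if max_iters is not None \
        else cfg.epochs * iters_per_epoch
    log = []
    order = rng.permutation(n)
    cursor = 0
    for it in range(total_iters):
        if max_iters is None:
            epoch = it // iters_per_epoch
            decay = sum(1 for e in cfg.lr_decay_epochs if epoch >= e)
            opt.lr = cfg.lr * (cfg.lr_decay_factor ** decay)
        opt.zero_grad()
        terms = {"rpn_cls": 0.0, "rpn_loc": 0.0, "cls": 0.0, "loc": 0.0}
        for _ in range(cfg.batch_size):
            if cursor >= n:
                order = rng.permutation(n)
                cursor = 0
            _, img, gts = dataset[order[cursor]]
            cursor += 1
            if rng.random() < cfg.flip_prob:
                img, gts = _hflip(img, gts)
            losses = det.training_losses(img, gts, rng)
            total = None
            for key in terms:
                t = losses[key]
                terms[key] += t.item() / cfg.batch_size
                scaled = F.mul(t, 1.0 / cfg.batch_size)
                total = scaled if total is None else F.add(total, scaled)
            total.backward()
        opt.step()
        rec = {"iter": it, "lr": opt.lr, **terms,
               "total": sum(terms.values())}
        log.append(rec)
    return det, log


def _hflip(img: np.ndarray, gts: BoxSet):
    W = img.shape[1]
    flipped = np.ascontiguousarray(img[:, ::-1])
    if len(gts) == 0:
        return flipped, gts
    b = gts.boxes.copy()
    b[:, [0, 2]] = W - gts.boxes[:, [2, 0]]
    return flipped, BoxSet(b, gts.labels, gts.scores)


def save_checkpoint(det: Detector, path):
    path = Path(path)
    state = det.state_dict()
    np.savez(path, __version__=CHECKPOINT_VERSION,
             __config__=json.dumps(asdict(det.cfg)), **state)


def load_checkpoint(path) -> Detector:
    with np.load(path, allow_pickle=False) as data:
        version = str(data["__version__"])
        if version != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {version}")
        raw = json.loads(str(data["__config__"]))
        cfg = DetectorConfig(**{k: tuple(v) if isinstance(v, list) else v
                                for k, v in raw.items()})
        det = Detector(cfg)
        det.load_state_dict({k: data[k] for k in data.files
                             if not k.startswith("__")})
    return det


def infer(det: Detector, images) -> list[BoxSet]:
    """Detections (score-sorted, per-class NMS applied) for each image."""
    return [det.detect(np.asarray(img, dtype=np.float64)) for img in images]


# ---------------------------------------------------------------------------
# ablation harness
# ---------------------------------------------------------------------------

ABLATION_ROWS = [
    (False, False, False),
    (True, False, False),
    (False, True, False),
    (False, True, True),
    (True, True, False),
    (True, True, True),
]


def ablation_grid(base_cfg: DetectorConfig, dataset, *,
                  train_iters: int = 1, rows=None) -> list[dict]:
    """Build, briefly train and run every module on/off combination."""
    results = []
    for cfem, rffm, tsm in (rows or ABLATION_ROWS):
        cfg = base_cfg.with_toggles(cfem, rffm, tsm)
        det = Detector(cfg)
        n_params = det.num_parameters()
        det, log = train(cfg, dataset, max_iters=train_iters, detector=det)
        dets = det.detect(dataset[0][1])
        results.append({
            "cfem": cfem, "rffm": rffm, "tsm": tsm,
            "params": n_params, "final_loss": log[-1]["total"],
            "n_detections": len(dets),
        })
    return results
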